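# Methods

This note documents the models, the estimation and search procedures,
the synthetic-data generators, and the numerical and design choices made
where the design was genuinely open. It states no empirical numbers
beyond what the test suite and `scripts/acceptance.py` themselves
compute.

## Decision-path model and estimation

A decision-path model for a test person is a pair (S, θ). S is a
conjunction of features V₁=v₁ ∧ … ∧ V_J=v_J over distinct predictors,
with every v_j equal to the person's observed value; θ is a
K-vector of outcome probabilities (K = 2 throughout the experiments the
package targets). θ is the BDeu posterior mean

    θ_k = (α_k + N_k) / (α + N),  α_k = pess/K,

computed from the training individuals that satisfy S. **pess** (prior
equivalent sample size, unitless, default 1) is the total Dirichlet
prior mass: larger values pull θ toward uniform. With pess > 0, θ is
strictly inside (0,1)^K, so log scores and Brier scores are always
defined. An individual satisfies a conjunct only with an observed equal
value; a missing value never matches. Rows whose *target* is missing are
dropped at load time and counted in the load report — they cannot
contribute to any count in any estimator.

## Greedy growth

Growth starts from the empty path with the matching subgroup D equal to
the full training set. The candidate set is every predictor not yet in S
whose value the person has observed (missingness in the test person thus
needs no imputation: those variables are simply never candidates). Each
candidate V = v is scored on the split of the current D into D_temp
(matches V = v) and D − D_temp, always as a two-sample score so that all
candidates at a step are judged on the same set of individuals.
Candidates with empty D_temp are skipped: adding one would leave the
search without training individuals. Growth terminates when the
candidate set is empty, every candidate would empty the subgroup, or the
remaining individuals all share one outcome value. There is no depth cap
beyond those three conditions.

Scoring criteria:

* **Bayesian (DP-BAY).** The log marginal likelihood of the outcome
  labels in the two subsamples under independent Dirichlet–multinomial
  models, Σ_{j=1,2} [logΓ(α_j) − logΓ(N_j+α_j) + Σ_k (logΓ(N_jk+α_jk) −
  logΓ(α_jk))], with the non-informative per-sample prior α_jk = 1/K
  (hence α_j = 1). All paths are equally likely a priori, so this
  marginal is the model score up to a constant. Computed entirely with
  `scipy.special.gammaln`; never via factorials.
* **Information gain (DP-IG).** Parent entropy minus size-weighted child
  entropies, in bits, with 0·log 0 ≡ 0 and the empty dataset assigned
  entropy 0. Tiny negative values from float rounding are clipped to 0.
* **LOOCV AUC (DP-AUC).** Within each of D_temp and D − D_temp
  separately, each individual receives a leave-one-out BDeu prediction
  θ_p = (α_p + N_p − [y_i = p])/(α + N − 1) (a singleton subgroup falls
  back to the prior α_p/α); the pooled |D| predictions are scored by the
  Mann–Whitney AUC against the true labels. The symmetric treatment of
  the two subsamples is a deliberate reading: applying leave-one-out in
  only one subsample would score the two samples on different footings.
  If the pooled labels are single-class the score is defined as 0.5.

Tie-breaking on candidate scores is deterministic: strictly-greater
comparison in schema order, so the earliest variable wins ties.

## Pruning

During growth the score recorded for each added feature is kept; the
pruned path is the prefix ending at the step with the **highest recorded
score**, ties resolved toward the shortest prefix (simpler model).
Pruning never empties a path that grew at least one feature — the empty
path's prior score is not part of the trace. θ is then re-estimated from
the pruned path's matching subgroup.

A property worth stating plainly: scores recorded at different depths
condition on different (nested, shrinking) subgroups. For the Bayesian
criterion the log marginal of a smaller subgroup is systematically
closer to zero, and a pure split of a tiny subgroup attains the maximal
information gain of its parent, so for DP-BAY and DP-IG the recorded
maximum tends to sit at or near the final step and pruning truncates
little; DP-AUC's bounded scores prune more aggressively. This is an
inherent feature of comparing the recorded scores across depths, which
the package implements as specified rather than renormalizing; its
practical consequence is that personalized paths often end in small
matching subgroups whose smoothed estimates are noisy at small training
sizes. The cross-validated benchmark in the acceptance tests measures
exactly this trade-off against the population tree.

## Population-tree comparator

The comparator is a single probabilistic tree fitted to the whole
training set: top-down recursive **multiway** splits on the variable
maximizing multiway information gain (the "deviance" criterion), with
children covering the split variable's full domain. It is a standard
greedy information-gain tree, not a re-implementation of any particular
CART code: binary-split CART would differ, and this is a documented
comparator caveat. Defaults: `min_leaf = 1`, no depth cap, pruning on.

Design choices that the tree needed and a path does not:

* **Training rows missing the split variable** follow the child that
  received the most training rows (ties toward the earliest domain
  value), so every training row reaches exactly one leaf and leaf counts
  partition the training set. The same child handles missing values at
  prediction time.
* **Zero-gain splits are allowed** (the tie rule picks the earliest
  variable); this lets the tree solve parity-structured problems where
  no single variable is marginally informative, at the cost of growing
  on noise — which pruning is expected to undo.
* **Pruning** is a bottom-up Bayesian collapse: an internal node whose
  children are all leaves is collapsed unless the children's summed
  Dirichlet–multinomial log marginals (α = 1/K per class per child)
  exceed the merged node's. This reuses the same marginal machinery as
  the split score and needs no held-out set.
* Leaves carry BDeu-smoothed θ with the same pess as the path methods,
  so leaf estimation is identical across comparators.

## Discretization and screening

Continuous predictors are discretized by recursive MDL entropy
partitioning. Within an interval, candidate cuts are midpoints between
adjacent distinct values (midpoints between two groups pure in the same
class are skipped — they cannot host an optimum); the gain-maximal cut
is accepted iff

    gain > log2(N−1)/N + [log2(3^k − 2) − (k·H − k₁·H₁ − k₂·H₂)]/N

with k, k₁, k₂ the numbers of classes present in the interval and its
halves and H, H₁, H₂ their entropies; accepted cuts recurse into both
halves. Bins are half-open (lo, hi] — a value equal to a threshold falls
in the lower bin. Variables earning no cut become single-bin ("all") and
are flagged uninformative. Cut sets serialize to a plain-text sidecar
(variable name plus thresholds per line).

In cross-validation, cuts are learned on the training folds only and
applied to the held-out fold; a `global` mode (cuts learned once on the
full table) exists for sensitivity analysis since fold-scoped
discretization is a leakage-avoidance choice, not a logical necessity.

Discrete marker screening uses the raw Pearson chi-square statistic of
each variable-by-outcome table (no continuity correction, no p-value
threshold): it is a ranking device for wide genotype panels, with rows
missing a variable excluded from that variable's table and constant
variables scored 0.

## Evaluation protocol

Stratified k-fold cross-validation, k = 20 by default, folds preserving
the positive proportion (delegated to scikit-learn's `StratifiedKFold`
with a fixed seed; k may not exceed the smallest class count). Per fold,
the tree is fitted once and each decision-path method derives one model
per test individual, so every individual gets exactly one prediction per
method; a method failure on an individual falls back to the smoothed
training prevalence and is counted in the result.

Metrics: the Mann–Whitney AUC (midrank tie handling — half credit per
tied pair, matching the probabilistic reading of the AUC) reported as
the across-fold mean with a t-based 95% CI (single-class folds are
skipped and counted) alongside the pooled-prediction AUC; the Brier
score BS reported positively oriented as 1 − BS; and the Brier skill
score BSS = 1 − BS/BS_ref, the reference predicting the dataset
prevalence for everyone (its own BSS is exactly 0). Methods are compared
across datasets with a classic two-sided paired t-test (mean difference,
t, df, p reported separately; zero-variance differences use the edge
conventions p = 1 for identical pairs, p = 0 otherwise). Raw p-values
are reported by default, with an optional Holm correction in the CLI.
Personalized-vs-tree disagreement is computed both as the fraction of
individuals whose 0.5-thresholded labels differ and as the fraction
whose conjunct *sets* differ from the tree routing path — the two
readings answer different questions and both are reported.

## Synthetic data

The generators exist so that every stage is testable without any
clinical data download, and their defaults define the package's study
conditions.

`gen_path_process` draws independent Bernoulli(½) binary signal
variables; the outcome follows an explicit conditional table
P(T=1 | signal pattern); noise variables (domain sizes 2–4, like
discretized clinical measurements) are independent of everything;
missingness is injected MCAR on predictor cells. Signal columns are
placed at random positions so schema order carries no hint. The
generator returns ground truth: the signal set, each row's Bayes-optimal
positive probability, and the Bayes-optimal AUC computed by pair
counting of those probabilities against the realized outcomes.

Two canonical parameterizations:

* `single_signal`: one binary signal with P(T=1|V=1) = 0.9 and
  P(T=1|V=0) = 0.1 — the recovery benchmark. Its population Bayes AUC is
  0.9·0.9 + ½·(0.9·0.1 + 0.1·0.9) = 0.90 (the tie term is essential:
  the optimal score takes only two values).
* `planted`: a logistic risk model, logit P(T=1|pattern) = a + β·(Σ
  pattern − s/2), with β = 1.5 per risk feature (odds ratio ≈ 4.5, the
  moderate effect size typical of clinical risk factors) and the
  intercept a solved by bisection so the expected prevalence is exact.
  This parameterization was chosen for face validity — it produces
  cohorts whose Bayes-optimal AUC sits in the 0.75–0.82 range where
  published clinical discrimination typically lives — and is fixed.

`make_benchmark_suite` instantiates seven shapes spanning the clinically
realistic range (21–158 discrete predictors; full-scale sample sizes
549–11,178; prevalence 4.5%–61%), each with 3 planted signal variables
and 2% MCAR missingness, at a configurable scale factor (default 1/10)
so a full cross-validated comparison runs at desk scale. At that scale
the smallest dataset has too few positives for 20 stratified folds, so
the benchmark uses k = min(20, smallest class count) per dataset.

What the generators deliberately do **not** emulate: covariance between
predictors, linkage disequilibrium between markers, informative
missingness, and measurement drift. Passing benchmarks on this data
therefore demonstrates correct mechanics and the expected behavior under
clean conditional-independence structure, not performance on real
clinical records.

## Numerical choices and degenerate inputs

* All marginal likelihoods in log-gamma space; no factorials.
* Candidate and variable ties: earliest in schema order (strict-greater
  scan). Pruning ties: shortest prefix.
* Mathematically tied split scores can acquire 1-ulp differences along
  different float summation routes; the oracle tests therefore validate
  greedy optimality step-by-step with a 1e-9 tolerance and demand exact
  sequence equality only on tie-free cases.
* Empty datasets: class counts (0,…,0); entropy 0; the empty conjunction
  matches everything; splitting never errors on empty sides.
* AUC with a single class raises a typed error; the growth loop and fold
  AUC catch it where the protocol defines a fallback (0.5, or skipping
  the fold with a count).
* Internal value encoding is by domain index; all user-facing output
  uses original value labels.

## Known limitations

* Only discrete predictors are modelled; continuous variables must pass
  through discretization, and binary outcomes are the tested regime
  (the estimators generalize to K > 2, the AUC machinery does not).
* The recorded-score pruning rule compares scores across nesting depths;
  see the pruning section for its consequence at small training sizes.
* The population tree is a comparator, not a tuned CART: multiway
  splits, Bayesian pruning, and majority-child missing routing are
  reasonable but not the only defensible choices.
* Per-person model derivation costs one greedy search per prediction;
  the implementation is vectorized but a large test set multiplies the
  cost accordingly.
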