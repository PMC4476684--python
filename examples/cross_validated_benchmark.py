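"""Cross-validated comparison of all four methods on one synthetic cohort.

Runs stratified 20-fold cross-validation with the three personalized
criteria (Bayesian score, information gain, LOOCV AUC) and the population
tree, then prints discrimination (AUC), calibration (1-BS, BSS) and
personalized-vs-tree disagreement.
"""

from decisionpath import (
    GeneratorSpec,
    gen_path_process,
    metric_table,
    run_cross_validation,
)

spec = GeneratorSpec.planted(n=1000, prevalence=0.2, n_signal=3, n_noise=18,
                             missing_rate=0.02, seed=5)
data, truth = gen_path_process(spec)
print(f"cohort: n={data.n_rows}, prevalence={data.y.mean():.3f}, "
      f"Bayes-optimal AUC={truth.bayes_auc:.3f}")

res = run_cross_validation(data, methods=("dp-bay", "dp-ig", "dp-auc", "tree"),
                           k=20, seed=5)
table = metric_table({"synthetic": res})
cols = ["method", "auc", "auc_lo", "auc_hi", "one_minus_bs", "bss",
        "disagree_pred"]
print("\n" + table[cols].round(3).to_string(index=False))
print("\nAUC is the across-fold mean with a t-based 95% CI; BSS compares each")
print("model's Brier score to a reference that always predicts the prevalence.")
print("No learner can exceed the Bayes-optimal AUC printed above.")
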