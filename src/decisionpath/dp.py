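"""Personalized decision-path learning: greedy growth, pruning, prediction.

For each test person a fresh model is grown lazily: starting from the empty
path, the candidate set is every predictor the person has an observed value
for; each candidate (V = person's v) is scored by how well it splits the
current matching subgroup into (DTemp, D - DTemp), the best feature is
appended, and the subgroup is restricted to DTemp.  Growth stops when no
candidates remain, the subgroup would become empty, or the remaining
individuals all share the same target value.  Pruning then truncates the
grown conjunct sequence at the step whose recorded criterion score is
maximal, and the target distribution is re-estimated (BDeu-smoothed) from
the training individuals matching the pruned path.

Three criteria are supported: ``"bay"`` (two-sample Bayesian score),
``"ig"`` (information gain) and ``"auc"`` (leave-one-out AUC).
"""

from __future__ import annotations

import numpy as np

from .core import (
    MISSING,
    DecisionPathModel,
    DiscreteDataset,
    GrowthStep,
    GrowthTrace,
    PersonInstance,
    ScoringConfig,
    class_counts,
    filter_matching,
)
from .scoring import (
    UndefinedAUCError,
    bayes_score,
    bdeu_theta,
    info_gain,
    mann_whitney_auc,
)

CRITERIA = ("bay", "ig", "auc")

__all__ = ["CRITERIA", "grow_path", "prune_path", "fit_decision_path",
           "predict_proba", "export_rule"]


def _loocv_preds_from_counts(n_pos: int, n: int, is_pos: np.ndarray,
                             pess: float, k: int) -> np.ndarray:
    """Vectorized leave-one-out BDeu prediction within one sample."""
    alpha_p = pess / k
    if n == 1:
        return np.full(1, alpha_p / pess)
    return (alpha_p + n_pos - is_pos) / (pess + n - 1)


def _score_candidate(criterion: str, y_sub: np.ndarray, in_mask: np.ndarray,
                     counts_D: np.ndarray, pos_index: int, k: int,
                     config: ScoringConfig) -> float:
    counts_in = np.bincount(y_sub[in_mask], minlength=k)
    counts_out = counts_D - counts_in
    if criterion == "bay":
        return bayes_score(counts_in, counts_out, config)
    if criterion == "ig":
        return info_gain(counts_D, counts_in, counts_out)
    if criterion == "auc":
        is_pos = (y_sub == pos_index).astype(float)
        preds = np.empty(y_sub.shape[0], dtype=float)
        n_in = int(in_mask.sum())
        n_out = y_sub.shape[0] - n_in
        if n_in:
            preds[in_mask] = _loocv_preds_from_counts(
                int(counts_in[pos_index]), n_in, is_pos[in_mask], config.pess, k)
        if n_out:
            out_mask = ~in_mask
            preds[out_mask] = _loocv_preds_from_counts(
                int(counts_out[pos_index]), n_out, is_pos[out_mask], config.pess, k)
        try:
            return mann_whitney_auc(preds, y_sub == pos_index)
        except UndefinedAUCError:
            return 0.5
    raise ValueError(f"unknown criterion {criterion!r}")


def grow_path(
    train: DiscreteDataset,
    person: PersonInstance,
    criterion: str = "bay",
    config: ScoringConfig = ScoringConfig(),
):
    """Greedy forward growth of a personalized path.

    Returns ``(trace, conjuncts)`` where ``conjuncts`` is the full grown
    path as [(variable, value), ...].  Variables missing in the test
    person are never candidates; candidates whose DTemp would be empty
    are skipped (they would strand the search with no individuals).
    """
    if criterion not in CRITERIA:
        raise ValueError(f"criterion must be one of {CRITERIA}")
    if train.n_rows == 0:
        raise ValueError("empty training set")
    trace = GrowthTrace(criterion=criterion)
    conjuncts: list = []
    k = train.n_classes
    pos = train.positive_index
    idx = np.arange(train.n_rows)
    candidates = [j for j in range(len(train.schema)) if person.codes[j] != MISSING]
    while candidates and idx.size:
        y_sub = train.y[idx]
        if (y_sub == y_sub[0]).all():
            break  # remaining individuals all share the target value
        counts_D = np.bincount(y_sub, minlength=k)
        best_j = -1
        best_score = -np.inf
        best_mask = None
        for j in candidates:  # schema order => earliest-variable tie-break
            in_mask = train.X[idx, j] == person.codes[j]
            if not in_mask.any():
                continue
            score = _score_candidate(criterion, y_sub, in_mask, counts_D, pos, k, config)
            if score > best_score:
                best_j, best_score, best_mask = j, score, in_mask
        if best_j < 0:
            break  # every candidate would empty the subgroup
        idx = idx[best_mask]
        var = train.schema[best_j]
        value = var.domain[person.codes[best_j]]
        conjuncts.append((var.name, value))
        trace.append(GrowthStep(variable=var.name, value=value,
                                score=float(best_score), n_matching=int(idx.size)))
        candidates.remove(best_j)
    return trace, conjuncts


def prune_path(trace: GrowthTrace) -> list:
    """Truncate the grown path at the step with the maximal recorded score.

    Ties break toward the shortest qualifying prefix (simpler model); an
    empty trace yields the empty path.  When growth added at least one
    feature the result is never empty — the empty path's prior score is
    not part of the trace.
    """
    if len(trace) == 0:
        return []
    best = int(np.argmax(trace.scores()))  # argmax returns the first max
    return [(s.variable, s.value) for s in trace.steps[: best + 1]]


def fit_decision_path(
    train: DiscreteDataset,
    person: PersonInstance,
    criterion: str = "bay",
    config: ScoringConfig = ScoringConfig(),
) -> DecisionPathModel:
    """Grow, prune, and parameterize a decision path for one person."""
    trace, _ = grow_path(train, person, criterion, config)
    pruned = prune_path(trace)
    match = filter_matching(train, pruned)
    counts = class_counts(match)
    return DecisionPathModel(
        path=pruned,
        theta=bdeu_theta(counts, config),
        support_counts=counts,
        trace=trace,
        target=train.target,
        positive_index=train.positive_index,
        config=config,
    )


def predict_proba(model: DecisionPathModel) -> float:
    """Probability of the positive target value, theta_p.

    Thresholding at 0.5 for a hard label is the caller's concern.
    """
    return float(model.theta[model.positive_index])


def export_rule(model: DecisionPathModel) -> str:
    """Render the model as a single IF-THEN rule.

    The antecedent lists the conjuncts in growth order ("TRUE" for the
    empty path); the consequent gives the smoothed positive-class
    probability with its supporting sample size and class counts.
    """
    if model.path:
        antecedent = " AND ".join(f"{v}={val}" for v, val in model.path)
    else:
        antecedent = "TRUE"
    p = model.theta[model.positive_index]
    pos_label = model.target.domain[model.positive_index]
    counts = "/".join(str(int(c)) for c in model.support_counts)
    n = int(model.support_counts.sum())
    return (f"IF {antecedent} THEN P({model.target.name}={pos_label})={p:.3f} "
            f"(n={n}, counts={counts})")
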