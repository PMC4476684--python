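"""Split criteria and probability estimators.

Three split criteria drive the personalized learners:

* the Bayesian score — the log marginal likelihood of the target values in
  the two subsamples induced by a candidate split, under independent
  Dirichlet-multinomial models (DP-BAY);
* information gain — parent entropy minus size-weighted child entropies,
  in bits (DP-IG);
* a leave-one-out AUC — smoothed LOOCV predictions computed within each
  subsample, pooled into a Mann-Whitney AUC (DP-AUC).

Probabilities everywhere are BDeu posterior means
``theta_k = (alpha_k + N_k) / (alpha + N)`` with uniform prior mass
``alpha_k = pess / K``; candidate splits are always scored on the pair
(DTemp, D - DTemp) so that every candidate is judged on the same set of
individuals.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.special import gammaln
from scipy.stats import rankdata

from .core import DiscreteDataset, ScoringConfig, class_counts, split_by_feature

logger = logging.getLogger(__name__)

__all__ = [
    "bdeu_theta",
    "bayes_score",
    "entropy_bits",
    "info_gain",
    "mann_whitney_auc",
    "loocv_predictions",
    "auc_criterion_score",
    "UndefinedAUCError",
]


class UndefinedAUCError(ValueError):
    """AUC requested with only one class present."""


def bdeu_theta(counts, config: ScoringConfig = ScoringConfig()) -> np.ndarray:
    """BDeu posterior-mean probability vector over target values.

    theta_k = (pess/K + N_k) / (pess + N).  With no data this is the
    uniform prior; every entry is strictly inside (0, 1) for pess > 0.
    """
    counts = np.asarray(counts, dtype=float)
    if (counts < 0).any():
        raise ValueError("negative counts")
    k = counts.shape[0]
    return (config.pess / k + counts) / (config.pess + counts.sum())


def _dirichlet_marginal(counts: np.ndarray, alpha_jk: float) -> float:
    """Log marginal likelihood of one sample's class counts.

    log [ Gamma(alpha_j)/Gamma(N_j + alpha_j) * prod_k
          Gamma(N_jk + alpha_jk)/Gamma(alpha_jk) ],  alpha_j = K * alpha_jk.
    """
    counts = np.asarray(counts, dtype=float)
    alpha_j = alpha_jk * counts.shape[0]
    return float(
        gammaln(alpha_j)
        - gammaln(counts.sum() + alpha_j)
        + (gammaln(counts + alpha_jk) - gammaln(alpha_jk)).sum()
    )


def bayes_score(counts_in, counts_out, config: ScoringConfig = ScoringConfig()) -> float:
    """Two-sample Bayesian split score (log marginal likelihood).

    Sum over the samples DTemp (``counts_in``) and D-DTemp (``counts_out``)
    of the Dirichlet-multinomial log marginal with per-class prior mass
    alpha_jk = 1/K; symmetric in its two samples.  Computed in log-gamma
    space throughout.
    """
    counts_in = np.asarray(counts_in, dtype=float)
    counts_out = np.asarray(counts_out, dtype=float)
    if (counts_in < 0).any() or (counts_out < 0).any():
        raise ValueError("negative counts")
    a = config.alpha_jk(counts_in.shape[0])
    return _dirichlet_marginal(counts_in, a) + _dirichlet_marginal(counts_out, a)


def entropy_bits(counts) -> float:
    """Shannon entropy of the class proportions, in bits; empty -> 0."""
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts[counts > 0] / n
    return float(-(p * np.log2(p)).sum())


def info_gain(counts_D, counts_in, counts_out) -> float:
    """Information gain of a binary split, in bits.

    H(D) - |DTemp|/|D| H(DTemp) - |D-DTemp|/|D| H(D-DTemp); requires the
    two parts to partition D (counts add elementwise).
    """
    counts_D = np.asarray(counts_D, dtype=float)
    counts_in = np.asarray(counts_in, dtype=float)
    counts_out = np.asarray(counts_out, dtype=float)
    if not np.array_equal(counts_in + counts_out, counts_D):
        raise ValueError("split does not partition D: counts mismatch")
    n = counts_D.sum()
    if n == 0:
        return 0.0
    gain = (
        entropy_bits(counts_D)
        - counts_in.sum() / n * entropy_bits(counts_in)
        - counts_out.sum() / n * entropy_bits(counts_out)
    )
    return float(max(gain, 0.0))  # clip tiny negative rounding


def mann_whitney_auc(scores, labels) -> float:
    """Rank-based AUC: (#concordant + 1/2 #tied) / (#pos * #neg).

    ``labels`` is boolean-like (True = positive).  Invariant under any
    strictly increasing transform of the scores; ties get half credit.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise UndefinedAUCError("AUC undefined with a single class")
    ranks = rankdata(scores)  # midranks handle ties
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def loocv_predictions(subgroup: DiscreteDataset, config: ScoringConfig = ScoringConfig()) -> np.ndarray:
    """Leave-one-out smoothed probability of the positive value, per row.

    Row i is predicted from the subgroup with row i removed:
    theta_p = (alpha_p + N_p - [y_i = p]) / (alpha + N - 1).
    A singleton subgroup falls back to the prior alpha_p / alpha.
    """
    n = subgroup.n_rows
    if n == 0:
        raise ValueError("empty subgroup")
    k = subgroup.n_classes
    counts = class_counts(subgroup)
    p = subgroup.positive_index
    alpha_k = config.pess / k
    is_pos = (subgroup.y == p).astype(float)
    if n == 1:
        return np.full(1, alpha_k / config.pess)
    return (alpha_k + counts[p] - is_pos) / (config.pess + n - 1)


def auc_criterion_score(
    data: DiscreteDataset,
    variable: str,
    value,
    config: ScoringConfig = ScoringConfig(),
) -> float:
    """LOOCV AUC criterion for a candidate split of ``data``.

    Splits on (variable, value); leave-one-out predictions are computed
    separately within DTemp and within D-DTemp, then all |D| predictions
    are pooled with the true labels into a Mann-Whitney AUC.  If the AUC
    is undefined (single class), 0.5 is returned.
    """
    d_in, d_out = split_by_feature(data, variable, value)
    preds = np.empty(data.n_rows, dtype=float)
    labels = np.empty(data.n_rows, dtype=bool)
    k = 0
    for part in (d_in, d_out):
        if part.n_rows == 0:
            continue
        preds[k : k + part.n_rows] = loocv_predictions(part, config)
        labels[k : k + part.n_rows] = part.y == part.positive_index
        k += part.n_rows
    try:
        return mann_whitney_auc(preds[:k], labels[:k])
    except UndefinedAUCError:
        logger.debug("single-class subgroup at (%s=%r); AUC set to 0.5", variable, value)
        return 0.5
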