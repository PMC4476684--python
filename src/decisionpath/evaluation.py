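"""Cross-validated evaluation protocol and performance measures.

The benchmark protocol is stratified k-fold cross-validation (k = 20 by
default): each fold preserves the positive-outcome proportion, the
population tree is fitted once per training fold, and each decision-path
method derives one personalized model per test individual, so every
individual receives exactly one prediction per method.  When continuous
predictors are present, discretization cuts are learned on the training
folds only and applied to the held-out fold (a global mode is available
for sensitivity analysis).

Metrics: Mann-Whitney AUC (per-fold mean with a t-based 95% CI, plus the
pooled-prediction AUC), the Brier score BS (reported positively oriented
as 1 - BS) and the Brier skill score BSS = 1 - BS/BS_ref, where the
reference model predicts the dataset prevalence for everyone.  Methods
are compared across datasets with a classic two-sided paired t-test, and
personalized-vs-tree disagreement is summarized either as the fraction of
individuals whose thresholded labels differ or as the fraction whose
conjunct sets differ.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from .core import DiscreteDataset, PersonInstance, ScoringConfig, class_counts
from .dp import fit_decision_path, predict_proba
from .preprocess import apply_cuts, learn_cuts
from .scoring import UndefinedAUCError, bdeu_theta, mann_whitney_auc
from .tree import TreeControls, fit_population_tree, tree_path_for_person, tree_predict_index

logger = logging.getLogger(__name__)

DP_METHODS = {"dp-bay": "bay", "dp-ig": "ig", "dp-auc": "auc"}
ALL_METHODS = tuple(DP_METHODS) + ("tree",)

__all__ = ["PredictionRecord", "CVResult", "stratified_folds",
           "run_cross_validation", "brier_metrics", "auc_with_ci",
           "paired_t_test", "disagreement_proportion", "metric_table",
           "ALL_METHODS"]


@dataclass(frozen=True)
class PredictionRecord:
    individual: int
    method: str
    fold: int
    probability: float
    is_positive: bool


@dataclass
class CVResult:
    records: list
    n_fallbacks: int
    paths: dict  # method -> {individual: frozenset of conjuncts}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.records])

    def for_method(self, method: str) -> list:
        return [r for r in self.records if r.method == method]


def stratified_folds(data: DiscreteDataset, k: int, seed: int) -> np.ndarray:
    """Fold index per row; folds preserve the class proportions.

    Deterministic given the seed.  k must not exceed the size of the
    smallest class.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    counts = class_counts(data)
    if (counts == 0).any():
        raise ValueError("both classes must be present")
    if k > counts.min():
        raise ValueError(f"k={k} exceeds smallest class count {int(counts.min())}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment = np.empty(data.n_rows, dtype=np.int32)
    for f, (_, test_idx) in enumerate(skf.split(np.zeros(data.n_rows), data.y)):
        assignment[test_idx] = f
    return assignment


def _fit_predict_fold(train, test, test_ids, fold, methods, config, records, paths):
    """One fold's predictions; returns the number of fallbacks used."""
    n_fallback = 0
    prevalence_theta = bdeu_theta(class_counts(train), config)
    fallback = float(prevalence_theta[train.positive_index])
    tree = None
    if "tree" in methods:
        tree = fit_population_tree(train, config, TreeControls())
    for row, ind in enumerate(test_ids):
        person = PersonInstance.from_row(test, row)
        truth = bool(test.y[row] == test.positive_index)
        for method in methods:
            if method == "tree":
                prob = tree_predict_index(tree, person, train.positive_index)
                paths["tree"][ind] = frozenset(tree_path_for_person(tree, person))
            else:
                try:
                    model = fit_decision_path(train, person, DP_METHODS[method], config)
                    prob = predict_proba(model)
                    paths[method][ind] = frozenset(model.path)
                except Exception:  # noqa: BLE001 — fall back, count, keep going
                    logger.exception("method %s failed on individual %d", method, ind)
                    prob = fallback
                    paths[method][ind] = frozenset()
                    n_fallback += 1
            records.append(PredictionRecord(ind, method, fold, prob, truth))
    return n_fallback


def run_cross_validation(
    data,
    methods=ALL_METHODS,
    k: int = 20,
    seed: int = 0,
    config: ScoringConfig = ScoringConfig(),
    target: str | None = None,
    positive=None,
    continuous: list | None = None,
    discretize_scope: str = "per-fold",
) -> CVResult:
    """Full cross-validated benchmark on one dataset.

    ``data`` is either an all-discrete :class:`DiscreteDataset` or a raw
    pandas frame (then ``target`` and the ``continuous`` column list are
    required and discretization is performed per fold, or once globally
    when ``discretize_scope="global"``).
    """
    for m in methods:
        if m not in ALL_METHODS:
            raise ValueError(f"unknown method {m!r}")
    records: list = []
    paths: dict = {m: {} for m in methods}
    n_fallbacks = 0

    if isinstance(data, DiscreteDataset):
        ds = data
        folds = stratified_folds(ds, k, seed)
        for f in range(k):
            test_mask = folds == f
            train = ds.subset(~test_mask)
            test = ds.subset(test_mask)
            ids = np.nonzero(test_mask)[0]
            n_fallbacks += _fit_predict_fold(train, test, ids, f, methods,
                                             config, records, paths)
        return CVResult(records, n_fallbacks, paths)

    df = data
    if target is None or continuous is None:
        raise ValueError("raw-frame input needs target and continuous columns")
    if discretize_scope not in ("per-fold", "global"):
        raise ValueError("discretize_scope must be 'per-fold' or 'global'")
    # fold assignment on the un-discretized frame (stratify on the target)
    tmask = df[target].notna().to_numpy()
    df = df.loc[tmask].reset_index(drop=True)
    y_raw = df[target].to_numpy()
    classes, y_codes = np.unique(y_raw, return_inverse=True)
    if classes.size < 2 or k > np.bincount(y_codes).min():
        raise ValueError("k exceeds smallest class count")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = np.empty(len(df), dtype=np.int32)
    for f, (_, test_idx) in enumerate(skf.split(np.zeros(len(df)), y_codes)):
        folds[test_idx] = f
    if discretize_scope == "global":
        cuts_global = learn_cuts(df, target, continuous)
    for f in range(k):
        test_mask = folds == f
        if discretize_scope == "per-fold":
            cuts = learn_cuts(df.loc[~test_mask], target, continuous)
        else:
            cuts = cuts_global
        binned = apply_cuts(df, cuts)
        ds = DiscreteDataset.from_dataframe(binned, target, positive=positive)
        train = ds.subset(~test_mask)
        test = ds.subset(test_mask)
        ids = np.nonzero(test_mask)[0]
        n_fallbacks += _fit_predict_fold(train, test, ids, f, methods,
                                         config, records, paths)
    return CVResult(records, n_fallbacks, paths)


def brier_metrics(records) -> tuple:
    """(BS, 1 - BS, BSS) for one method's prediction records.

    BS is the mean squared difference between the predicted positive
    probability and the binary outcome; the BSS reference predicts the
    records' own prevalence for everyone.
    """
    probs = np.array([r.probability for r in records], dtype=float)
    y = np.array([r.is_positive for r in records], dtype=float)
    if probs.size == 0:
        raise ValueError("no records")
    bs = float(np.mean((probs - y) ** 2))
    prevalence = float(y.mean())
    bs_ref = float(np.mean((prevalence - y) ** 2))
    bss = 1.0 - bs / bs_ref if bs_ref > 0 else 0.0
    return bs, 1.0 - bs, bss


def auc_with_ci(records, confidence: float = 0.95) -> dict:
    """Across-fold mean AUC with a t-based CI, plus the pooled AUC.

    Folds containing a single class are skipped (their count is
    reported).  The CI has zero width when the fold AUCs are constant.
    """
    by_fold: dict = {}
    for r in records:
        by_fold.setdefault(r.fold, []).append(r)
    fold_aucs, skipped = [], 0
    for f in sorted(by_fold):
        rs = by_fold[f]
        try:
            fold_aucs.append(mann_whitney_auc(
                [r.probability for r in rs], [r.is_positive for r in rs]))
        except UndefinedAUCError:
            skipped += 1
            logger.info("fold %d skipped for AUC: single class", f)
    if not fold_aucs:
        raise UndefinedAUCError("no fold with both classes")
    arr = np.asarray(fold_aucs)
    mean = float(arr.mean())
    if arr.size > 1 and arr.std(ddof=1) > 0:
        half = float(stats.t.ppf(0.5 + confidence / 2, arr.size - 1)
                     * arr.std(ddof=1) / np.sqrt(arr.size))
    else:
        half = 0.0
    pooled = mann_whitney_auc([r.probability for r in records],
                              [r.is_positive for r in records])
    return {"auc": mean, "ci": (mean - half, mean + half),
            "pooled_auc": float(pooled), "n_folds": int(arr.size),
            "n_folds_skipped": skipped}


def paired_t_test(values_a, values_b) -> dict:
    """Two-sided paired t-test on per-dataset metric pairs.

    Returns mean difference (a - b), t, df and p.  Zero-variance edge
    cases: identical pairs give p = 1.0; a constant nonzero difference
    gives p = 0.0 (t reported as signed infinity).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need >= 2 aligned pairs")
    d = a - b
    mean_d = float(d.mean())
    sd = float(d.std(ddof=1))
    n = d.size
    if sd == 0.0:
        if mean_d == 0.0:
            t, p = 0.0, 1.0
        else:
            t, p = float(np.sign(mean_d) * np.inf), 0.0
        logger.info("paired t-test: zero-variance differences (edge convention)")
    else:
        t = mean_d / (sd / np.sqrt(n))
        p = float(2 * stats.t.sf(abs(t), n - 1))
    return {"mean_difference": mean_d, "t": float(t), "df": n - 1, "p": p}


def disagreement_proportion(dp_records, tree_records, mode: str = "prediction",
                            threshold: float = 0.5,
                            dp_paths: dict | None = None,
                            tree_paths: dict | None = None) -> float:
    """Fraction of individuals where a DP method and the tree disagree.

    mode="prediction": thresholded labels differ.  mode="path": the DP
    conjunct set is not identical (as a set) to the tree routing path's
    conjunct set (pass ``dp_paths``/``tree_paths`` keyed by individual).
    """
    if mode == "path":
        if dp_paths is None or tree_paths is None:
            raise ValueError("path mode needs dp_paths and tree_paths")
        if set(dp_paths) != set(tree_paths):
            raise ValueError("misaligned individuals")
        ids = sorted(dp_paths)
        return float(np.mean([dp_paths[i] != tree_paths[i] for i in ids]))
    if mode != "prediction":
        raise ValueError("mode must be 'prediction' or 'path'")
    dp = {r.individual: r.probability for r in dp_records}
    tr = {r.individual: r.probability for r in tree_records}
    if set(dp) != set(tr):
        raise ValueError("misaligned individuals")
    ids = sorted(dp)
    dp_lab = np.array([dp[i] >= threshold for i in ids])
    tr_lab = np.array([tr[i] >= threshold for i in ids])
    return float(np.mean(dp_lab != tr_lab))


def metric_table(results: dict, methods=ALL_METHODS) -> pd.DataFrame:
    """One row per (dataset, method): AUC + CI, 1-BS, BSS, disagreement.

    ``results`` maps dataset name -> CVResult.  Disagreement columns are
    present when the tree is among the methods.
    """
    rows = []
    for name, res in results.items():
        tree_recs = res.for_method("tree") if "tree" in methods else None
        for m in methods:
            recs = res.for_method(m)
            auc = auc_with_ci(recs)
            bs, one_minus_bs, bss = brier_metrics(recs)
            row = {"dataset": name, "method": m, "auc": auc["auc"],
                   "auc_lo": auc["ci"][0], "auc_hi": auc["ci"][1],
                   "pooled_auc": auc["pooled_auc"],
                   "one_minus_bs": one_minus_bs, "bss": bss}
            if tree_recs is not None and m != "tree":
                row["disagree_pred"] = disagreement_proportion(recs, tree_recs)
                row["disagree_path"] = disagreement_proportion(
                    None, None, mode="path",
                    dp_paths=res.paths[m], tree_paths=res.paths["tree"])
            rows.append(row)
    return pd.DataFrame(rows)
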