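import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import build_dataset
from decisionpath import evaluation as ev
from decisionpath.core import class_counts
from decisionpath.evaluation import (
    PredictionRecord,
    auc_with_ci,
    brier_metrics,
    disagreement_proportion,
    paired_t_test,
    run_cross_validation,
    stratified_folds,
)


def _records(probs, truths, method="m", fold=0):
    return [PredictionRecord(i, method, fold, p, bool(t))
            for i, (p, t) in enumerate(zip(probs, truths))]


def _balanced_dataset(n=100, n_pos=20, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.integers(0, 2, (n, 3))
    y = np.zeros(n, dtype=int)
    y[:n_pos] = 1
    return build_dataset(X, y, domains=[(0, 1)] * 3)


class TestStratifiedFolds:
    def test_exact_divisibility_gives_one_positive_per_fold(self):
        ds = _balanced_dataset(100, 20)
        folds = stratified_folds(ds, 20, seed=0)
        for f in range(20):
            m = folds == f
            assert m.sum() == 5
            assert ds.y[m].sum() == 1

    def test_folds_partition_the_dataset(self):
        ds = _balanced_dataset(103, 31)
        folds = stratified_folds(ds, 10, seed=1)
        assert np.bincount(folds).sum() == 103
        assert set(folds) == set(range(10))

    def test_deterministic_per_seed(self):
        ds = _balanced_dataset(100, 30)
        a = stratified_folds(ds, 5, seed=3)
        b = stratified_folds(ds, 5, seed=3)
        c = stratified_folds(ds, 5, seed=4)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_k_exceeding_class_count_rejected(self):
        ds = _balanced_dataset(50, 3)
        with pytest.raises(ValueError):
            stratified_folds(ds, 5, seed=0)


class TestCrossValidation:
    def test_leave_one_out_emits_one_record_per_individual_per_method(self):
        ds = _balanced_dataset(10, 5, seed=2)
        res = run_cross_validation(ds, methods=("dp-bay", "tree"), k=5, seed=0)
        frame = res.to_frame()
        assert len(frame) == 20
        for m in ("dp-bay", "tree"):
            ids = sorted(r.individual for r in res.for_method(m))
            assert ids == list(range(10))

    def test_tree_fit_once_per_fold_dp_once_per_individual(self, monkeypatch):
        ds = _balanced_dataset(40, 16, seed=3)
        calls = {"tree": 0, "dp": 0}
        orig_tree = ev.fit_population_tree
        orig_dp = ev.fit_decision_path

        def count_tree(*a, **k):
            calls["tree"] += 1
            return orig_tree(*a, **k)

        def count_dp(*a, **k):
            calls["dp"] += 1
            return orig_dp(*a, **k)

        monkeypatch.setattr(ev, "fit_population_tree", count_tree)
        monkeypatch.setattr(ev, "fit_decision_path", count_dp)
        run_cross_validation(ds, methods=("dp-bay", "tree"), k=4, seed=0)
        assert calls["tree"] == 4
        assert calls["dp"] == 40

    def test_method_failure_falls_back_to_prevalence(self, monkeypatch):
        ds = _balanced_dataset(20, 8, seed=4)

        def boom(*a, **k):
            raise RuntimeError("synthetic failure")

        monkeypatch.setattr(ev, "fit_decision_path", boom)
        res = run_cross_validation(ds, methods=("dp-bay",), k=4, seed=0)
        assert res.n_fallbacks == 20
        train_prev_smoothed = {r.probability for r in res.records}
        # every prediction is a smoothed training prevalence, hence ~8/20
        assert all(abs(p - 0.4) < 0.1 for p in train_prev_smoothed)


class TestBrierMetrics:
    def test_perfect_hard_predictions(self):
        bs, one_minus, bss = brier_metrics(_records([1.0, 0.0], [1, 0]))
        assert bs == 0.0 and one_minus == 1.0

    def test_reference_model_has_zero_skill(self):
        y = [1, 0, 0, 1, 0]
        prev = np.mean(y)
        _, _, bss = brier_metrics(_records([prev] * 5, y))
        assert bss == pytest.approx(0.0, abs=1e-15)

    def test_hand_computed_example(self):
        bs, one_minus, bss = brier_metrics(_records([0.8, 0.3], [1, 0]))
        assert bs == pytest.approx(0.065, abs=1e-12)
        assert one_minus == pytest.approx(0.935, abs=1e-12)
        assert bss == pytest.approx(0.74, abs=1e-12)

    @settings(max_examples=40, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_matches_textbook_formula(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 50))
        probs = rng.random(n)
        y = rng.integers(0, 2, n)
        if len(set(y)) < 2:
            return
        bs, _, bss = brier_metrics(_records(probs, y))
        want_bs = sum((p - t) ** 2 for p, t in zip(probs, y)) / n
        prev = sum(y) / n
        want_ref = sum((prev - t) ** 2 for t in y) / n
        assert bs == pytest.approx(want_bs, abs=1e-10)
        assert bss == pytest.approx(1 - want_bs / want_ref, abs=1e-10)


class TestAucWithCI:
    def test_perfect_predictor_zero_width(self):
        recs = []
        for f in range(4):
            recs += _records([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0], fold=f)
        out = auc_with_ci(recs)
        assert out["auc"] == 1.0 and out["ci"] == (1.0, 1.0)
        assert out["pooled_auc"] == 1.0

    def test_null_predictions_near_half(self):
        rng = np.random.default_rng(0)
        n = 2000
        y = rng.random(n) < 0.3
        recs = [PredictionRecord(i, "m", i % 20, rng.random(), bool(y[i]))
                for i in range(n)]
        out = auc_with_ci(recs)
        assert 0.45 < out["auc"] < 0.55

    def test_ci_contains_mean_and_single_class_folds_skipped(self):
        recs = _records([0.9, 0.2, 0.6, 0.4], [1, 0, 1, 0], fold=0)
        recs += _records([0.5, 0.6], [1, 1], fold=1)  # single-class fold
        out = auc_with_ci(recs)
        assert out["n_folds_skipped"] == 1
        assert out["ci"][0] <= out["auc"] <= out["ci"][1]


class TestPairedTTest:
    def test_identical_pairs_edge_convention(self):
        out = paired_t_test([0.7, 0.8, 0.6], [0.7, 0.8, 0.6])
        assert out["mean_difference"] == 0.0 and out["p"] == 1.0

    def test_constant_nonzero_difference_edge(self):
        out = paired_t_test([0.8] * 7, [0.7] * 7)
        assert out["p"] == 0.0 and math.isinf(out["t"])

    @settings(max_examples=40, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_matches_textbook_formula(self, seed):
        rng = np.random.default_rng(seed)
        n = 7
        a = rng.random(n)
        b = rng.random(n)
        out = paired_t_test(a, b)
        d = a - b
        t = d.mean() / (d.std(ddof=1) / math.sqrt(n))
        assert out["t"] == pytest.approx(t, abs=1e-10)
        assert out["df"] == n - 1
        from scipy.stats import t as tdist

        assert out["p"] == pytest.approx(2 * tdist.sf(abs(t), n - 1), abs=1e-10)


class TestDisagreement:
    def test_identical_then_complementary(self):
        a = _records([0.9, 0.1, 0.8, 0.2], [1, 0, 1, 0], method="dp")
        b = _records([0.6, 0.4, 0.7, 0.3], [1, 0, 1, 0], method="tree")
        assert disagreement_proportion(a, b) == 0.0
        c = _records([0.4, 0.6, 0.3, 0.7], [1, 0, 1, 0], method="tree")
        assert disagreement_proportion(a, c) == 1.0

    def test_one_of_four_differs(self):
        a = _records([0.9, 0.1, 0.8, 0.2], [1, 0, 1, 0], method="dp")
        b = _records([0.6, 0.4, 0.7, 0.6], [1, 0, 1, 0], method="tree")
        assert disagreement_proportion(a, b) == 0.25

    def test_misaligned_ids_rejected(self):
        a = _records([0.9], [1])
        b = [PredictionRecord(99, "tree", 0, 0.5, True)]
        with pytest.raises(ValueError):
            disagreement_proportion(a, b)

    def test_path_mode_compares_conjunct_sets(self):
        dp_paths = {0: frozenset({("V1", "a")}), 1: frozenset()}
        tree_paths = {0: frozenset({("V1", "a")}), 1: frozenset({("V2", "x")})}
        got = disagreement_proportion(None, None, mode="path",
                                      dp_paths=dp_paths, tree_paths=tree_paths)
        assert got == 0.5


def test_dp_predictions_use_personal_paths_not_population_splits():
    """End-to-end: on signal data every method beats chance in a small CV."""
    rng = np.random.default_rng(9)
    n = 300
    signal = rng.integers(0, 2, n)
    X = np.column_stack([signal, rng.integers(0, 2, (n, 2))])
    y = np.where(rng.random(n) < 0.85, signal, 1 - signal)
    ds = build_dataset(X, y, domains=[(0, 1)] * 3)
    res = run_cross_validation(ds, methods=("dp-bay", "dp-ig", "tree"), k=5, seed=0)
    for m in ("dp-bay", "dp-ig", "tree"):
        assert auc_with_ci(res.for_method(m))["auc"] > 0.6
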