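import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import build_dataset
from decisionpath.core import ScoringConfig
from decisionpath.scoring import (
    UndefinedAUCError,
    auc_criterion_score,
    bayes_score,
    bdeu_theta,
    entropy_bits,
    info_gain,
    loocv_predictions,
    mann_whitney_auc,
)
from oracles import pair_counting_auc, two_sample_log_marginal, _loocv_preds


class TestBdeuTheta:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            ((0, 0), (0.5, 0.5)),
            ((40, 62), (40.5 / 103, 62.5 / 103)),
            ((28, 3), (28.5 / 32, 3.5 / 32)),
        ],
    )
    def test_posterior_mean_with_unit_pess(self, counts, expected):
        theta = bdeu_theta(np.array(counts), ScoringConfig(pess=1.0))
        assert theta == pytest.approx(expected, abs=1e-12)

    def test_strictly_interior_and_normalized(self):
        theta = bdeu_theta(np.array([0, 10_000]), ScoringConfig(pess=0.5))
        assert 0 < theta[0] < 1 and theta.sum() == pytest.approx(1.0)

    def test_converges_to_empirical_frequencies(self):
        rng = np.random.default_rng(0)
        y = rng.random(100_000) < 0.3
        counts = np.array([(~y).sum(), y.sum()])
        theta = bdeu_theta(counts, ScoringConfig(pess=1.0))
        assert theta[1] == pytest.approx(y.mean(), abs=1e-2)

    def test_large_pess_pulls_to_uniform(self):
        theta = bdeu_theta(np.array([90, 10]), ScoringConfig(pess=1e9))
        assert theta == pytest.approx((0.5, 0.5), abs=1e-6)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            bdeu_theta(np.array([-1, 2]))


class TestBayesScore:
    def test_empty_data_marginal_is_one(self):
        assert bayes_score((0, 0), (0, 0)) == pytest.approx(0.0, abs=1e-12)

    def test_single_observation_each_side(self):
        # Gamma(1.5)/Gamma(0.5) = 1/2 per sample
        assert bayes_score((1, 0), (0, 1)) == pytest.approx(2 * math.log(0.5), abs=1e-12)

    def test_symmetric_in_the_two_samples(self):
        a, b = (3, 1), (0, 5)
        assert bayes_score(a, b) == pytest.approx(bayes_score(b, a), abs=0)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            bayes_score((1, -1), (0, 0))

    @settings(max_examples=60, derandomize=True)
    @given(
        c=st.tuples(*[st.integers(0, 6)] * 4),
    )
    def test_matches_exact_dirichlet_multinomial(self, c):
        got = bayes_score((c[0], c[1]), (c[2], c[3]))
        want = two_sample_log_marginal((c[0], c[1]), (c[2], c[3]), Fraction(1, 2))
        assert got == pytest.approx(want, abs=1e-9)


class TestEntropyAndInfoGain:
    @pytest.mark.parametrize(
        "counts, expected",
        [((2, 2), 1.0), ((4, 0), 0.0), ((1, 3), 0.8112781244591328), ((0, 0), 0.0)],
    )
    def test_entropy_bits(self, counts, expected):
        assert entropy_bits(counts) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize(
        "d, cin, cout, expected",
        [
            ((2, 2), (2, 0), (0, 2), 1.0),
            ((2, 2), (1, 1), (1, 1), 0.0),
            ((3, 1), (2, 0), (1, 1), 0.8112781244591328 - 0.5),
        ],
    )
    def test_info_gain_hand_values(self, d, cin, cout, expected):
        assert info_gain(d, cin, cout) == pytest.approx(expected, abs=1e-12)

    def test_info_gain_symmetric_and_bounded(self):
        d, a, b = (5, 3), (4, 1), (1, 2)
        assert info_gain(d, a, b) == pytest.approx(info_gain(d, b, a))
        assert 0 <= info_gain(d, a, b) <= entropy_bits(d)

    def test_non_partition_rejected(self):
        with pytest.raises(ValueError):
            info_gain((2, 2), (2, 0), (1, 1))


class TestMannWhitneyAUC:
    def test_perfect_separation(self):
        assert mann_whitney_auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_all_tied_scores(self):
        assert mann_whitney_auc([0.5] * 6, [1, 0, 1, 0, 1, 0]) == 0.5

    def test_four_pair_hand_count(self):
        assert mann_whitney_auc([0.9, 0.8, 0.7, 0.6], [1, 0, 1, 0]) == 0.75

    def test_single_class_is_undefined(self):
        with pytest.raises(UndefinedAUCError):
            mann_whitney_auc([0.1, 0.2], [1, 1])

    @settings(max_examples=50, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_complement_and_shift_invariance(self, seed):
        rng = np.random.default_rng(seed)
        s = rng.permutation(np.linspace(0, 1, 12))  # tie-free
        y = np.r_[np.ones(5, bool), np.zeros(7, bool)]
        auc = mann_whitney_auc(s, y)
        assert auc + mann_whitney_auc(-s, y) == pytest.approx(1.0)
        assert mann_whitney_auc(s + 3.7, y) == pytest.approx(auc)
        assert auc == pytest.approx(pair_counting_auc(s, y))


class TestLoocv:
    def test_singleton_falls_back_to_prior(self):
        ds = build_dataset([[0]], [1], domains=[(0, 1)])
        assert loocv_predictions(ds) == pytest.approx([0.5])

    def test_two_row_anticorrelation(self):
        ds = build_dataset([[0], [0]], [0, 1], domains=[(0, 1)])
        preds = loocv_predictions(ds)
        # positive row predicted from (1 neg, 0 pos): 0.25; negative row 0.75
        assert preds[ds.y == 1] == pytest.approx([0.25])
        assert preds[ds.y == 0] == pytest.approx([0.75])

    @pytest.mark.parametrize("n", [2, 5, 9])
    def test_all_positive_closed_form(self, n):
        ds = build_dataset([[0]] * n, [1] * n, domains=[(0, 1)])
        assert loocv_predictions(ds) == pytest.approx([(0.5 + n - 1) / n] * n)

    @settings(max_examples=30, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_matches_materialized_tables(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 10))
        y = rng.integers(0, 2, n)
        ds = build_dataset([[0]] * n, y, domains=[(0, 1)])
        want = _loocv_preds(list(map(int, y)), pos=1)
        assert loocv_predictions(ds) == pytest.approx(want, abs=1e-12)


class TestAucCriterion:
    def test_degenerate_split_equals_within_d_auc(self):
        # V1 constant 0: splitting on V1=1 leaves DTemp empty
        ds = build_dataset([[0], [0], [0], [0]], [1, 1, 0, 0], domains=[(0, 1)])
        score = auc_criterion_score(ds, "V1", 1)
        preds = loocv_predictions(ds)
        assert score == pytest.approx(mann_whitney_auc(preds, ds.y == 1))

    def test_perfect_binary_predictor_scores_one(self):
        ds = build_dataset([[1], [1], [0], [0]], [1, 1, 0, 0], domains=[(0, 1)])
        assert auc_criterion_score(ds, "V1", 1) == 1.0

    @settings(max_examples=25, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_matches_quadratic_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 12))
        col = rng.integers(0, 2, n)
        y = rng.integers(0, 2, n)
        ds = build_dataset(col.reshape(-1, 1), y, domains=[(0, 1)])
        inside = [int(y[i]) for i in range(n) if col[i] == 1]
        outside = [int(y[i]) for i in range(n) if col[i] != 1]
        preds, labels = [], []
        for part in (inside, outside):
            if part:
                preds += _loocv_preds(part, 1)
                labels += [v == 1 for v in part]
        if any(labels) and not all(labels):
            want = pair_counting_auc(preds, labels)
        else:
            want = 0.5
        assert auc_criterion_score(ds, "V1", 1) == pytest.approx(want, abs=1e-12)
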