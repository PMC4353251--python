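"""Confusion accounting, edge-corrected d-prime, nulls, and aggregation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from pbci.evaluation import (
    ConfusionMatrix,
    balanced_permutation,
    compare_to_null,
    confusion,
    d_prime,
    empirical_null,
    median_over_folds,
    run_kfold,
    tpr_fpr,
)
from pbci.evaluation import PerformanceRecord
from pbci.learning import FoldSpec


H, L = 1, 0


class TestConfusion:
    def test_perfect_agreement(self):
        cm = confusion([H, H, L, L], [H, H, L, L])
        assert (cm.tp, cm.tn, cm.fp, cm.fn) == (2, 2, 0, 0)

    def test_all_high_predictions(self):
        y = np.repeat([H, L], 50)
        cm = confusion(y, np.full(100, H))
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (50, 50, 0, 0)

    def test_hand_counted_toy(self):
        cm = confusion([H, H, H, L, L, L], [H, L, H, L, L, H])
        assert (cm.tp, cm.fn, cm.fp, cm.tn) == (2, 1, 1, 2)

    def test_counts_sum_to_epochs(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 40)
        p = rng.integers(0, 2, 40)
        assert confusion(y, p).n == 40

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion([H, L], [H])


class TestTprFpr:
    def test_zero_tp_branch(self):
        tpr, _ = tpr_fpr(ConfusionMatrix(tp=0, fn=100, fp=10, tn=90))
        assert tpr == 0.01

    def test_zero_fn_branch(self):
        tpr, _ = tpr_fpr(ConfusionMatrix(tp=100, fn=0, fp=10, tn=90))
        assert tpr == 0.99

    def test_ordinary_branch(self):
        tpr, fpr = tpr_fpr(ConfusionMatrix(tp=90, fn=10, fp=20, tn=80))
        assert (tpr, fpr) == (0.9, 0.2)

    def test_zero_tn_branch_for_fpr(self):
        _, fpr = tpr_fpr(ConfusionMatrix(tp=50, fn=50, fp=100, tn=0))
        assert fpr == 0.99

    @given(
        tp=st.integers(0, 200),
        fn=st.integers(0, 200),
        fp=st.integers(0, 200),
        tn=st.integers(0, 200),
    )
    @settings(max_examples=200, deadline=None)
    def test_rates_strictly_inside_unit_interval(self, tp, fn, fp, tn):
        if tp + fn < 1 or fp + tn < 1:
            return
        tpr, fpr = tpr_fpr(ConfusionMatrix(tp, fn, fp, tn))
        assert 0.0 < tpr < 1.0
        assert 0.0 < fpr < 1.0

    def test_empty_truth_class_rejected(self):
        with pytest.raises(ValueError):
            tpr_fpr(ConfusionMatrix(tp=0, fn=0, fp=5, tn=5))


class TestDPrime:
    def test_zero_when_rates_equal(self):
        assert d_prime(ConfusionMatrix(tp=30, fn=70, fp=30, tn=70)) == pytest.approx(0.0)

    def test_oracle_value_ordinary(self):
        # Phi^-1(0.9) - Phi^-1(0.2)
        assert d_prime(ConfusionMatrix(tp=90, fn=10, fp=20, tn=80)) == pytest.approx(
            2.1232, abs=1e-3
        )

    def test_oracle_value_perfect_matrix(self):
        # edge-corrected rates 0.99 / 0.01
        assert d_prime(ConfusionMatrix(tp=100, fn=0, fp=0, tn=100)) == pytest.approx(
            4.6527, abs=1e-3
        )

    def test_finite_everywhere(self):
        for cm in (
            ConfusionMatrix(0, 10, 0, 10),
            ConfusionMatrix(10, 0, 10, 0),
            ConfusionMatrix(1, 1, 1, 1),
        ):
            assert np.isfinite(d_prime(cm))

    def test_monotone_in_tp(self):
        vals = [
            d_prime(ConfusionMatrix(tp=tp, fn=100 - tp, fp=20, tn=80))
            for tp in range(0, 101, 5)
        ]
        assert (np.diff(vals) >= 0).all()

    def test_antisymmetric_under_positive_class_swap(self):
        """Designating the other truth class as positive, with the detection
        response fixed, swaps TPR and FPR and so negates d'."""
        cm = ConfusionMatrix(tp=80, fn=20, fp=30, tn=70)
        swapped = ConfusionMatrix(tp=cm.fp, fn=cm.tn, fp=cm.tp, tn=cm.fn)
        assert d_prime(swapped) == pytest.approx(-d_prime(cm))


@pytest.fixture(scope="module")
def separable_sessions():
    rng = np.random.default_rng(9)
    n = 150  # per class per session

    def session(shift=0.0):
        x = np.vstack(
            [
                rng.normal(-2.0 + shift, 1.0, size=(n, 6)),
                rng.normal(2.0 + shift, 1.0, size=(n, 6)),
            ]
        )
        y = np.repeat([0, 1], n)
        perm = rng.permutation(2 * n)
        return x[perm], y[perm]

    return session(), session(0.2)


class TestEmpiricalNull:

    def test_null_accuracy_tightly_bounded_around_chance(self, separable_sessions):
        (x1, y1), (x2, y2) = separable_sessions
        spec = FoldSpec(k=10, seed=0)
        recs = empirical_null(x1, y1, x2, y2, spec, "LDA", seed=3)
        accs = [r.accuracy for r in recs]
        assert all(0.4 <= a <= 0.6 for a in accs)
        assert all(r.null_flag for r in recs)

    def test_true_labels_beat_matched_null(self, separable_sessions):
        (x1, y1), (x2, y2) = separable_sessions
        spec = FoldSpec(k=10, seed=0)
        from pbci.learning import make_folds

        folds = make_folds(y1, spec)
        true = run_kfold(x1, y1, x2, y2, spec, "LDA", seed=1, folds=folds)
        null = empirical_null(x1, y1, x2, y2, spec, "LDA", seed=2, folds=folds)
        for t, n0 in zip(true, null):
            assert t.d_prime > n0.d_prime

    def test_unbalanced_labels_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            balanced_permutation(np.array([0, 0, 0, 1]), rng)

    def test_null_mean_d_prime_near_zero_many_folds(self):
        """Across 20 seeded label-independent problems x k=10, the null
        d-prime mean sits within 0.1 of 0."""
        rng = np.random.default_rng(1)
        vals = []
        for rep in range(20):
            n = 60
            x1 = rng.standard_normal((2 * n, 5))
            y1 = np.repeat([0, 1], n)
            x2 = rng.standard_normal((2 * n, 5))
            y2 = np.repeat([0, 1], n)
            recs = empirical_null(
                x1, y1, x2, y2, FoldSpec(k=10, seed=rep), "LDA", seed=100 + rep
            )
            vals.extend(r.d_prime for r in recs)
        assert abs(np.mean(vals)) < 0.1


class TestAggregation:
    def test_median_is_outlier_robust(self):
        recs = [
            PerformanceRecord(accuracy=0.9, d_prime=d, fold=i, kind="LDA")
            for i, d in enumerate([1, 2, 3, 4, 100])
        ]
        assert median_over_folds(recs)["d_prime"] == 3.0

    def test_single_fold_is_itself(self):
        recs = [PerformanceRecord(accuracy=0.8, d_prime=1.5, fold=0, kind="LDA")]
        assert median_over_folds(recs) == {"accuracy": 0.8, "d_prime": 1.5}

    def test_even_count_midpoint(self):
        recs = [
            PerformanceRecord(accuracy=0.5, d_prime=d, fold=i, kind="LDA")
            for i, d in enumerate([1, 2, 3, 4])
        ]
        assert median_over_folds(recs)["d_prime"] == 2.5

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            median_over_folds([])


class TestCompareToNull:
    def test_identical_vectors_non_significant(self):
        v = np.array([1.0, 2.0, 3.0, 4.0])
        res = compare_to_null(v, v)
        assert res["t"] == 0.0 and not res["significant"]

    def test_constant_shift_zero_noise_significant(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        res = compare_to_null(a + 1.0, a)
        assert res["significant"]

    def test_matches_textbook_paired_t(self):
        a = np.array([2.1, 2.5, 1.9, 2.8, 2.4])
        b = np.array([0.1, -0.2, 0.05, 0.0, 0.15])
        res = compare_to_null(a, b)
        d = a - b
        t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        assert res["t"] == pytest.approx(t_hand)
        assert res["p"] == pytest.approx(
            2 * stats.t.sf(abs(t_hand), len(d) - 1)
        )

    def test_bonferroni_adjusts_threshold(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        res = compare_to_null(a, a * 0 + 0.1, alpha=0.01, m_comparisons=4)
        assert res["alpha_adjusted"] == pytest.approx(0.0025)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            compare_to_null(np.zeros(4), np.zeros(5))
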