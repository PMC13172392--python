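"""Statistical operations against hand-computed values, printed worked
examples, and independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import cohen_kappa_score

import tissuebench.comparison_stats as cs
from tissuebench.core import InvalidSpecError, TissueMask


def mask(arr):
    return TissueMask(np.asarray(arr, bool))


class TestPixelMetrics:
    def test_perfect_prediction(self):
        m = mask(np.eye(5))
        pm = cs.pixel_metrics(m, m)
        assert (pm.sensitivity, pm.precision) == (1.0, 1.0)
        assert not pm.undefined_precision_flag

    def test_partial_overlap_counts(self):
        truth = np.zeros((5, 5), bool)
        truth.ravel()[:10] = True
        pred = np.zeros((5, 5), bool)
        pred.ravel()[2:12] = True  # 8 TP, 2 FP, 2 FN
        pm = cs.pixel_metrics(mask(pred), mask(truth))
        assert pm.sensitivity == pytest.approx(0.8)
        assert pm.precision == pytest.approx(0.8)

    def test_empty_prediction_flags_undefined_precision(self):
        truth = np.ones((4, 4), bool)
        pm = cs.pixel_metrics(mask(np.zeros((4, 4))), mask(truth))
        assert pm.sensitivity == 0.0
        assert np.isnan(pm.precision)
        assert pm.undefined_precision_flag

    def test_dim_mismatch_rejected(self):
        with pytest.raises(InvalidSpecError):
            cs.pixel_metrics(mask(np.zeros((3, 3))), mask(np.zeros((4, 4))))


class TestClopperPearson:
    @pytest.mark.parametrize("k,n,rate,lo,hi", [
        (24, 27272, 0.088, 0.056, 0.131),
        (138, 27272, 0.506, 0.425, 0.598),
    ])
    def test_failure_rate_intervals(self, k, n, rate, lo, hi):
        """Printed failure rates and exact 95% CIs, in percent to 3 dp."""
        ci = cs.clopper_pearson(k, n)
        assert round(100 * ci.rate, 3) == rate
        assert round(100 * ci.lower, 3) == lo
        assert round(100 * ci.upper, 3) == hi

    def test_zero_successes_boundary(self):
        ci = cs.clopper_pearson(0, 10)
        assert ci.lower == 0.0
        assert 0.0 < ci.upper < 1.0

    def test_interval_brackets_rate(self):
        for k, n in [(1, 7), (5, 10), (10, 10)]:
            ci = cs.clopper_pearson(k, n)
            assert ci.lower <= k / n <= ci.upper


class TestMcNemar:
    def test_table2_discordant_pairs_below_printed_bound(self):
        assert cs.mcnemar_exact(2, 116) < 1e-10
        assert cs.mcnemar_exact(2, 116, mode="chi2") < 1e-10

    def test_no_discordance_convention(self):
        assert cs.mcnemar_exact(0, 0) == 1.0

    def test_hand_computed_binomial_sum(self):
        # 2 * P(X <= 1 | n=6, p=1/2) = 2 * 7/64
        assert cs.mcnemar_exact(1, 5) == pytest.approx(14 / 64)

    def test_agrees_with_statsmodels(self):
        from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar
        for b, c in [(3, 9), (10, 4), (1, 1)]:
            table = [[0, b], [c, 0]]
            expect = sm_mcnemar(table, exact=True).pvalue
            assert cs.mcnemar_exact(b, c) == pytest.approx(expect, abs=1e-12)


class TestQuadraticWeightedKappa:
    def test_identical_vectors(self):
        assert cs.quadratic_weighted_kappa([0, 3, 5, 1], [0, 3, 5, 1]) == 1.0

    def test_hand_computed_two_category_example(self):
        k = cs.quadratic_weighted_kappa([0, 0, 1, 1], [0, 1, 1, 1], categories=(0, 1))
        assert k == pytest.approx(0.5)

    def test_matches_sklearn_oracle_on_random_vectors(self):
        rng = np.random.default_rng(12)
        for _ in range(5):
            ref = rng.integers(0, 6, 200)
            pred = rng.integers(0, 6, 200)
            ours = cs.quadratic_weighted_kappa(ref, pred)
            oracle = cohen_kappa_score(ref, pred, weights="quadratic",
                                       labels=list(range(6)))
            assert ours == pytest.approx(oracle, abs=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_symmetric_and_permutation_invariant(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 50))
        a = rng.integers(0, 6, n)
        b = rng.integers(0, 6, n)
        k = cs.quadratic_weighted_kappa(a, b)
        assert k == pytest.approx(cs.quadratic_weighted_kappa(b, a), abs=1e-12)
        perm = rng.permutation(n)
        assert k == pytest.approx(cs.quadratic_weighted_kappa(a[perm], b[perm]), abs=1e-12)
        assert -1.0 <= k <= 1.0 + 1e-12

    def test_independent_uniform_predictions_near_zero(self):
        rng = np.random.default_rng(77)
        ks = [cs.quadratic_weighted_kappa(rng.integers(0, 6, 400),
                                          rng.integers(0, 6, 400))
              for _ in range(50)]
        assert abs(np.mean(ks)) < 0.02

    def test_constant_equal_vectors_convention_and_short_input(self):
        assert cs.quadratic_weighted_kappa([2, 2, 2], [2, 2, 2]) == 1.0
        with pytest.raises(InvalidSpecError):
            cs.quadratic_weighted_kappa([1], [1])


class TestBootstrap:
    def test_constant_statistic_degenerate_interval(self):
        (lo, hi), _ = cs.bootstrap_ci(lambda c: 3.14, list(range(10)), 100, seed=0)
        assert lo == hi == 3.14

    def test_seeded_reproducibility(self):
        cases = list(np.random.default_rng(0).normal(size=60))
        a = cs.bootstrap_ci(np.mean, cases, 200, seed=5)
        b = cs.bootstrap_ci(np.mean, cases, 200, seed=5)
        assert a == b

    def test_coverage_of_the_mean(self):
        """Percentile bootstrap of the mean of n=100 standard normals:
        empirical 95% coverage within +/- 4 points over 200 repetitions."""
        rng = np.random.default_rng(42)
        hits = 0
        reps = 200
        for i in range(reps):
            sample = rng.standard_normal(100)
            (lo, hi), _ = cs.bootstrap_ci(
                lambda c: float(np.mean(c.astype(float))), sample, 1000, seed=i)
            hits += lo <= 0.0 <= hi
        assert abs(hits / reps - 0.95) <= 0.04

    def test_kappa_with_ci_contains_point_and_reproduces(self):
        rng = np.random.default_rng(3)
        ref = rng.integers(0, 6, 80)
        pred = np.where(rng.random(80) < 0.8, ref, rng.integers(0, 6, 80))
        r1 = cs.kappa_with_ci(ref, pred, replicates=300, seed=9)
        r2 = cs.kappa_with_ci(ref, pred, replicates=300, seed=9)
        assert r1 == r2
        assert r1.ci[0] <= r1.point <= r1.ci[1]
        assert r1.replicates == 300


class TestPairedFailures:
    def test_table2_totals_row(self):
        """AI-only 2, thresholding-only 116, both 22 of 27,272 slides:
        24 and 138 per-method failures, 140 exclusions."""
        table = cs.PairedFailureTable(a_only=2, b_only=116, both=22, total=27272)
        fa = cs.failure_analysis_from_counts(table)
        assert fa.table.a_failures == 24
        assert fa.table.b_failures == 138
        assert fa.table.excluded == 140
        assert fa.a_ci.k == 24 and fa.b_ci.k == 138
        assert fa.mcnemar_p < 1e-10

    def test_no_failures(self):
        fa = cs.paired_failure_analysis({"s1": False, "s2": False},
                                        {"s1": False, "s2": False})
        assert fa.table.excluded == 0
        assert fa.mcnemar_p == 1.0

    def test_random_assignment_recount_oracle(self):
        rng = np.random.default_rng(8)
        slides = [f"s{i}" for i in range(300)]
        fa_map = {s: bool(rng.random() < 0.1) for s in slides}
        fb_map = {s: bool(rng.random() < 0.2) for s in slides}
        fa = cs.paired_failure_analysis(fa_map, fb_map)
        assert fa.table.a_failures == sum(fa_map.values())
        assert fa.table.b_failures == sum(fb_map.values())
        assert fa.table.both == sum(fa_map[s] and fb_map[s] for s in slides)
        assert fa.table.total == 300

    def test_mismatched_slide_sets_rejected(self):
        with pytest.raises(InvalidSpecError):
            cs.paired_failure_analysis({"a": True}, {"b": True})


class TestDiscordance:
    def test_identical_predictions(self):
        d = cs.discordance([1, 2, 0], [1, 2, 0], [1, 2, 0])
        assert d.n_discordant == 0
        assert d.confusion.sum() == 0

    def test_hand_enumerated_directions(self):
        d = cs.discordance([1, 2, 0], [1, 3, 2], [1, 3, 0])
        assert d.n_discordant == 2
        assert d.n_malignant == 2
        assert d.n_malignant_discordant == 1   # case 3 is benign by reference
        assert d.b_correct_only == 1           # case 2: B hits ref grade 3
        assert d.a_correct_only == 0 and d.neither_correct == 0
        assert d.confusion[2, 3] == 1 and d.confusion[0, 2] == 1
        assert np.trace(d.confusion) == 0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_direction_counts_conserve(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 60))
        a = rng.integers(0, 6, n)
        b = rng.integers(0, 6, n)
        ref = rng.integers(0, 6, n)
        d = cs.discordance(a, b, ref)
        assert (d.a_correct_only + d.b_correct_only + d.neither_correct
                == d.n_malignant_discordant)
        assert d.confusion.sum() == d.n_discordant
        assert np.trace(d.confusion) == 0


class TestBinaryScreen:
    def test_perfect(self):
        assert cs.binary_screen_metrics([1, 0, 1], [1, 0, 1]) == (1.0, 1.0)

    def test_direct_counts(self):
        ref = [True] * 10 + [False] * 20
        pred = [True] * 9 + [False] + [False] * 18 + [True] * 2
        sens, spec = cs.binary_screen_metrics(ref, pred)
        assert sens == pytest.approx(0.9)
        assert spec == pytest.approx(0.9)

    def test_all_malignant_cohort_has_undefined_specificity(self):
        sens, spec = cs.binary_screen_metrics([1, 1, 1], [1, 0, 1])
        assert sens == pytest.approx(2 / 3)
        assert np.isnan(spec)

    def test_all_benign_cohort_has_undefined_sensitivity(self):
        sens, spec = cs.binary_screen_metrics([0, 0], [0, 1])
        assert np.isnan(sens)
        assert spec == pytest.approx(0.5)
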