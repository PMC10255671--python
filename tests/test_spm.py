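import itertools
import math

import numpy as np
import pytest
from scipy import stats as st

from strokemetrics.config import SnpmConfig
from strokemetrics.spm import (GroupCurves, compare_scalars, lilliefors_test,
                               player_mean_curve, snpm_paired,
                               snpm_two_sample, spm_parametric_field)

from conftest import smooth_gaussian_curves

GRID = np.linspace(-1.0, 1.0, 51)


# --------------------------------------------------------------------------
# independent brute-force oracles

def oracle_threshold(null_values, alpha):
    """Conservative (1−α) quantile of a permutation null: the smallest
    value whose upper-tail count (ties merged at 1e-9 relative) is at most
    floor(αN)."""
    s = np.sort(np.asarray(null_values, dtype=float))
    k = math.floor(alpha * s.size)
    if k < 1:
        return float("inf")
    for v in s:
        if (s >= v - 1e-9 * (1 + abs(v))).sum() <= k:
            return float(v)
    return float("inf")


def brute_force_two_sample_null(A, B):
    X = np.vstack([A, B])
    n_a = A.shape[0]
    out = []
    for combo in itertools.combinations(range(X.shape[0]), n_a):
        ia = list(combo)
        ib = [i for i in range(X.shape[0]) if i not in combo]
        t = st.ttest_ind(X[ia], X[ib], axis=0).statistic
        out.append(np.abs(t).max())
    return out


def brute_force_paired_null(A, B):
    D = A - B
    out = []
    for signs in itertools.product((1.0, -1.0), repeat=D.shape[0]):
        t = st.ttest_1samp(D * np.array(signs)[:, None], 0.0, axis=0).statistic
        out.append(np.abs(t).max())
    return out


# --------------------------------------------------------------------------

class TestPlayerMeanCurve:
    class _Stroke:
        def __init__(self, values):
            self.time = GRID
            self.values = np.asarray(values, dtype=float)

    def test_single_stroke_mean_is_stroke_sd_zero(self):
        s = self._Stroke(np.sin(GRID))
        mean, sd = player_mean_curve([s], "values")
        np.testing.assert_allclose(mean, s.values)
        np.testing.assert_allclose(sd, 0.0)

    def test_two_strokes_sample_sd(self):
        a = self._Stroke(np.full(51, 1.0))
        b = self._Stroke(np.full(51, 3.0))
        mean, sd = player_mean_curve([a, b], "values")
        np.testing.assert_allclose(mean, 2.0)
        np.testing.assert_allclose(sd, np.sqrt(2.0))

    def test_identical_strokes_zero_sd(self):
        s = [self._Stroke(np.cos(GRID)) for _ in range(4)]
        _, sd = player_mean_curve(s, "values")
        np.testing.assert_allclose(sd, 0.0)

    def test_grid_mismatch_rejected(self):
        a = self._Stroke(np.zeros(51))
        b = self._Stroke(np.zeros(51))
        b.time = GRID + 0.5
        with pytest.raises(ValueError, match="grid"):
            player_mean_curve([a, b], "values")


class TestTwoSampleSnpm:
    def test_exhaustive_threshold_matches_brute_force(self):
        rng = np.random.default_rng(42)
        A = rng.standard_normal((3, 51))
        B = rng.standard_normal((3, 51)) + 0.5
        for alpha in (0.05, 0.2):
            res = snpm_two_sample(GroupCurves(GRID, A), GroupCurves(GRID, B),
                                  SnpmConfig(alpha=alpha))
            assert res.exhaustive
            assert res.n_permutations_used == 20
            expected = oracle_threshold(brute_force_two_sample_null(A, B), alpha)
            if math.isinf(expected):
                assert math.isinf(res.critical_t)
            else:
                assert res.critical_t == pytest.approx(expected, rel=1e-9)

    def test_injected_offset_recovered_as_cluster(self):
        """A step offset confined to [0.1, 0.3] s, large against the noise,
        yields a cluster overlapping that interval with direction A>B."""
        rng = np.random.default_rng(3)
        grid = np.linspace(-1.0, 1.0, 101)
        A = smooth_gaussian_curves(rng, 10, 101)
        B = smooth_gaussian_curves(rng, 10, 101)
        A[:, (grid >= 0.1) & (grid <= 0.3)] += 8.0
        res = snpm_two_sample(GroupCurves(grid, A), GroupCurves(grid, B),
                              SnpmConfig(n_permutations=1000, seed=0))
        assert res.significant
        overlapping = [c for c in res.clusters
                       if c[0] <= 0.3 and c[1] >= 0.1 and c[2] == "A>B"]
        assert overlapping

    def test_sign_convention_swaps_with_input_order(self):
        rng = np.random.default_rng(9)
        A = smooth_gaussian_curves(rng, 6, 51) + 1.0
        B = smooth_gaussian_curves(rng, 6, 51)
        cfg = SnpmConfig(n_permutations=500, seed=1)
        ab = snpm_two_sample(GroupCurves(GRID, A), GroupCurves(GRID, B), cfg)
        ba = snpm_two_sample(GroupCurves(GRID, B), GroupCurves(GRID, A), cfg)
        np.testing.assert_allclose(ba.t_field, -ab.t_field, atol=1e-9)
        flipped = {"A>B": "B>A", "B>A": "A>B"}
        assert [d for *_, d in ba.clusters] == [flipped[d] for *_, d in ab.clusters]

    def test_alpha_monotonicity(self):
        rng = np.random.default_rng(5)
        A = smooth_gaussian_curves(rng, 8, 51)
        B = smooth_gaussian_curves(rng, 8, 51)
        c05 = snpm_two_sample(GroupCurves(GRID, A), GroupCurves(GRID, B),
                              SnpmConfig(alpha=0.05, n_permutations=1000, seed=2))
        c01 = snpm_two_sample(GroupCurves(GRID, A), GroupCurves(GRID, B),
                              SnpmConfig(alpha=0.01, n_permutations=1000, seed=2))
        assert c01.critical_t >= c05.critical_t

    def test_too_few_curves_rejected(self):
        A = np.zeros((1, 51))
        B = np.zeros((3, 51))
        with pytest.raises(ValueError, match="2 curves"):
            snpm_two_sample(GroupCurves(GRID, A), GroupCurves(GRID, B))


class TestPairedSnpm:
    def test_identical_conditions_give_flat_zero_field(self):
        rng = np.random.default_rng(1)
        A = rng.standard_normal((5, 51))
        res = snpm_paired(GroupCurves(GRID, A), GroupCurves(GRID, A.copy()),
                          SnpmConfig())
        np.testing.assert_allclose(res.t_field, 0.0)
        assert res.clusters == []

    def test_exhaustive_threshold_matches_brute_force(self):
        rng = np.random.default_rng(8)
        A = rng.standard_normal((4, 51))
        B = A + 0.3 + 0.2 * rng.standard_normal((4, 51))
        for alpha in (0.05, 0.2):
            res = snpm_paired(GroupCurves(GRID, A), GroupCurves(GRID, B),
                              SnpmConfig(alpha=alpha))
            assert res.exhaustive
            assert res.n_permutations_used == 16
            expected = oracle_threshold(brute_force_paired_null(A, B), alpha)
            if math.isinf(expected):
                assert math.isinf(res.critical_t)
            else:
                assert res.critical_t == pytest.approx(expected, rel=1e-9)

    def test_constant_shift_spans_full_grid(self):
        """A constant offset added to condition B for every player produces
        one cluster spanning the whole grid with direction B>A."""
        rng = np.random.default_rng(12)
        A = smooth_gaussian_curves(rng, 10, 51)
        B = A + 5.0 + 0.1 * smooth_gaussian_curves(rng, 10, 51)
        res = snpm_paired(GroupCurves(GRID, A), GroupCurves(GRID, B),
                          SnpmConfig())
        assert res.exhaustive   # 2^10 = 1024 sign patterns enumerated
        assert len(res.clusters) == 1
        (c0, c1, direction) = res.clusters[0]
        assert direction == "B>A"
        assert c0 == GRID[0] and c1 == GRID[-1]

    def test_unmatched_players_rejected(self):
        A = np.zeros((4, 51))
        B = np.zeros((5, 51))
        with pytest.raises(ValueError, match="matched"):
            snpm_paired(GroupCurves(GRID, A), GroupCurves(GRID, B))


class TestFwerCalibration:
    def test_null_cluster_rate_at_most_alpha(self):
        """Empirical familywise false-positive rate over seeded null
        cohorts stays within binomial noise of α = 0.05."""
        n_rep = 120
        hits = 0
        grid = np.linspace(-1.0, 1.0, 101)
        for i in range(n_rep):
            rng = np.random.default_rng(5000 + i)
            X = smooth_gaussian_curves(rng, 16, 101)
            res = snpm_two_sample(GroupCurves(grid, X[:8]),
                                  GroupCurves(grid, X[8:]),
                                  SnpmConfig(n_permutations=600, seed=i))
            hits += res.significant
        rate = hits / n_rep
        assert rate <= 0.05 + 2 * math.sqrt(0.05 * 0.95 / n_rep)


class TestParametricField:
    def test_same_t_field_as_nonparametric(self):
        rng = np.random.default_rng(2)
        A = smooth_gaussian_curves(rng, 8, 51)
        B = smooth_gaussian_curves(rng, 8, 51)
        res_np = snpm_two_sample(GroupCurves(GRID, A), GroupCurves(GRID, B),
                                 SnpmConfig(n_permutations=300, seed=0))
        res_p = spm_parametric_field(GroupCurves(GRID, A), GroupCurves(GRID, B))
        np.testing.assert_allclose(res_p.t_field, res_np.t_field, atol=1e-9)

    def test_masks_agree_on_smooth_gaussian_null(self):
        """On smooth Gaussian null data the parametric and non-parametric
        significance masks coincide in at least 95% of replicates."""
        agree = 0
        n_rep = 40
        grid = np.linspace(-1.0, 1.0, 101)
        for i in range(n_rep):
            rng = np.random.default_rng(900 + i)
            X = smooth_gaussian_curves(rng, 20, 101)
            a = GroupCurves(grid, X[:10])
            b = GroupCurves(grid, X[10:])
            res_np = snpm_two_sample(a, b, SnpmConfig(n_permutations=500, seed=i))
            res_p = spm_parametric_field(a, b)
            mask_np = np.abs(res_np.t_field) >= res_np.critical_t
            mask_p = np.abs(res_p.t_field) >= res_p.critical_t
            agree += np.array_equal(mask_np, mask_p)
        assert agree / n_rep >= 0.95

    def test_thresholds_converge_on_gaussian_data(self):
        """With 20 smooth Gaussian curves per group the permutation
        threshold approaches the random-field-theory threshold."""
        rng = np.random.default_rng(77)
        grid = np.linspace(-1.0, 1.0, 101)
        X = smooth_gaussian_curves(rng, 40, 101)
        a = GroupCurves(grid, X[:20])
        b = GroupCurves(grid, X[20:])
        res_np = snpm_two_sample(a, b, SnpmConfig(n_permutations=10_000, seed=0))
        res_p = spm_parametric_field(a, b)
        gap = abs(res_np.critical_t - res_p.critical_t) / res_p.critical_t
        assert gap <= 0.10


class TestLilliefors:
    def test_statistic_matches_statsmodels(self):
        """The KS distance agrees with the reference implementation; the
        Monte-Carlo p-value agrees with its table-based p to sampling
        error."""
        from statsmodels.stats.diagnostic import lilliefors as sm_lilliefors
        rng = np.random.default_rng(0)
        x = rng.gamma(2.0, size=60)
        d, p = lilliefors_test(x, n_mc=4000, seed=1)
        d_sm, p_sm = sm_lilliefors(x, dist="norm")
        assert d == pytest.approx(d_sm, abs=1e-12)
        assert p == pytest.approx(p_sm, abs=0.05)

    def test_uniform_samples_rejected(self):
        """Lilliefors has high power against uniform data at n = 200:
        every replicate rejects at the 5% level and most at the 1% level
        (matching the power of the reference implementation)."""
        p_values = []
        for i in range(10):
            rng = np.random.default_rng(40 + i)
            x = rng.uniform(0, 1, 200)
            _, p = lilliefors_test(x, n_mc=2000, seed=i)
            p_values.append(p)
        assert max(p_values) < 0.05
        assert sum(p < 0.01 for p in p_values) >= 5

    def test_normal_sample_usually_passes(self):
        passes = 0
        for i in range(20):
            rng = np.random.default_rng(100 + i)
            _, p = lilliefors_test(rng.standard_normal(200), n_mc=500, seed=i)
            passes += p > 0.05
        assert passes / 20 >= 0.90

    def test_constant_sample_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            lilliefors_test(np.full(20, 3.0))

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            lilliefors_test([1.0, 2.0, 3.0])


class TestCompareScalars:
    def test_paired_normal_shift_uses_t_test(self):
        rng = np.random.default_rng(0)
        a = rng.standard_normal(30)
        b = a + 2.0 + 0.1 * rng.standard_normal(30)
        rep = compare_scalars(a, b, paired=True)
        assert rep.test_name == "paired t-test"
        assert rep.p_value < 0.05

    def test_skewed_samples_use_wilcoxon(self):
        rng = np.random.default_rng(1)
        a = rng.lognormal(0.0, 1.5, 80)
        b = rng.lognormal(0.5, 1.5, 80)
        rep = compare_scalars(a, b, paired=False)
        assert rep.test_name == "Wilcoxon rank-sum"

    def test_identical_paired_samples_no_rejection(self):
        a = np.arange(10, dtype=float)
        rep = compare_scalars(a, a.copy(), paired=True)
        assert rep.statistic == 0.0
        assert rep.p_value == 1.0

    def test_two_sample_normal_uses_t_test(self):
        rng = np.random.default_rng(2)
        rep = compare_scalars(rng.standard_normal(40) + 1.0,
                              rng.standard_normal(40), paired=False)
        assert rep.test_name == "two-sample t-test"
        assert rep.p_value < 0.05

    def test_unequal_paired_lengths_rejected(self):
        with pytest.raises(ValueError):
            compare_scalars(np.zeros(5), np.zeros(6), paired=True)
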