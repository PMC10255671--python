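"""One-dimensional statistical (non-)parametric mapping and scalar tests.

Stroke-aligned curves (grip %, EMG envelopes, racket-head acceleration,
racket face-angle rate) are compared over the whole ±1 s window rather
than at hand-picked instants.  The experimental unit is the player mean
curve: strokes are averaged within player first, and groups are compared
across players.

The non-parametric route (SnPM) computes a pointwise t field and controls
the familywise error rate over the grid with the permutation distribution
of the maximum |t|: group labels are relabelled (two-sample) or
difference curves are sign-flipped (paired), all distinct rearrangements
enumerated exactly when their count is small enough, otherwise sampled
with the identity included.  The critical value is the conservative
(1 − α) quantile of the max-|t| null — the smallest null value whose
upper tail mass is at most α — so the FWER is at most α under
exchangeability.  Supra-threshold clusters are maximal runs of
|t| ≥ critical t; a cluster's direction follows the sign convention that
t > 0 means the first input's mean is higher.

The parametric route thresholds the same t field with the 1-D
random-field-theory approximation (smoothness estimated from normalized
residuals).  It exists to support the standard decision rule: when
parametric and non-parametric significance masks disagree the data are
treated as non-Gaussian and the non-parametric result is reported.

Discrete scalar outcomes (peaks, percentages) use a Lilliefors
normality test with a seeded Monte-Carlo null, branching to paired or
two-sample t-tests when normality is not rejected and to Wilcoxon
signed-rank / rank-sum tests otherwise; all tests are two-sided.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as st
from scipy.optimize import brentq

from .config import SnpmConfig

__all__ = [
    "GroupCurves",
    "SnpmResult",
    "ScalarTestReport",
    "player_mean_curve",
    "decimate_to_grid",
    "snpm_two_sample",
    "snpm_paired",
    "spm_parametric_field",
    "lilliefors_test",
    "compare_scalars",
]


@dataclass
class GroupCurves:
    """One curve per player (the experimental unit) on a common grid."""

    grid: np.ndarray
    curves: np.ndarray          # shape (n_players, n_nodes)
    group: str = ""
    variable: str = ""

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.curves = np.atleast_2d(np.asarray(self.curves, dtype=float))
        if self.curves.shape[1] != self.grid.size:
            raise ValueError("curves do not share the grid")

    @property
    def n(self) -> int:
        return self.curves.shape[0]


@dataclass
class SnpmResult:
    """Outcome of a 1-D SnPM test."""

    grid: np.ndarray
    t_field: np.ndarray
    critical_t: float
    clusters: list               # (start_s, end_s, direction)
    n_permutations_used: int
    exhaustive: bool
    variable: str = ""

    @property
    def significant(self) -> bool:
        return len(self.clusters) > 0


@dataclass(frozen=True)
class ScalarTestReport:
    """One discrete comparison: which test ran and what it found."""

    statistic: float
    p_value: float
    test_name: str
    normal: bool
    normality_p: float
    mean_a: float
    mean_b: float


# ---------------------------------------------------------------------------
# Curve preparation

def player_mean_curve(strokes, variable: str) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise mean and sample SD of one variable across a player's strokes."""
    if not strokes:
        raise ValueError("need at least one stroke")
    grids = [np.asarray(s.time) for s in strokes]
    for g in grids[1:]:
        if g.shape != grids[0].shape or not np.allclose(g, grids[0]):
            raise ValueError("stroke grids do not match")
    data = np.vstack([np.asarray(getattr(s, variable), dtype=float) for s in strokes])
    mean = data.mean(axis=0)
    sd = data.std(axis=0, ddof=1) if data.shape[0] > 1 else np.zeros_like(mean)
    return mean, sd


def decimate_to_grid(time: np.ndarray, curve: np.ndarray, n_nodes: int) -> tuple[np.ndarray, np.ndarray]:
    """Linear-interpolate a curve onto an evenly spaced n-node grid."""
    grid = np.linspace(time[0], time[-1], n_nodes)
    return grid, np.interp(grid, time, curve)


# ---------------------------------------------------------------------------
# t fields

def _two_sample_t(sum_a, ssq_a, n_a, sum_b, ssq_b, n_b):
    """Pooled-variance two-sample t from per-group sums and sums of squares."""
    mean_a = sum_a / n_a
    mean_b = sum_b / n_b
    var_a = (ssq_a - sum_a**2 / n_a) / (n_a - 1)
    var_b = (ssq_b - sum_b**2 / n_b) / (n_b - 1)
    sp2 = ((n_a - 1) * var_a + (n_b - 1) * var_b) / (n_a + n_b - 2)
    denom = np.sqrt(sp2 * (1.0 / n_a + 1.0 / n_b))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mean_a - mean_b) / denom
    return np.nan_to_num(t, nan=0.0, posinf=np.inf, neginf=-np.inf)


def _paired_t(D: np.ndarray) -> np.ndarray:
    n = D.shape[0]
    mean = D.mean(axis=0)
    sd = D.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / math.sqrt(n))
    return np.nan_to_num(t, nan=0.0, posinf=np.inf, neginf=-np.inf)


def _conservative_threshold(null_max: np.ndarray, alpha: float) -> float:
    """Smallest null value whose upper-tail count is at most floor(alpha N).

    Guarantees P(max |t| >= threshold) <= alpha over the permutation
    distribution even in the presence of ties; returns +inf when the
    permutation resolution cannot support the requested alpha
    (floor(alpha N) < 1)."""
    null_sorted = np.sort(null_max)
    n = null_sorted.size
    k = int(math.floor(alpha * n))
    if k < 1:
        return float("inf")
    # Candidate thresholds are the null values themselves.  Upper-tail
    # counts use a small relative tolerance so exact permutation ties that
    # differ only by floating-point round-off (e.g. complementary
    # relabelings, whose t fields are negatives of each other) are counted
    # as ties.
    tol = 1e-9 * (1.0 + np.abs(null_sorted))
    counts = n - np.searchsorted(null_sorted, null_sorted - tol, side="left")
    ok = np.flatnonzero(counts <= k)
    return float(null_sorted[ok[0]]) if ok.size else float("inf")


def _clusters(grid: np.ndarray, t_field: np.ndarray, critical: float) -> list:
    """Maximal supra-threshold runs with their direction labels."""
    if not np.isfinite(critical):
        return []
    supra = np.abs(t_field) >= critical
    clusters = []
    idx = np.flatnonzero(supra)
    if idx.size == 0:
        return clusters
    splits = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
    for run in splits:
        direction = "A>B" if t_field[run[0]] > 0 else "B>A"
        clusters.append((float(grid[run[0]]), float(grid[run[-1]]), direction))
    return clusters


def snpm_two_sample(a: GroupCurves, b: GroupCurves, cfg: SnpmConfig | None = None) -> SnpmResult:
    """Two-sided non-parametric 1-D two-sample t-test (A minus B orientation).

    The max-|t| null is built by relabelling group membership: all
    C(n_a + n_b, n_a) distinct relabelings are enumerated when that count
    is at most ``cfg.exhaustive_limit``, otherwise ``cfg.n_permutations``
    relabelings are drawn (identity included) with the configured seed.
    """
    cfg = cfg or SnpmConfig()
    if a.n < 2 or b.n < 2:
        raise ValueError("need at least 2 curves per group")
    if a.grid.shape != b.grid.shape or not np.allclose(a.grid, b.grid):
        raise ValueError("groups do not share a grid")
    X = np.vstack([a.curves, b.curves])
    n_a, n_b = a.n, b.n
    n = n_a + n_b
    total_sum = X.sum(axis=0)
    total_ssq = (X**2).sum(axis=0)

    n_distinct = math.comb(n, n_a)
    exhaustive = n_distinct <= cfg.exhaustive_limit
    if exhaustive:
        subsets = np.array(list(itertools.combinations(range(n), n_a)), dtype=int)
    else:
        rng = np.random.default_rng(cfg.seed)
        rand = np.argsort(rng.random((cfg.n_permutations - 1, n)), axis=1)[:, :n_a]
        subsets = np.vstack([np.arange(n_a)[None, :], rand])

    member = np.zeros((subsets.shape[0], n))
    np.put_along_axis(member, subsets, 1.0, axis=1)
    sum_a = member @ X
    ssq_a = member @ (X**2)
    t_perm = _two_sample_t(sum_a, ssq_a, n_a,
                           total_sum[None, :] - sum_a, total_ssq[None, :] - ssq_a, n_b)
    null_max = np.abs(t_perm).max(axis=1)
    critical = _conservative_threshold(null_max, cfg.alpha)

    t_obs = _two_sample_t(X[:n_a].sum(0), (X[:n_a]**2).sum(0), n_a,
                          X[n_a:].sum(0), (X[n_a:]**2).sum(0), n_b)
    return SnpmResult(
        grid=a.grid,
        t_field=t_obs,
        critical_t=critical,
        clusters=_clusters(a.grid, t_obs, critical),
        n_permutations_used=subsets.shape[0],
        exhaustive=exhaustive,
        variable=a.variable or b.variable,
    )


def snpm_paired(a: GroupCurves, b: GroupCurves, cfg: SnpmConfig | None = None) -> SnpmResult:
    """Two-sided non-parametric 1-D paired t-test on matched players.

    The null is built by sign-flipping the within-player difference
    curves (a − b); all 2^n flips are enumerated when feasible.
    """
    cfg = cfg or SnpmConfig()
    if a.n != b.n:
        raise ValueError("paired test requires matched players in both conditions")
    if a.n < 2:
        raise ValueError("need at least 2 matched pairs")
    if a.grid.shape != b.grid.shape or not np.allclose(a.grid, b.grid):
        raise ValueError("conditions do not share a grid")
    D = a.curves - b.curves
    n = D.shape[0]

    n_distinct = 2 ** n
    exhaustive = n_distinct <= cfg.exhaustive_limit
    if exhaustive:
        signs = np.array(list(itertools.product((1.0, -1.0), repeat=n)))
    else:
        rng = np.random.default_rng(cfg.seed)
        signs = rng.choice([-1.0, 1.0], size=(cfg.n_permutations - 1, n))
        signs = np.vstack([np.ones((1, n)), signs])

    null_max = np.empty(signs.shape[0])
    for i, s in enumerate(signs):      # modest loop; D is small
        null_max[i] = np.abs(_paired_t(D * s[:, None])).max()
    critical = _conservative_threshold(null_max, cfg.alpha)

    t_obs = _paired_t(D)
    return SnpmResult(
        grid=a.grid,
        t_field=t_obs,
        critical_t=critical,
        clusters=_clusters(a.grid, t_obs, critical),
        n_permutations_used=signs.shape[0],
        exhaustive=exhaustive,
        variable=a.variable or b.variable,
    )


# ---------------------------------------------------------------------------
# Parametric (random field theory) route

def _estimate_fwhm(residuals: np.ndarray) -> float:
    """Smoothness (FWHM, in node units) from normalized residual gradients."""
    ssq = (residuals**2).sum(axis=0)
    ssq = np.where(ssq > 0, ssq, 1.0)
    u = residuals / np.sqrt(ssq)
    du = np.diff(u, axis=1)
    v = (du**2).sum(axis=0)
    v_mean = v.mean()
    if v_mean <= 0:
        return float("inf")
    return math.sqrt(4.0 * math.log(2.0) / v_mean)


def _rft_threshold(df: int, resels: float, alpha: float) -> float:
    """Two-sided RFT critical value for a 1-D t field."""
    c = math.sqrt(4.0 * math.log(2.0)) / (2.0 * math.pi)

    def excursion_prob(t):
        ec1 = c * (1.0 + t * t / df) ** (-(df - 1) / 2.0)
        return 2.0 * (st.t.sf(t, df) + resels * ec1)

    lo, hi = 1e-3, 100.0
    if excursion_prob(hi) > alpha:
        return float("inf")
    return float(brentq(lambda t: excursion_prob(t) - alpha, lo, hi))


def spm_parametric_field(a: GroupCurves, b: GroupCurves, paired: bool = False,
                         alpha: float = 0.05) -> SnpmResult:
    """Parametric 1-D SPM t-test with a random-field-theory threshold.

    Produces the same t field as the non-parametric route; only the
    critical value differs.  Used for the parametric/non-parametric
    agreement decision rule.
    """
    if paired:
        if a.n != b.n:
            raise ValueError("paired test requires matched players")
        D = a.curves - b.curves
        t_obs = _paired_t(D)
        residuals = D - D.mean(axis=0)
        df = D.shape[0] - 1
    else:
        X = np.vstack([a.curves, b.curves])
        n_a = a.n
        t_obs = _two_sample_t(X[:n_a].sum(0), (X[:n_a]**2).sum(0), n_a,
                              X[n_a:].sum(0), (X[n_a:]**2).sum(0), b.n)
        residuals = np.vstack([a.curves - a.curves.mean(axis=0),
                               b.curves - b.curves.mean(axis=0)])
        df = a.n + b.n - 2
    fwhm = _estimate_fwhm(residuals)
    resels = (a.grid.size - 1) / fwhm if np.isfinite(fwhm) else 0.0
    critical = _rft_threshold(df, resels, alpha)
    return SnpmResult(
        grid=a.grid,
        t_field=t_obs,
        critical_t=critical,
        clusters=_clusters(a.grid, t_obs, critical),
        n_permutations_used=0,
        exhaustive=False,
        variable=a.variable or b.variable,
    )


# ---------------------------------------------------------------------------
# Scalar tests

def lilliefors_test(sample, n_mc: int = 2000, seed: int = 0) -> tuple[float, float]:
    """Lilliefors normality test with a seeded Monte-Carlo null.

    Kolmogorov–Smirnov distance between the sample and a normal
    distribution with mean/SD estimated from the sample; the p-value is
    the fraction of ``n_mc`` simulated normal samples (of the same size,
    each re-standardised by its own estimates) with at least as large a
    distance.  Returns ``(statistic, p_value)``.
    """
    x = np.asarray(sample, dtype=float)
    if x.size < 4:
        raise ValueError("Lilliefors test requires at least 4 observations")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance sample")
    d_obs = st.kstest(x, "norm", args=(x.mean(), sd)).statistic
    rng = np.random.default_rng(seed)
    sims = rng.standard_normal((n_mc, x.size))
    mu = sims.mean(axis=1, keepdims=True)
    s = sims.std(axis=1, ddof=1, keepdims=True)
    z = np.sort((sims - mu) / s, axis=1)
    # KS distance of each standardised sample against N(0, 1)
    cdf = st.norm.cdf(z)
    grid = np.arange(1, x.size + 1) / x.size
    d_sim = np.maximum(np.abs(cdf - grid), np.abs(cdf - (grid - 1.0 / x.size))).max(axis=1)
    p = (1.0 + np.sum(d_sim >= d_obs)) / (n_mc + 1.0)
    return float(d_obs), float(p)


def compare_scalars(a, b, paired: bool = False, alpha: float = 0.05,
                    n_mc: int = 2000, seed: int = 0) -> ScalarTestReport:
    """Normality-branched two-sided scalar comparison.

    Lilliefors is applied to the within-pair differences (paired) or to
    each sample (two-sample).  If normality is not rejected at 0.05 a
    paired / two-sample t-test is used; otherwise the Wilcoxon
    signed-rank / rank-sum test.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if paired:
        if a.size != b.size:
            raise ValueError("paired comparison requires equal sample sizes")
        diff = a - b
        if np.all(diff == 0):
            return ScalarTestReport(0.0, 1.0, "degenerate (identical samples)",
                                    True, 1.0, float(a.mean()), float(b.mean()))
        if diff.size < 4:
            p_norm, normal = float("nan"), True   # too small to test normality
        else:
            _, p_norm = lilliefors_test(diff, n_mc=n_mc, seed=seed)
            normal = p_norm > 0.05
        if normal:
            res = st.ttest_rel(a, b)
            name = "paired t-test"
        else:
            res = st.wilcoxon(a, b)
            name = "Wilcoxon signed-rank"
    else:
        if min(a.size, b.size) < 4:
            p_norm, normal = float("nan"), True   # too small to test normality
        else:
            _, p_a = lilliefors_test(a, n_mc=n_mc, seed=seed)
            _, p_b = lilliefors_test(b, n_mc=n_mc, seed=seed + 1)
            p_norm = min(p_a, p_b)
            normal = p_norm > 0.05
        if normal:
            res = st.ttest_ind(a, b)
            name = "two-sample t-test"
        else:
            res = st.ranksums(a, b)
            name = "Wilcoxon rank-sum"
    return ScalarTestReport(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        test_name=name,
        normal=bool(normal),
        normality_p=float(p_norm),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
    )
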