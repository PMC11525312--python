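"""Statistical toolbox for ratio studies and integral data.

Thin, validated wrappers around SciPy for Shapiro-Wilk, Brown-Forsythe
(median-centred Levene), Kruskal-Wallis and the chi-squared goodness-of-fit
statistic, plus in-package implementations of Dunn's post-hoc test (pooled
ranks with tie correction) and Hampel's median/MAD outlier rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats as sps

from .errors import DataError


@dataclass(frozen=True)
class TestResult:
    method: str
    statistic: float
    p_value: float
    df: float | None = None
    group_sizes: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.p_value <= 1 or np.isnan(self.p_value)):
            raise DataError("p-value outside [0, 1]")


def shapiro_wilk(sample) -> TestResult:
    """Shapiro-Wilk test of normality (3 <= n <= 5000)."""
    x = np.asarray(sample, float)
    if not 3 <= len(x) <= 5000:
        raise DataError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise DataError("constant sample is degenerate for Shapiro-Wilk")
    w, p = sps.shapiro(x)
    return TestResult("shapiro-wilk", float(w), float(p))


def levene(groups) -> TestResult:
    """Median-centred Levene (Brown-Forsythe) test of variance homogeneity."""
    gs = [np.asarray(g, float) for g in groups]
    if len(gs) < 2 or any(len(g) < 2 for g in gs):
        raise DataError("Levene requires >= 2 groups with n >= 2 each")
    if all(np.ptp(g) == 0 for g in gs):
        # identical spreads of zero: no variance anywhere
        return TestResult("levene(median)", 0.0, 1.0, group_sizes=tuple(map(len, gs)))
    stat, p = sps.levene(*gs, center="median")
    if np.isnan(stat):
        return TestResult("levene(median)", 0.0, 1.0, group_sizes=tuple(map(len, gs)))
    return TestResult("levene(median)", float(stat), float(p), group_sizes=tuple(map(len, gs)))


def kruskal_wallis(groups) -> TestResult:
    """Kruskal-Wallis H test with tie correction and chi-squared p-value."""
    gs = [np.asarray(g, float) for g in groups]
    if len(gs) < 2:
        raise DataError("Kruskal-Wallis requires >= 2 groups")
    pooled = np.concatenate(gs)
    if np.ptp(pooled) == 0:
        raise DataError("all values identical: Kruskal-Wallis is degenerate")
    h, p = sps.kruskal(*gs)
    return TestResult(
        "kruskal-wallis", float(h), float(p), df=len(gs) - 1, group_sizes=tuple(map(len, gs))
    )


def dunn_posthoc(groups, adjust: str = "none") -> list[tuple[int, int, TestResult]]:
    """Dunn's post-hoc pairwise comparisons on pooled ranks.

    For groups i, j the statistic is
    z = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) (1/n_i + 1/n_j)),
    with tie correction T = sum(t^3 - t) / (12 (N - 1)) over tie groups, and
    two-sided normal p-values. ``adjust`` is 'none' (default) or 'holm'.

    Returns a list of (i, j, TestResult) for every unordered pair.
    """
    gs = [np.asarray(g, float) for g in groups]
    if len(gs) < 3:
        raise DataError("Dunn's test requires >= 3 groups")
    if any(len(g) == 0 for g in gs):
        raise DataError("empty group in Dunn's test")
    if adjust not in ("none", "holm"):
        raise DataError("adjust must be 'none' or 'holm'")
    pooled = np.concatenate(gs)
    n_total = len(pooled)
    ranks = sps.rankdata(pooled)
    # mean rank per group
    means, sizes = [], []
    start = 0
    for g in gs:
        means.append(ranks[start : start + len(g)].mean())
        sizes.append(len(g))
        start += len(g)
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (12.0 * (n_total - 1))
    var_unit = n_total * (n_total + 1) / 12.0 - tie_term

    pairs = list(combinations(range(len(gs)), 2))
    zs, ps = [], []
    for i, j in pairs:
        se = np.sqrt(var_unit * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (means[i] - means[j]) / se if se > 0 else 0.0
        zs.append(z)
        ps.append(2.0 * sps.norm.sf(abs(z)))
    if adjust == "holm":
        order = np.argsort(ps)
        m = len(ps)
        adj = np.empty(m)
        running = 0.0
        for rank_idx, k in enumerate(order):
            running = max(running, (m - rank_idx) * ps[k])
            adj[k] = min(1.0, running)
        ps = list(adj)
    return [
        (i, j, TestResult("dunn", float(z), float(p), group_sizes=(sizes[i], sizes[j])))
        for (i, j), z, p in zip(pairs, zs, ps)
    ]


def hampel_outliers(sample, k: float = 3.0) -> np.ndarray:
    """Flag values outside median +/- k * scaled MAD (Hampel's rule).

    The MAD is scaled by 1.4826 for consistency with the normal standard
    deviation; the default multiplier k = 3 is the customary conservative
    choice. A zero MAD with non-constant data falls back to flagging every
    value different from the median.
    """
    x = np.asarray(sample, float)
    if len(x) < 3:
        raise DataError("Hampel's rule requires n >= 3")
    med = np.median(x)
    mad = 1.4826 * np.median(np.abs(x - med))
    if mad == 0:
        if np.ptp(x) == 0:
            return np.zeros(len(x), dtype=bool)
        return x != med
    return np.abs(x - med) > k * mad


def chi_squared_gof(observed, fitted, n_params: int = 0) -> TestResult:
    """Chi-squared goodness of fit between data and a fitted curve.

    statistic = sum((obs - fit)^2 / fit) over the compared points, with
    df = n - n_params. Following the assay-evaluation convention, a p-value
    near 0.5 marks the best-balanced fit and values in [0.05, 0.95] count
    as sufficient.
    """
    obs = np.asarray(observed, float)
    fit = np.asarray(fitted, float)
    if obs.shape != fit.shape:
        raise DataError("observed and fitted must have the same shape")
    if np.any(fit <= 0):
        raise DataError("chi-squared requires strictly positive fitted values")
    stat = float(np.sum((obs - fit) ** 2 / fit))
    df = len(obs) - n_params
    if df <= 0:
        raise DataError("non-positive degrees of freedom")
    return TestResult("chi2-gof", stat, float(sps.chi2.sf(stat, df)), df=df)


def chi2_sufficient(result: TestResult, lo: float = 0.05, hi: float = 0.95) -> bool:
    """Whether a goodness-of-fit p-value falls in the sufficiency band."""
    return lo <= result.p_value <= hi
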