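"""Method-comparison statistics for paired continuous-vs-snapshot readings.

Bland–Altman agreement (bias, limits of agreement, confidence interval of
the bias), per-patient good/poor agreement classification, Passing–Bablok
rank-based regression with its CUSUM linearity test, and Spearman rank
correlation.

Two deliberately distinct interval notions are always reported: the limits
of agreement ``bias ± loa_multiplier * SD(differences)`` describe where
individual differences fall, while the confidence interval of the bias
``bias ± t * SD/sqrt(n)`` describes the precision of the mean difference.
The limits-of-agreement multiplier defaults to 2 (not 1.96) and is
configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateInputError, InsufficientDataError

__all__ = [
    "AgreementResult",
    "PBResult",
    "bland_altman",
    "classify_agreement",
    "passing_bablok",
    "cusum_linearity",
    "spearman",
]

#: Kolmogorov–Smirnov 5% critical value used by the CUSUM linearity decision
CUSUM_CRITICAL_5PCT = 1.36


@dataclass(frozen=True)
class AgreementResult:
    """Bland–Altman summary of paired differences ``d = y - x``."""

    n_pairs: int
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    bias_ci_low: float
    bias_ci_high: float
    bias_significant: bool
    loa_multiplier: float = 2.0
    ci_level: float = 0.95


@dataclass(frozen=True)
class PBResult:
    """Passing–Bablok regression fit ``y = intercept + slope * x``."""

    slope: float
    slope_ci_low: float
    slope_ci_high: float
    intercept: float
    intercept_ci_low: float
    intercept_ci_high: float
    n_pairs: int
    cusum_stat: float | None = None
    linearity_rejected: bool | None = None
    linearity_p: float | None = None


def bland_altman(
    x, y, loa_multiplier: float = 2.0, ci_level: float = 0.95
) -> AgreementResult:
    """Bland–Altman agreement between two measurement methods.

    ``d = y - x``; bias is the mean difference, the limits of agreement are
    ``bias ± loa_multiplier * SD(d)`` and the bias CI uses the t
    distribution on n-1 degrees of freedom.  The bias is significant when 0
    lies outside its CI.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise InsufficientDataError("x and y must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    d = (y - x)[keep]
    n = d.size
    if n < 3:
        raise InsufficientDataError(f"need at least 3 complete pairs, got {n}")
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    tcrit = float(stats.t.ppf(0.5 + ci_level / 2, n - 1))
    half = tcrit * sd / np.sqrt(n)
    ci = (bias - half, bias + half)
    return AgreementResult(
        n_pairs=n,
        bias=bias,
        sd_diff=sd,
        loa_low=bias - loa_multiplier * sd,
        loa_high=bias + loa_multiplier * sd,
        bias_ci_low=ci[0],
        bias_ci_high=ci[1],
        bias_significant=not (ci[0] <= 0.0 <= ci[1]),
        loa_multiplier=loa_multiplier,
        ci_level=ci_level,
    )


def classify_agreement(
    patient_differences: dict[str, list[float]],
    loa: tuple[float, float],
) -> dict[str, str]:
    """Per-patient good/poor agreement against pooled limits of agreement.

    A patient is ``poor`` when at least one difference lies strictly outside
    ``[loa_low, loa_high]``; a difference exactly on a limit counts as good.
    """
    lo, hi = loa
    out = {}
    for pid, diffs in patient_differences.items():
        d = np.asarray(diffs, float)
        out[pid] = "poor" if np.any((d < lo) | (d > hi)) else "good"
    return out


def _pairwise_slopes(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """All valid pairwise slopes per the original Passing–Bablok procedure.

    Slopes of exactly -1 are omitted, 0/0 pairs (both coordinates tied) are
    omitted, and vertical pairs (x tied, y not) enter as signed infinities.
    """
    n = len(x)
    i, j = np.triu_indices(n, k=1)
    dx = x[j] - x[i]
    dy = y[j] - y[i]
    both_tied = (dx == 0) & (dy == 0)
    dx, dy = dx[~both_tied], dy[~both_tied]
    s = np.full_like(dy, np.nan)
    np.divide(dy, dx, out=s, where=dx != 0)
    vert = dx == 0
    s[vert] = np.sign(dy[vert]) * np.inf
    return s[s != -1.0]


def passing_bablok(x, y, alpha: float = 0.05, linearity: bool = True) -> PBResult:
    """Passing–Bablok rank-based regression for method comparison.

    The slope is the K-offset shifted median of all pairwise slopes, where K
    counts slopes below -1 (this makes the estimate invariant under swapping
    the methods); the intercept is ``median(y - slope*x)``.  Confidence
    bounds come from the rank offsets ``w = z * sqrt(n(n-1)(2n+5)/18)``
    around the median rank.  The CUSUM linearity test is run unless
    ``linearity=False``.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        raise InsufficientDataError(f"need at least 3 pairs, got {n}")
    if np.all(x == x[0]):
        raise DegenerateInputError("all x values identical")

    s = np.sort(_pairwise_slopes(x, y))
    N = len(s)
    if N == 0:
        raise DegenerateInputError("no valid pairwise slopes")
    K = int(np.sum(s < -1.0))

    def shifted_quantile(rank_1based: int) -> float:
        return float(s[np.clip(rank_1based + K - 1, 0, N - 1)])

    if N % 2:
        b = shifted_quantile((N + 1) // 2)
    else:
        b = 0.5 * (shifted_quantile(N // 2) + shifted_quantile(N // 2 + 1))

    z = float(stats.norm.ppf(1 - alpha / 2))
    w = z * np.sqrt(n * (n - 1) * (2 * n + 5) / 18.0)
    m1 = int(round((N - w) / 2.0))
    m2 = N - m1 + 1
    b_lo = shifted_quantile(m1)
    b_hi = shifted_quantile(m2)

    def icpt(slope):
        return float(np.median(y - slope * x)) if np.isfinite(slope) else float("nan")

    a = icpt(b)
    a_lo = icpt(b_hi)
    a_hi = icpt(b_lo)

    result = PBResult(
        slope=b,
        slope_ci_low=b_lo,
        slope_ci_high=b_hi,
        intercept=a,
        intercept_ci_low=a_lo,
        intercept_ci_high=a_hi,
        n_pairs=n,
    )
    if linearity:
        stat, rejected = cusum_linearity(x, y, result)
        result = PBResult(
            **{**result.__dict__, "cusum_stat": stat, "linearity_rejected": rejected}
        )
    return result


def cusum_linearity(x, y, fit: PBResult) -> tuple[float, bool]:
    """CUSUM test for the linearity of a Passing–Bablok fit.

    Residual signs are accumulated in score order (``D_i = y_i + x_i/b``):
    ``+sqrt(M/L)`` per positive and ``-sqrt(L/M)`` per negative residual,
    with L and M the positive and negative counts.  The statistic is
    ``max|cusum| / sqrt(L+M)``; linearity is rejected at 5% when it exceeds
    the Kolmogorov–Smirnov critical value 1.36.  For an explicit p-value use
    :func:`cusum_linearity_p` (Monte-Carlo permutation of residual signs).
    """
    stat, rejected, _ = _cusum(x, y, fit, n_mc=0)
    return stat, rejected


def cusum_linearity_p(
    x, y, fit: PBResult, n_mc: int = 2000, seed: int | np.random.Generator = 0
) -> tuple[float, bool, float]:
    """CUSUM statistic, 5% decision and Monte-Carlo permutation p-value."""
    return _cusum(x, y, fit, n_mc=n_mc, seed=seed)


def _cusum(x, y, fit, n_mc=0, seed=0):
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    resid = y - fit.intercept - fit.slope * x
    r = np.sign(resid)
    nz = r != 0
    r = r[nz]
    L = int(np.sum(r > 0))
    M = int(np.sum(r < 0))
    if L == 0 or M == 0:
        return 0.0, False, 1.0
    score = y[nz] + x[nz] / fit.slope if fit.slope != 0 else x[nz]
    order = np.argsort(score, kind="stable")
    steps = np.where(r[order] > 0, np.sqrt(M / L), -np.sqrt(L / M))
    stat = float(np.max(np.abs(np.cumsum(steps))) / np.sqrt(L + M))
    rejected = stat > CUSUM_CRITICAL_5PCT
    p = float("nan")
    if n_mc > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        hits = 0
        for _ in range(n_mc):
            perm = rng.permutation(steps)
            if np.max(np.abs(np.cumsum(perm))) / np.sqrt(L + M) >= stat - 1e-12:
                hits += 1
        p = (hits + 1) / (n_mc + 1)
    return stat, rejected, p


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties.

    Returns ``(rho, p)``; constant input yields ``(nan, nan)`` rather than
    raising.  The p-value uses the t approximation.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise InsufficientDataError("need at least 3 pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan"), float("nan")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)
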