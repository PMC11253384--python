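"""Weaning-failure prediction statistics.

ROC curves with an explicit, never-inferred direction (for diaphragm
excursion and velocity, *lower* values predict failure), Youden-optimal
cutoffs with deterministic tie-breaking, Clopper–Pearson exact confidence
intervals for the diagnostic proportions, class-stratified bootstrap
confidence intervals, and the DeLong structural-component test for
correlated AUCs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateInputError, InvalidParameterError

__all__ = [
    "ROCResult",
    "ProportionCI",
    "DiagnosticPerformance",
    "BootstrapROC",
    "DeLongResult",
    "roc_curve",
    "youden_cutoff",
    "diagnostic_metrics",
    "clopper_pearson",
    "bootstrap_roc",
    "delong_test",
]

DIRECTIONS = ("lower", "higher")


def _check_inputs(scores, labels):
    scores = np.asarray(scores, float)
    labels = np.asarray(labels).astype(bool)
    if scores.shape != labels.shape:
        raise InvalidParameterError("scores and labels must have equal length")
    keep = ~np.isnan(scores)
    scores, labels = scores[keep], labels[keep]
    if labels.all() or not labels.any():
        raise DegenerateInputError("both classes must be present")
    return scores, labels


def _check_direction(direction: str) -> None:
    if direction not in DIRECTIONS:
        raise InvalidParameterError(f"direction must be one of {DIRECTIONS}")


@dataclass(frozen=True)
class ROCResult:
    """ROC curve: one row per threshold, plus the trapezoid AUC."""

    thresholds: np.ndarray
    sens: np.ndarray
    spec: np.ndarray
    auc: float
    direction: str
    n_pos: int
    n_neg: int


def roc_curve(scores, labels, direction: str = "lower") -> ROCResult:
    """ROC curve over all distinct-score midpoints plus infinite sentinels.

    ``direction="lower"`` calls a case positive when its score is at or
    below the threshold (low excursion predicts failure); ``"higher"``
    flips the inequality.  The direction is applied exactly as stated — the
    AUC is not forced above 0.5.  The trapezoid AUC equals the tie-corrected
    Mann–Whitney probability.
    """
    _check_direction(direction)
    scores, labels = _check_inputs(scores, labels)
    sign = -1.0 if direction == "lower" else 1.0
    s = sign * scores  # positive call <=> s >= threshold'
    distinct = np.unique(s)
    mids = (distinct[:-1] + distinct[1:]) / 2
    thr = np.concatenate([[-np.inf], distinct[:1], mids, [np.inf]])
    # include the lowest score itself so the all-positive point is reachable
    thr = np.unique(thr)
    pos = s[labels]
    neg = s[~labels]
    sens = np.array([(pos >= t).mean() for t in thr])
    spec = np.array([(neg < t).mean() for t in thr])
    fpr = 1 - spec
    # ties in FPR must be ordered by TPR as well, or the trapezoid rule
    # connects the wrong corner of a vertical ROC segment
    order = np.lexsort((sens, fpr))
    auc = float(np.trapezoid(sens[order], fpr[order]))
    return ROCResult(
        thresholds=sign * thr,
        sens=sens,
        spec=spec,
        auc=auc,
        direction=direction,
        n_pos=len(pos),
        n_neg=len(neg),
    )


def youden_cutoff(roc: ROCResult) -> float:
    """Cutoff maximizing the Youden index J = sens + spec - 1.

    Ties are broken toward higher sensitivity, then toward the threshold
    making more positive calls; the result is deterministic.
    """
    j = roc.sens + roc.spec - 1
    n_calls = roc.sens * roc.n_pos + (1 - roc.spec) * roc.n_neg
    best = np.lexsort((n_calls, roc.sens, j))[-1]
    return float(roc.thresholds[best])


@dataclass(frozen=True)
class ProportionCI:
    """A proportion with its exact (Clopper–Pearson) confidence interval."""

    value: float
    ci_low: float
    ci_high: float
    k: int
    n: int


def clopper_pearson(k: int, n: int, level: float = 0.95) -> ProportionCI:
    """Exact binomial confidence interval; ``n = 0`` yields NaN with CI [0, 1]."""
    if n == 0:
        return ProportionCI(float("nan"), 0.0, 1.0, 0, 0)
    alpha = 1 - level
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return ProportionCI(k / n, lo, hi, k, n)


@dataclass(frozen=True)
class DiagnosticPerformance:
    """Confusion counts and diagnostic proportions at a fixed cutoff."""

    cutoff: float
    direction: str
    tp: int
    fp: int
    tn: int
    fn: int
    sens: ProportionCI
    spec: ProportionCI
    ppv: ProportionCI
    npv: ProportionCI

    @property
    def youden_j(self) -> float:
        return self.sens.value + self.spec.value - 1


def diagnostic_metrics(
    scores, labels, cutoff: float, direction: str = "lower", ci_level: float = 0.95
) -> DiagnosticPerformance:
    """Sensitivity, specificity and predictive values at a cutoff.

    Positive calls are scores at or below the cutoff for ``direction
    "lower"`` (at or above for ``"higher"``); each proportion carries a
    Clopper–Pearson exact CI.  Zero-denominator proportions are NaN with CI
    [0, 1].
    """
    _check_direction(direction)
    if not np.isfinite(cutoff):
        raise InvalidParameterError("cutoff must be finite")
    scores, labels = _check_inputs(scores, labels)
    call = scores <= cutoff if direction == "lower" else scores >= cutoff
    tp = int(np.sum(call & labels))
    fp = int(np.sum(call & ~labels))
    tn = int(np.sum(~call & ~labels))
    fn = int(np.sum(~call & labels))
    return DiagnosticPerformance(
        cutoff=float(cutoff),
        direction=direction,
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        sens=clopper_pearson(tp, tp + fn, ci_level),
        spec=clopper_pearson(tn, tn + fp, ci_level),
        ppv=clopper_pearson(tp, tp + fp, ci_level),
        npv=clopper_pearson(tn, tn + fn, ci_level),
    )


@dataclass(frozen=True)
class BootstrapROC:
    """Percentile bootstrap summary of the AUC and Youden cutoff."""

    auc: float
    auc_ci_low: float
    auc_ci_high: float
    cutoff: float
    cutoff_ci_low: float
    cutoff_ci_high: float
    n_replicates: int
    auc_distribution: np.ndarray
    cutoff_distribution: np.ndarray


def bootstrap_roc(
    scores,
    labels,
    B: int = 1000,
    seed: int | np.random.Generator = 0,
    direction: str = "lower",
    ci_level: float = 0.95,
) -> BootstrapROC:
    """Class-stratified bootstrap of the AUC and Youden-optimal cutoff.

    Each replicate resamples subjects with replacement within each outcome
    class (so both classes are always present at the study's sample size)
    and recomputes the full ROC; confidence intervals are percentile.
    Fully reproducible from the seed.
    """
    if B < 1:
        raise InvalidParameterError("B must be >= 1")
    scores, labels = _check_inputs(scores, labels)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pos_idx = np.nonzero(labels)[0]
    neg_idx = np.nonzero(~labels)[0]
    aucs = np.empty(B)
    cuts = np.empty(B)
    for b in range(B):
        take = np.concatenate(
            [rng.choice(pos_idx, len(pos_idx)), rng.choice(neg_idx, len(neg_idx))]
        )
        roc = roc_curve(scores[take], labels[take], direction)
        aucs[b] = roc.auc
        cuts[b] = youden_cutoff(roc)
    roc = roc_curve(scores, labels, direction)
    q = [(1 - ci_level) / 2 * 100, (1 + ci_level) / 2 * 100]
    finite_cuts = cuts[np.isfinite(cuts)]
    cut_ci = (
        np.percentile(finite_cuts, q) if finite_cuts.size else (float("nan"),) * 2
    )
    return BootstrapROC(
        auc=roc.auc,
        auc_ci_low=float(np.percentile(aucs, q[0])),
        auc_ci_high=float(np.percentile(aucs, q[1])),
        cutoff=youden_cutoff(roc),
        cutoff_ci_low=float(cut_ci[0]),
        cutoff_ci_high=float(cut_ci[1]),
        n_replicates=B,
        auc_distribution=aucs,
        cutoff_distribution=cuts,
    )


@dataclass(frozen=True)
class DeLongResult:
    auc_a: float
    auc_b: float
    z: float
    p: float


def delong_test(scores_a, scores_b, labels, direction: str = "higher") -> DeLongResult:
    """DeLong comparison of two correlated (paired) AUCs.

    Uses the structural-component (placement-value) estimates of each AUC,
    their variances and covariance; the z statistic is the AUC difference
    over the standard error of the difference, with a two-sided normal
    p-value.  Degenerate placement variance yields NaN z and p.
    """
    _check_direction(direction)
    a = np.asarray(scores_a, float)
    b = np.asarray(scores_b, float)
    labels = np.asarray(labels).astype(bool)
    if a.shape != b.shape or a.shape != labels.shape:
        raise InvalidParameterError("paired scores must share the subjects")
    if labels.all() or not labels.any():
        raise DegenerateInputError("both classes must be present")
    if direction == "lower":
        a, b = -a, -b

    def components(s):
        pos = s[labels]
        neg = s[~labels]
        psi = (pos[:, None] > neg[None, :]).astype(float)
        psi += 0.5 * (pos[:, None] == neg[None, :])
        return psi.mean(axis=1), psi.mean(axis=0)  # V10_i, V01_j

    v10a, v01a = components(a)
    v10b, v01b = components(b)
    auc_a = float(v10a.mean())
    auc_b = float(v10b.mean())
    m, n = len(v10a), len(v01a)
    if m < 2 or n < 2:
        return DeLongResult(auc_a, auc_b, float("nan"), float("nan"))
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1)
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n
    if var <= 0:
        # degenerate difference variance: identical placements (e.g. one
        # marker is a monotone transform of the other) give a zero difference
        if auc_a == auc_b:
            return DeLongResult(auc_a, auc_b, 0.0, 1.0)
        return DeLongResult(auc_a, auc_b, float("nan"), float("nan"))
    z = (auc_a - auc_b) / np.sqrt(var)
    p = 2 * float(stats.norm.sf(abs(z)))
    return DeLongResult(auc_a, auc_b, float(z), p)
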