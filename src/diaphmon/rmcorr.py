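"""Repeated-measures correlation and per-subject correlation profiles.

The repeated-measures correlation estimates the common within-subject
association between two repeatedly measured variables by a shared-slope
ANCOVA: ``y = subject-intercepts + b*x + error``.  Between-subject variation
is absorbed by the intercepts, so the coefficient reflects only the
within-subject coupling — here, between minute-level Pdi-derived effort
indices and excursion-derived motion indices during a breathing trial.

Unbalanced designs are first-class: subjects contribute what complete pairs
they have, and subjects with fewer than two pairs are dropped (and counted).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError
from .agreement import spearman

__all__ = ["RmcorrResult", "rmcorr", "per_subject_spearman"]


@dataclass(frozen=True)
class RmcorrResult:
    """Repeated-measures correlation estimate.

    ``df = n_obs - n_subjects - 1`` (complete cases); the CI is a Fisher
    z interval with standard error ``1/sqrt(df - 1)``; the p-value comes
    from the F statistic on (1, df).
    """

    r_rm: float
    df: int
    ci_low: float
    ci_high: float
    p: float
    n_subjects: int
    n_obs: int
    slope: float
    n_subjects_excluded: int = 0


def _complete_by_subject(subjects, x, y, min_pairs: int = 2):
    df = pd.DataFrame({"subject": np.asarray(subjects), "x": x, "y": y}).dropna()
    counts = df.groupby("subject", sort=False)["x"].transform("size")
    excluded = df.loc[counts < min_pairs, "subject"].nunique()
    return df[counts >= min_pairs], excluded


def rmcorr(subjects, x, y, ci_level: float = 0.95) -> RmcorrResult:
    """Repeated-measures correlation via the shared-slope ANCOVA model.

    Subjects' x and y are centered within subject (equivalent to least
    squares with subject as a categorical factor); the shared slope b and the
    effect/error sums of squares give
    ``r_rm = sign(b) * sqrt(SS_effect / (SS_effect + SS_error))``.
    Incomplete pairs are dropped per subject; subjects left with fewer than
    two pairs are excluded.
    """
    data, excluded = _complete_by_subject(subjects, x, y)
    n_obs = len(data)
    n_subj = data["subject"].nunique()
    if n_subj < 2:
        raise InsufficientDataError("need at least 2 subjects with >= 2 complete pairs")
    g = data.groupby("subject", sort=False)
    xc = (data["x"] - g["x"].transform("mean")).to_numpy()
    yc = (data["y"] - g["y"].transform("mean")).to_numpy()
    df_err = n_obs - n_subj - 1
    if df_err < 1 or np.allclose(xc, 0):
        raise InsufficientDataError("no within-subject variation in x")

    sxx = float(xc @ xc)
    sxy = float(xc @ yc)
    syy = float(yc @ yc)
    b = sxy / sxx
    ss_effect = b * sxy          # = sxy^2 / sxx
    ss_error = syy - ss_effect
    if ss_effect + ss_error <= 0:
        r = 0.0
    else:
        r = float(np.sign(b) * np.sqrt(ss_effect / (ss_effect + ss_error)))
    r = float(np.clip(r, -1.0, 1.0))

    if ss_error <= 0:
        p = 0.0
    elif b == 0:
        p = 1.0
    else:
        f = (r**2 * df_err) / (1 - r**2)
        p = float(stats.f.sf(f, 1, df_err))

    if abs(r) >= 1.0 or df_err < 2:
        lo, hi = r, r
    else:
        zr = np.arctanh(r)
        zcrit = float(stats.norm.ppf(0.5 + ci_level / 2))
        se = 1.0 / np.sqrt(df_err - 1)
        lo, hi = float(np.tanh(zr - zcrit * se)), float(np.tanh(zr + zcrit * se))

    return RmcorrResult(
        r_rm=r,
        df=df_err,
        ci_low=lo,
        ci_high=hi,
        p=p,
        n_subjects=n_subj,
        n_obs=n_obs,
        slope=b,
        n_subjects_excluded=excluded,
    )


def per_subject_spearman(subjects, x, y) -> pd.DataFrame:
    """Intra-individual Spearman correlations, one row per eligible subject.

    Subjects with constant x or y get NaN rho; subjects with exactly two
    pairs are rho = +/-1 by construction and are flagged ``low_n``.
    """
    data, _ = _complete_by_subject(subjects, x, y)
    rows = []
    for sid, grp in data.groupby("subject", sort=False):
        n = len(grp)
        if n < 3 or grp["x"].nunique() == 1 or grp["y"].nunique() == 1:
            if n == 2 and grp["x"].nunique() > 1 and grp["y"].nunique() > 1:
                rho = float(np.sign((grp["x"].diff() * grp["y"].diff()).iloc[-1]))
            else:
                rho = float("nan")
        else:
            rho, _ = spearman(grp["x"], grp["y"])
        rows.append(dict(subject=sid, rho=rho, n_pairs=n, low_n=n < 3))
    return pd.DataFrame(rows)
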