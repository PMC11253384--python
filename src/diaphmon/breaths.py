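"""Breath segmentation and per-breath / per-minute respiratory metrics.

Breaths are detected as positive-going zero crossings of a baseline-corrected
signal (transdiaphragmatic pressure when available, otherwise the diaphragm
displacement itself).  Baseline correction subtracts a centered rolling
median whose window (default 10 s) is much longer than a breath period and
much shorter than a session phase, so slow drift is removed without
distorting individual breaths.

Per-breath metrics:

* ``exdi`` — maximal diaphragm excursion: displacement rise from breath onset
  to the in-breath displacement maximum (cm).
* ``pcvdi`` — peak contraction velocity: maximum of the central-difference
  derivative of a 50-ms moving-average-smoothed displacement over the
  inspiratory rise (cm/s).
* ``pdi_peak`` — Pdi rise from onset to the in-breath Pdi maximum (cmH2O).
* ``ptpdi`` — pressure-time product: trapezoidal integral of the
  onset-referenced Pdi over the breath, negative parts clipped (cmH2O*s).
* ``vt`` — tidal volume: half the trapezoidal integral of |flow| over the
  breath (mL); an inspiration-only mode integrates positive flow instead.

Artifact rejection is automated: a breath is flagged invalid when its
amplitude exceeds ``k_mad`` median absolute deviations above the median
amplitude of its 3-minute neighborhood (coughs and swallows are transients
several times the typical breath amplitude).  Flags only — nothing is
deleted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter, uniform_filter1d

from .errors import MissingChannelError
from .signal_io import WaveformRecord

__all__ = [
    "DetectOptions",
    "RejectOptions",
    "detect_breaths",
    "reject_artifacts",
    "compute_breath_metrics",
    "breath_table",
    "trimmed_mean",
    "minute_summary",
    "write_breath_table",
    "DEFAULT_TIMEPOINTS",
]

DEFAULT_TIMEPOINTS = (1, 2, 3, 4, 5, 10, 20, 30)

#: amplitude floors for the adaptive detection threshold, per channel kind
AMPLITUDE_FLOOR = {"pdi": 0.5, "displacement": 0.05}


@dataclass(frozen=True)
class DetectOptions:
    """Breath-detection tuning knobs.

    ``min_amplitude`` of ``None`` selects the adaptive default: 10% of the
    record's median breath amplitude, floored at ``amplitude_floor`` (use
    0.5 cmH2O for Pdi, 0.05 cm for displacement).
    """

    min_duration_s: float = 0.5
    min_amplitude: float | None = None
    rel_amplitude: float = 0.10
    amplitude_floor: float = 0.5
    baseline_window_s: float = 10.0


@dataclass(frozen=True)
class RejectOptions:
    k_mad: float = 5.0
    neighborhood_s: float = 180.0
    min_duration_s: float = 0.5


def rolling_median_baseline(x: np.ndarray, fs: float, window_s: float = 10.0) -> np.ndarray:
    """Centered rolling median, computed on a ~25 Hz decimated copy.

    Decimation keeps the cost linear in record length at 200 Hz; the median
    over a 10 s window is insensitive to the within-window sample order, so
    the decimated estimate matches the full-rate one to within sample noise.
    """
    n = len(x)
    dec = max(1, int(fs // 25))
    xd = x[::dec]
    w = max(3, min(int(round(window_s * fs / dec)) | 1, 2 * len(xd) - 1))
    # circular padding: edge windows borrow a distant stretch of the record,
    # which for quasi-stationary breathing keeps the inspiratory duty cycle —
    # and hence the median — representative (reflection would double the
    # local phase and bias the baseline at the record edges)
    med = median_filter(xd, size=w, mode="wrap")
    if dec == 1:
        return med
    return np.interp(np.arange(n), np.arange(len(xd)) * dec, med)


def detect_breaths(
    signal: np.ndarray,
    fs: float,
    options: DetectOptions | None = None,
) -> list[tuple[int, int, int]]:
    """Segment a respiratory signal into breaths.

    Returns ``(onset_idx, peak_idx, end_idx)`` triples; each breath spans one
    positive-going zero crossing of the baseline-corrected signal to the
    next (the final breath runs to the end of the record), with the peak at
    the in-breath maximum of the corrected signal.  Candidates shorter than
    ``min_duration_s`` or smaller than the amplitude threshold are merged
    into their neighbors.  Degenerate signals yield an empty list.
    """
    opts = options or DetectOptions()
    x = np.asarray(signal, dtype=float)
    n = len(x)
    if n < 2 or np.ptp(x) == 0:
        return []
    c = x - rolling_median_baseline(x, fs, opts.baseline_window_s)

    pos = c > 0
    onsets = np.nonzero(pos[1:] & ~pos[:-1])[0] + 1
    if pos[0] and (n > 1 and c[1] >= c[0]):
        onsets = np.concatenate([[0], onsets])
    if onsets.size == 0:
        return []

    bounds = list(zip(onsets, np.append(onsets[1:], n)))

    amps = [float(np.max(c[a:b]) - c[a]) for a, b in bounds]
    thr = opts.min_amplitude
    if thr is None:
        thr = max(opts.rel_amplitude * float(np.median(amps)), opts.amplitude_floor)
    min_len = opts.min_duration_s * fs

    def ok(a: int, b: int) -> bool:
        return (b - a) >= min_len and (np.max(c[a:b]) - c[a]) >= thr

    # merge undersized candidates into a neighbor until stable
    changed = True
    while changed and len(bounds) > 1:
        changed = False
        for k, (a, b) in enumerate(bounds):
            if not ok(a, b):
                if k + 1 < len(bounds):
                    bounds[k + 1] = (a, bounds[k + 1][1])
                else:
                    bounds[k - 1] = (bounds[k - 1][0], b)
                del bounds[k]
                changed = True
                break
    if len(bounds) == 1 and not ok(*bounds[0]):
        return []

    return [(a, a + int(np.argmax(c[a:b])), b) for a, b in bounds]


def reject_artifacts(
    breaths: list[tuple[int, int, int]],
    signal: np.ndarray,
    fs: float,
    options: RejectOptions | None = None,
) -> np.ndarray:
    """Flag artifact-contaminated breaths; returns a boolean validity mask.

    A breath is invalid when its amplitude exceeds ``k_mad`` median absolute
    deviations above the median amplitude of breaths within the surrounding
    3-minute neighborhood, or when it is shorter than ``min_duration_s``.
    The MAD is floored at 5% of the neighborhood median so uniform trains
    with negligible spread are not flagged.
    """
    opts = options or RejectOptions()
    x = np.asarray(signal, dtype=float)
    m = len(breaths)
    valid = np.ones(m, dtype=bool)
    if m == 0:
        return valid
    onset_t = np.array([a / fs for a, _, _ in breaths])
    amps = np.array([float(np.max(x[a:b]) - x[a]) for a, _, b in breaths])
    durations = np.array([(b - a) / fs for a, _, b in breaths])
    half = opts.neighborhood_s / 2
    for k in range(m):
        if durations[k] < opts.min_duration_s:
            valid[k] = False
            continue
        if not math.isfinite(opts.k_mad):
            continue
        neigh = amps[np.abs(onset_t - onset_t[k]) <= half]
        med = float(np.median(neigh))
        # 1.4826 makes the MAD a consistent robust SD estimate, so k_mad
        # counts Gaussian-equivalent SDs; floored at 5% of the median so
        # near-constant trains are never flagged
        mad = 1.4826 * float(np.median(np.abs(neigh - med)))
        if amps[k] > med + opts.k_mad * max(mad, 0.05 * abs(med), 1e-12):
            valid[k] = False
    return valid


def compute_breath_metrics(
    record: WaveformRecord,
    breaths: list[tuple[int, int, int]],
    valid: np.ndarray | None = None,
    vt_mode: str = "full_cycle",
) -> pd.DataFrame:
    """Per-breath metric table for a segmented record.

    Metrics whose source channel is absent are left as NaN columns; the
    others are computed.  ``vt_mode`` is ``"full_cycle"`` (half the |flow|
    integral over the whole breath) or ``"inspiratory"`` (positive-flow
    integral only).
    """
    fs = record.fs
    m = len(breaths)
    out = pd.DataFrame(
        {
            "onset_idx": [a for a, _, _ in breaths],
            "peak_idx": [p for _, p, _ in breaths],
            "end_idx": [b for _, _, b in breaths],
        },
        dtype=int,
    )
    out["onset_s"] = record.t0 + out["onset_idx"] / fs
    out["duration_s"] = (out["end_idx"] - out["onset_idx"]) / fs
    out["valid"] = np.ones(m, dtype=bool) if valid is None else np.asarray(valid, bool)
    for col in ("exdi", "pcvdi", "pdi_peak", "ptpdi", "vt"):
        out[col] = np.nan

    if record.has("displacement"):
        disp = record["displacement"]
        smooth_n = max(1, int(round(0.05 * fs)))
        vel = np.gradient(uniform_filter1d(disp, smooth_n, mode="nearest"), 1.0 / fs)
        exdi = np.empty(m)
        pcvdi = np.empty(m)
        for k, (a, _, b) in enumerate(breaths):
            dpk = a + int(np.argmax(disp[a:b]))
            exdi[k] = disp[dpk] - disp[a]
            pcvdi[k] = float(np.max(vel[a:dpk + 1]))
        out["exdi"] = exdi
        out["pcvdi"] = pcvdi

    if record.has("pdi"):
        pdi = record["pdi"]
        pdi_peak = np.empty(m)
        ptp = np.empty(m)
        for k, (a, _, b) in enumerate(breaths):
            ppk = a + int(np.argmax(pdi[a:b]))
            pdi_peak[k] = pdi[ppk] - pdi[a]
            seg = np.clip(pdi[a:b] - pdi[a], 0, None)
            ptp[k] = float(np.trapezoid(seg, dx=1.0 / fs))
        out["pdi_peak"] = pdi_peak
        out["ptpdi"] = ptp

    if record.has("flow"):
        flow = record["flow"]
        vt = np.empty(m)
        for k, (a, _, b) in enumerate(breaths):
            seg = flow[a:b]
            if vt_mode == "inspiratory":
                vt[k] = float(np.trapezoid(np.clip(seg, 0, None), dx=1.0 / fs)) * 1000.0
            else:
                vt[k] = 0.5 * float(np.trapezoid(np.abs(seg), dx=1.0 / fs)) * 1000.0
        out["vt"] = vt
    return out


def breath_table(
    record: WaveformRecord,
    detect_channel: str | None = None,
    detect_options: DetectOptions | None = None,
    reject_options: RejectOptions | None = None,
    vt_mode: str = "full_cycle",
) -> pd.DataFrame:
    """Detect, artifact-flag and measure breaths in one record.

    Detection runs on Pdi when present (the conventional choice for sessions
    with an esophageal/gastric catheter), otherwise on displacement, with
    the amplitude floor matched to the channel.
    """
    if detect_channel is None:
        detect_channel = "pdi" if record.has("pdi") else "displacement"
    if not record.has(detect_channel):
        raise MissingChannelError(f"detection channel {detect_channel!r} absent")
    if detect_options is None:
        detect_options = DetectOptions(
            amplitude_floor=AMPLITUDE_FLOOR.get(detect_channel, 0.5)
        )
    sig = record[detect_channel]
    breaths = detect_breaths(sig, record.fs, detect_options)
    valid = reject_artifacts(breaths, sig, record.fs, reject_options)
    return compute_breath_metrics(record, breaths, valid, vt_mode=vt_mode)


def trimmed_mean(values, fraction: float = 0.05) -> float:
    """Mean after dropping floor(fraction*n) values from each tail.

    Empty input (after NaN removal) yields NaN rather than raising.
    """
    if not 0 <= fraction < 0.5:
        raise ValueError("fraction must lie in [0, 0.5)")
    v = np.sort(np.asarray(values, dtype=float))
    v = v[~np.isnan(v)]
    if v.size == 0:
        return float("nan")
    k = int(math.floor(fraction * v.size))
    return float(np.mean(v[k:v.size - k]))


def minute_summary(
    table: pd.DataFrame,
    sbt_start: float,
    timepoints=DEFAULT_TIMEPOINTS,
    end_s: float | None = None,
    trim_fraction: float = 0.05,
) -> pd.DataFrame:
    """Trimmed per-minute metric summaries at the requested SBT timepoints.

    Minute ``m`` covers ``[sbt_start + (m-1)*60, sbt_start + m*60)`` on the
    record's time axis; only valid breaths whose onset falls inside the
    window contribute.  Windows extending past ``end_s`` (a truncated SBT or
    the record end) are absent from the output.  Respiratory rate is the
    count of contributing breaths; the pressure-time product is summed over
    the window (cmH2O*s/min); derived indices: RSBI = rr / VT[L],
    diaphragm RSBI = rr / EXdi[mm], VT/EXdi in mL/cm.
    """
    rows = []
    for m in timepoints:
        if m <= 0:
            raise ValueError("timepoints must be positive minutes")
        w0 = sbt_start + (m - 1) * 60.0
        w1 = sbt_start + m * 60.0
        if end_s is not None and w1 > end_s + 1e-9:
            continue
        in_win = (table["onset_s"] >= w0) & (table["onset_s"] < w1)
        win = table[in_win]
        used = win[win["valid"]]
        rr = int(len(used))
        exdi_tm = trimmed_mean(used["exdi"], trim_fraction)
        pcvdi_tm = trimmed_mean(used["pcvdi"], trim_fraction)
        pdi_peak_tm = trimmed_mean(used["pdi_peak"], trim_fraction)
        vt_tm = trimmed_mean(used["vt"], trim_fraction)
        ptpdi_per_min = float(used["ptpdi"].sum()) if used["ptpdi"].notna().any() else float("nan")
        rows.append(
            dict(
                minute=m,
                rr=rr,
                exdi_tm=exdi_tm,
                pcvdi_tm=pcvdi_tm,
                pdi_peak_tm=pdi_peak_tm,
                ptpdi_per_min=ptpdi_per_min,
                vt_tm=vt_tm,
                rsbi=rr / (vt_tm / 1000.0) if vt_tm and not np.isnan(vt_tm) else float("nan"),
                dia_rsbi=rr / (exdi_tm * 10.0) if exdi_tm and not np.isnan(exdi_tm) else float("nan"),
                vt_over_exdi=vt_tm / exdi_tm if exdi_tm and not np.isnan(exdi_tm) else float("nan"),
                n_breaths_used=rr,
                n_rejected=int(len(win) - len(used)),
            )
        )
    return pd.DataFrame(rows)


def write_breath_table(df: pd.DataFrame, path, provenance: dict | None = None) -> None:
    """Serialize a breath or minute table with a ``#`` provenance header."""
    with open(path, "w", encoding="utf-8") as fh:
        for key, value in (provenance or {}).items():
            fh.write(f"# {key}={value}\n")
        df.to_csv(fh, index=False)
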