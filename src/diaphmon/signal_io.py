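"""Multichannel respiratory waveform records and their delimited text format.

A record bundles synchronously sampled channels for one patient session:
diaphragm displacement (cm), esophageal and gastric pressure (cmH2O), the
derived transdiaphragmatic pressure Pdi = Pga - Pes, airflow (L/s) and an
analog synchronization channel.  Records are stored as UTF-8 delimited text
with a ``#``-prefixed metadata header (sampling rate, patient id, session
phases, units) followed by one row per sample.

The time base is uniform sampling declared in the header; the time column in
the file is redundant and is validated on read, never trusted.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import FormatError, MissingChannelError, SynchronizationError

__all__ = [
    "WaveformRecord",
    "read_waveforms",
    "write_waveforms",
    "derive_pdi",
    "estimate_lag",
    "synchronize",
    "CHANNEL_COLUMNS",
]

# canonical channel name -> file column name
CHANNEL_COLUMNS = {
    "displacement": "disp_cm",
    "pes": "pes_cmh2o",
    "pga": "pga_cmh2o",
    "pdi": "pdi_cmh2o",
    "flow": "flow_lps",
    "sync": "sync",
}
_COLUMN_CHANNELS = {v: k for k, v in CHANNEL_COLUMNS.items()}

DEFAULT_UNITS = {
    "displacement": "cm",
    "pes": "cmH2O",
    "pga": "cmH2O",
    "pdi": "cmH2O",
    "flow": "L/s",
    "sync": "au",
}

#: relative jitter tolerance on the redundant time column
TIME_JITTER_TOL = 0.01


@dataclass
class WaveformRecord:
    """Synchronously sampled multichannel waveforms for one session.

    Parameters
    ----------
    fs : float
        Sampling rate in Hz (nominally 200).
    channels : dict of str to ndarray
        Named sample series of equal length; keys drawn from
        ``displacement, pes, pga, pdi, flow, sync``.
    t0 : float
        Time of the first sample, in seconds.
    patient_id : str, optional
        Subject identifier carried in the file header.
    phases : dict of str to (float, float)
        Session phase labels mapping to ``(start_s, end_s)`` intervals;
        intervals must be non-overlapping and lie within the record span.
    units : dict of str to str
        Unit string per channel; defaults applied for known channels.
    """

    fs: float
    channels: dict[str, np.ndarray]
    t0: float = 0.0
    patient_id: str | None = None
    phases: dict[str, tuple[float, float]] = field(default_factory=dict)
    units: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise FormatError(f"sampling rate must be positive, got {self.fs}")
        if not self.channels:
            raise FormatError("record must carry at least one channel")
        self.channels = {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}
        lengths = {k: len(v) for k, v in self.channels.items()}
        if len(set(lengths.values())) != 1:
            raise FormatError(f"channels have unequal lengths: {lengths}")
        for name in self.channels:
            self.units.setdefault(name, DEFAULT_UNITS.get(name, ""))
        span = (self.t0, self.t0 + self.n_samples / self.fs)
        ordered = sorted(self.phases.items(), key=lambda kv: kv[1][0])
        prev_end = None
        for name, (a, b) in ordered:
            if a > b:
                raise FormatError(f"phase {name!r} has start > end")
            if a < span[0] - 1e-9 or b > span[1] + 1e-9:
                raise FormatError(f"phase {name!r} lies outside the record span {span}")
            if prev_end is not None and a < prev_end - 1e-9:
                raise FormatError(f"phase {name!r} overlaps the previous phase")
            prev_end = b

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.n_samples / self.fs

    def time(self) -> np.ndarray:
        """Sample timestamps in seconds."""
        return self.t0 + np.arange(self.n_samples) / self.fs

    def __getitem__(self, name: str) -> np.ndarray:
        try:
            return self.channels[name]
        except KeyError:
            raise MissingChannelError(
                f"channel {name!r} not present (have {sorted(self.channels)})"
            ) from None

    def has(self, name: str) -> bool:
        return name in self.channels

    def slice_time(self, start_s: float, end_s: float) -> "WaveformRecord":
        """Sub-record covering [start_s, end_s) on the record's time axis."""
        i0 = max(0, int(np.ceil((start_s - self.t0) * self.fs - 1e-9)))
        i1 = min(self.n_samples, int(np.ceil((end_s - self.t0) * self.fs - 1e-9)))
        chans = {k: v[i0:i1] for k, v in self.channels.items()}
        return replace(self, channels=chans, t0=self.t0 + i0 / self.fs, phases={})


def write_waveforms(record: WaveformRecord, path) -> None:
    """Write a record to the delimited text format (6 significant digits)."""
    cols = [c for c in CHANNEL_COLUMNS if c in record.channels]
    buf = io.StringIO()
    buf.write(f"# fs_hz={record.fs:.10g}\n")
    if record.patient_id is not None:
        buf.write(f"# patient_id={record.patient_id}\n")
    for name, (a, b) in record.phases.items():
        buf.write(f"# phase:{name}={a:.10g},{b:.10g}\n")
    for name in cols:
        buf.write(f"# units:{CHANNEL_COLUMNS[name]}={record.units[name]}\n")
    buf.write("time_s," + ",".join(CHANNEL_COLUMNS[c] for c in cols) + "\n")
    t = record.time()
    data = np.column_stack([t] + [record.channels[c] for c in cols])
    # time to microsecond resolution; samples to 6 significant digits
    fmt = ["%.6f"] + ["%.6g"] * len(cols)
    np.savetxt(buf, data, fmt=",".join(fmt))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(buf.getvalue())


def _parse_header(lines: list[str]):
    fs = None
    patient_id = None
    phases: dict[str, tuple[float, float]] = {}
    units: dict[str, str] = {}
    for i, line in enumerate(lines, start=1):
        body = line[1:].strip()
        if "=" not in body:
            raise FormatError(f"line {i}: malformed header line {line!r}")
        key, _, value = body.partition("=")
        key = key.strip()
        value = value.strip()
        if key == "fs_hz":
            fs = float(value)
        elif key == "patient_id":
            patient_id = value
        elif key.startswith("phase:"):
            try:
                a, b = (float(x) for x in value.split(","))
            except ValueError:
                raise FormatError(f"line {i}: bad phase interval {value!r}") from None
            phases[key[len("phase:"):]] = (a, b)
        elif key.startswith("units:"):
            col = key[len("units:"):]
            if col in _COLUMN_CHANNELS:
                units[_COLUMN_CHANNELS[col]] = value
        else:
            raise FormatError(f"line {i}: unknown header key {key!r}")
    return fs, patient_id, phases, units


def read_waveforms(path) -> WaveformRecord:
    """Read and validate a waveform record from delimited text.

    The redundant ``time_s`` column must be strictly increasing and uniform
    to within 1% relative jitter; ``fs`` comes from the header when present,
    otherwise it is inferred from the median sample interval.

    Raises
    ------
    FormatError
        Malformed header, ragged rows, non-monotone or jittery time column.
    """
    with open(path, encoding="utf-8") as fh:
        raw = fh.read().splitlines()
    header_lines = []
    body_start = 0
    for i, line in enumerate(raw):
        if line.startswith("#"):
            header_lines.append(line)
            body_start = i + 1
        else:
            break
    fs, patient_id, phases, units = _parse_header(header_lines)
    if body_start >= len(raw):
        raise FormatError("file has no column header row")
    columns = [c.strip() for c in raw[body_start].split(",")]
    if not columns or columns[0] != "time_s":
        raise FormatError(f"line {body_start + 1}: first column must be time_s, got {columns[:1]}")
    unknown = [c for c in columns[1:] if c not in _COLUMN_CHANNELS]
    if unknown:
        raise FormatError(f"line {body_start + 1}: unknown columns {unknown}")
    try:
        df = pd.read_csv(
            io.StringIO("\n".join(raw[body_start:])),
            dtype=float,
            na_filter=False,
        )
    except (ValueError, pd.errors.ParserError) as exc:
        raise FormatError(f"malformed data rows: {exc}") from exc
    if df.shape[1] != len(columns):
        raise FormatError("ragged rows: column count varies")
    if len(df) < 2:
        raise FormatError("record must contain at least 2 samples")

    t = df["time_s"].to_numpy()
    dt = np.diff(t)
    bad = np.nonzero(dt <= 0)[0]
    if bad.size:
        raise FormatError(
            f"line {body_start + 2 + bad[0] + 1}: non-monotone time column"
        )
    dt_med = float(np.median(dt))
    jitter = np.abs(dt - dt_med) / dt_med
    bad = np.nonzero(jitter > TIME_JITTER_TOL)[0]
    if bad.size:
        raise FormatError(
            f"line {body_start + 2 + bad[0] + 1}: non-uniform sampling "
            f"(interval deviates {jitter[bad[0]]:.1%} from median)"
        )
    if fs is None:
        fs = 1.0 / dt_med
    channels = {_COLUMN_CHANNELS[c]: df[c].to_numpy() for c in columns[1:]}
    return WaveformRecord(
        fs=fs, channels=channels, t0=float(t[0]),
        patient_id=patient_id, phases=phases, units=units,
    )


def derive_pdi(record: WaveformRecord) -> WaveformRecord:
    """Add the transdiaphragmatic pressure channel, Pdi = Pga - Pes.

    Existing channels are untouched; calling twice is idempotent (the pdi
    channel is recomputed from pes/pga each time).
    """
    if not record.has("pes") or not record.has("pga"):
        raise MissingChannelError("derive_pdi requires both pes and pga channels")
    channels = dict(record.channels)
    channels["pdi"] = record["pga"] - record["pes"]
    units = dict(record.units)
    units["pdi"] = DEFAULT_UNITS["pdi"]
    return replace(record, channels=channels, units=units)


def estimate_lag(
    reference: WaveformRecord, other: WaveformRecord, max_lag_s: float = 10.0
) -> float:
    """Lag of `other` relative to `reference`, from their sync channels.

    Maximizes the cross-covariance of the demeaned sync channels over a
    bounded window (default +/-10 s); positive lag means `other`'s pulses
    occur later on its own time axis.
    """
    for rec, name in ((reference, "reference"), (other, "other")):
        if not rec.has("sync"):
            raise SynchronizationError(f"{name} record has no sync channel")
    if abs(reference.fs - other.fs) > 1e-9:
        raise SynchronizationError("records must share a sampling rate")
    fs = reference.fs
    a = reference["sync"] - reference["sync"].mean()
    b = other["sync"] - other["sync"].mean()
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise SynchronizationError("sync channel is constant; cannot align")
    max_lag = int(round(max_lag_s * fs))
    n = min(len(a), len(b))
    a, b = a[:n], b[:n]
    # full cross-covariance, then restrict to the lag window
    xc = np.correlate(a, b, mode="full")  # index k <-> lag = (n-1) - k
    lags = np.arange(-(n - 1), n)[::-1]
    mask = np.abs(lags) <= max_lag
    k = int(np.argmax(xc[mask]))
    return float(lags[mask][k]) / fs


def synchronize(
    reference: WaveformRecord, other: WaveformRecord, max_lag_s: float = 10.0
) -> WaveformRecord:
    """Time-shift `other` so its sync pulse train aligns with `reference`'s.

    The estimated lag (integer samples, so the residual after alignment is
    below one sample) is subtracted from `other`'s time origin.  Raises
    :class:`SynchronizationError` when the sync channel is flat or the
    records no longer overlap after the shift.
    """
    lag = estimate_lag(reference, other, max_lag_s)
    shifted = replace(other, t0=other.t0 - lag, phases={
        name: (a - lag, b - lag) for name, (a, b) in other.phases.items()
    })
    ref_span = (reference.t0, reference.t0 + reference.duration)
    oth_span = (shifted.t0, shifted.t0 + shifted.duration)
    if oth_span[0] >= ref_span[1] or oth_span[1] <= ref_span[0]:
        raise SynchronizationError(
            f"no temporal overlap after shifting by {lag:+.3f} s"
        )
    return shifted
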