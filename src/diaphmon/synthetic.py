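"""Synthetic respiratory waveforms and cohorts with known ground truth.

Emulates continuous diaphragm-monitoring sessions around a spontaneous
breathing trial (SBT): a 15-min baseline, a 30-min SBT (terminated early,
uniformly between minutes 3 and 30, in weaning-failure patients), and a
15-min recovery, all sampled at 200 Hz.

Each breath is a raised-cosine inspiratory rise of the diaphragm
displacement followed by an exponential expiratory relaxation (time constant
0.4 x expiratory duration).  Transdiaphragmatic pressure (Pdi) is a half-sine
over the inspiration whose amplitude couples linearly to the breath's
excursion (``pdi_gain``) plus zero-mean Gaussian amplitude noise — the knob
that sets the within-subject Pdi–excursion correlation.  Esophageal and
gastric pressure split the Pdi waveform so that Pga - Pes = Pdi holds exactly
at every sample.  Flow is the analytic time-derivative of a volume trace
whose per-breath tidal volume is proportional to the excursion.

Breath-to-breath excursions and between-patient mean excursions are
lognormal (group medians/IQRs of real weaning cohorts are right-skewed).
Cough/swallow artifacts are brief high-amplitude transients at a Poisson
rate, logged in the ground truth so downstream rejection can be validated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import InvalidParameterError
from .signal_io import WaveformRecord

__all__ = [
    "BreathPhenotype",
    "CohortParams",
    "GroundTruth",
    "PatientDataset",
    "Cohort",
    "simulate_breath_train",
    "simulate_patient",
    "simulate_cohort",
    "simulate_rmcorr_pairs",
    "SUCCESS_PHENOTYPE",
    "FAILURE_PHENOTYPE",
    "PES_BASELINE",
    "PGA_BASELINE",
]

#: resting esophageal / gastric pressure offsets (cmH2O); their difference is
#: the resting Pdi baseline, removed downstream by baseline correction
PES_BASELINE = -7.0
PGA_BASELINE = 3.0

#: sync channel: rectangular pulse train, 1 Hz, 50 ms pulses
SYNC_PULSE_HZ = 1.0
SYNC_PULSE_WIDTH_S = 0.05

#: Pdi amplitudes are clipped at this floor (cmH2O) so additive amplitude
#: noise cannot produce non-physiological negative efforts
PDI_AMPLITUDE_FLOOR = 0.5


def _lognormal(rng: np.random.Generator, mean: float, cv: float, size) -> np.ndarray:
    """Lognormal draws with the requested arithmetic mean and CV (cv=0 -> constant)."""
    if cv == 0:
        return np.full(size, mean, dtype=float)
    sigma2 = np.log1p(cv**2)
    mu = np.log(mean) - sigma2 / 2
    return rng.lognormal(mu, np.sqrt(sigma2), size)


@dataclass(frozen=True)
class BreathPhenotype:
    """Subject-level breathing pattern parameters.

    Defaults correspond to the weaning-success group of an SBT cohort
    (minute-2 medians: excursion 1.4 cm, peak velocity ~2.1 cm/s at a 0.45
    inspiratory fraction, respiratory rate 26/min, Pdi_peak ~14 cmH2O,
    tidal volume ~410 mL).

    Parameters
    ----------
    mean_exdi : float
        Mean per-breath diaphragm excursion, cm.
    exdi_cv : float
        Breath-to-breath coefficient of variation of excursion, in [0, 1).
    mean_rr : float
        Mean respiratory rate, breaths/min.
    rr_cv : float
        Breath-to-breath CV of the breath period, in [0, 1).
    pdi_gain : float
        Subject-level coupling of Pdi amplitude to excursion, cmH2O per cm.
    pdi_noise_sd : float
        SD of additive zero-mean noise on the per-breath Pdi amplitude,
        cmH2O.  Sets the within-subject Pdi–excursion correlation.
    vt_per_exdi : float
        Tidal volume per unit excursion, mL/cm.
    artifact_rate : float
        Cough/swallow transients per minute (Poisson).
    insp_fraction : float
        Inspiratory fraction of the breath period, in (0.2, 0.6).
    between_patient_cv : float
        Lognormal CV of the patient-level mean excursion multiplier used by
        the cohort generator (0 = identical patients).
    """

    mean_exdi: float = 1.4
    exdi_cv: float = 0.15
    mean_rr: float = 26.0
    rr_cv: float = 0.10
    pdi_gain: float = 10.0
    pdi_noise_sd: float = 9.0
    vt_per_exdi: float = 300.0
    artifact_rate: float = 0.5
    insp_fraction: float = 0.45
    between_patient_cv: float = 0.45

    def __post_init__(self) -> None:
        for name in ("mean_exdi", "mean_rr", "pdi_gain", "vt_per_exdi"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be > 0")
        for name in ("pdi_noise_sd", "artifact_rate", "between_patient_cv"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")
        if not 0.2 < self.insp_fraction < 0.6:
            raise InvalidParameterError("insp_fraction must lie in (0.2, 0.6)")
        for name in ("exdi_cv", "rr_cv"):
            if not 0 <= getattr(self, name) < 1:
                raise InvalidParameterError(f"{name} must lie in [0, 1)")

    @property
    def expected_pdi_exdi_r(self) -> float:
        """Within-subject Pearson correlation implied by the linear coupling."""
        signal_sd = self.pdi_gain * self.mean_exdi * self.exdi_cv
        if signal_sd == 0 and self.pdi_noise_sd == 0:
            return 1.0
        denom = np.hypot(signal_sd, self.pdi_noise_sd)
        return float(signal_sd / denom) if denom > 0 else 1.0


#: weaning-success group phenotype (minute-2 medians of the emulated cohort)
SUCCESS_PHENOTYPE = BreathPhenotype()

#: weaning-failure group: lower excursion/velocity, slightly faster rate,
#: higher pressure per unit excursion (effort preserved, motion reduced),
#: tidal volume per excursion raised accordingly
FAILURE_PHENOTYPE = BreathPhenotype(
    mean_exdi=0.8,
    mean_rr=27.0,
    pdi_gain=20.0,
    pdi_noise_sd=7.5,
    vt_per_exdi=550.0,
    between_patient_cv=0.30,
)


@dataclass(frozen=True)
class CohortParams:
    """Cohort-level generator parameters (seed fully determines all output)."""

    n_patients: int = 46
    failure_prevalence: float = 25 / 46
    success_phenotype: BreathPhenotype = SUCCESS_PHENOTYPE
    failure_phenotype: BreathPhenotype = FAILURE_PHENOTYPE
    snapshot_noise_sd: float = 0.3
    snapshot_bias: float = 0.1
    poor_agreement_fraction: float = 0.15
    seed: int = 0
    fs: float = 200.0
    baseline_min: float = 15.0
    sbt_min: float = 30.0
    recovery_min: float = 15.0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise InvalidParameterError("n_patients must be >= 2")
        if not 0 <= self.failure_prevalence <= 1:
            raise InvalidParameterError("failure_prevalence must lie in [0, 1]")
        if not 0 <= self.poor_agreement_fraction <= 1:
            raise InvalidParameterError("poor_agreement_fraction must lie in [0, 1]")
        if self.snapshot_noise_sd < 0:
            raise InvalidParameterError("snapshot_noise_sd must be >= 0")
        if min(self.baseline_min, self.sbt_min, self.recovery_min) <= 0:
            raise InvalidParameterError("phase durations must be > 0")
        if self.fs < 50:
            raise InvalidParameterError("fs must be >= 50 Hz")


@dataclass
class GroundTruth:
    """Per-breath truth channel emitted alongside every simulated record."""

    onset_t: np.ndarray   # s
    peak_t: np.ndarray    # s (displacement maximum = end of inspiration)
    end_t: np.ndarray     # s
    exdi: np.ndarray      # cm
    pcvdi: np.ndarray     # cm/s
    pdi_peak: np.ndarray  # cmH2O
    vt: np.ndarray        # mL
    artifact_intervals: list[tuple[float, float]] = field(default_factory=list)
    pdi_exdi_r: float = 1.0   # within-subject Pearson r implied by the phenotype
    outcome: str | None = None

    def __post_init__(self) -> None:
        if np.any(self.end_t[:-1] > self.onset_t[1:] + 1e-9):
            raise InvalidParameterError("breath intervals must be disjoint and ordered")

    @property
    def n_breaths(self) -> int:
        return len(self.onset_t)


def simulate_breath_train(
    phenotype: BreathPhenotype,
    duration: float,
    fs: float = 200.0,
    seed: int | np.random.Generator = 0,
) -> tuple[WaveformRecord, GroundTruth]:
    """Simulate one continuous multichannel breath train.

    Returns a :class:`WaveformRecord` with displacement, pes, pga, pdi, flow
    and sync channels, and the :class:`GroundTruth` of every fully contained
    breath.  Identical seed implies identical output.
    """
    if duration <= 0:
        raise InvalidParameterError("duration must be > 0")
    if fs < 50:
        raise InvalidParameterError("fs must be >= 50 Hz")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    mean_period = 60.0 / phenotype.mean_rr
    n_draw = int(duration / mean_period * 1.5) + 10
    periods = _lognormal(rng, mean_period, phenotype.rr_cv, n_draw)
    onsets = np.concatenate([[0.0], np.cumsum(periods)])[:-1]
    keep = onsets + periods <= duration + 0.5 / fs
    onsets, periods = onsets[keep], periods[keep]
    n_breaths = len(onsets)

    exdi = _lognormal(rng, phenotype.mean_exdi, phenotype.exdi_cv, n_breaths)
    pdi_amp = np.maximum(
        phenotype.pdi_gain * exdi + rng.normal(0, phenotype.pdi_noise_sd, n_breaths),
        PDI_AMPLITUDE_FLOOR,
    )
    vt = phenotype.vt_per_exdi * exdi  # mL

    n = int(round(duration * fs))
    t = np.arange(n) / fs
    disp = np.zeros(n)
    w = np.zeros(n)      # active Pdi waveform (0 between efforts)
    vol = np.zeros(n)    # L

    ti = phenotype.insp_fraction * periods
    tau = 0.4 * (periods - ti)
    disp_base = 0.0
    vol_base = 0.0
    for k in range(n_breaths):
        i0 = int(np.ceil(onsets[k] * fs - 1e-9))
        i1 = min(n, int(np.ceil((onsets[k] + periods[k]) * fs - 1e-9)))
        tloc = t[i0:i1] - onsets[k]
        insp = tloc < ti[k]
        rise = 0.5 * (1 - np.cos(np.pi * np.minimum(tloc, ti[k]) / ti[k]))
        seg = np.where(
            insp,
            disp_base + exdi[k] * rise,
            (disp_base + exdi[k]) * np.exp(-(tloc - ti[k]) / tau[k]),
        )
        disp[i0:i1] = seg
        w[i0:i1] = np.where(insp, pdi_amp[k] * np.sin(np.pi * tloc / ti[k]), 0.0)
        vt_l = vt[k] / 1000.0
        vol[i0:i1] = np.where(
            insp,
            vol_base + vt_l * rise,
            (vol_base + vt_l) * np.exp(-(tloc - ti[k]) / tau[k]),
        )
        disp_base = (disp_base + exdi[k]) * np.exp(-(periods[k] - ti[k]) / tau[k])
        vol_base = (vol_base + vt_l) * np.exp(-(periods[k] - ti[k]) / tau[k])

    # cough/swallow artifacts: half-sine transients, 5x the phenotype's
    # typical amplitude, 0.3-0.8 s, Poisson-distributed
    artifact_intervals: list[tuple[float, float]] = []
    n_art = rng.poisson(phenotype.artifact_rate * duration / 60.0)
    for _ in range(n_art):
        a_dur = rng.uniform(0.3, 0.8)
        a_start = rng.uniform(0.0, max(duration - a_dur, 1e-6))
        i0 = int(a_start * fs)
        i1 = min(n, int((a_start + a_dur) * fs))
        if i1 <= i0:
            continue
        shape = np.sin(np.pi * (t[i0:i1] - a_start) / a_dur)
        w[i0:i1] += 5.0 * phenotype.pdi_gain * phenotype.mean_exdi * shape
        disp[i0:i1] += 5.0 * phenotype.mean_exdi * shape
        artifact_intervals.append((a_start, a_start + a_dur))
    artifact_intervals.sort()

    flow = np.gradient(vol, 1.0 / fs)
    sync = ((t * SYNC_PULSE_HZ) % 1.0 < SYNC_PULSE_WIDTH_S * SYNC_PULSE_HZ).astype(float)
    pes = PES_BASELINE - 0.5 * w
    pga = PGA_BASELINE + 0.5 * w

    record = WaveformRecord(
        fs=fs,
        channels={
            "displacement": disp,
            "pes": pes,
            "pga": pga,
            "pdi": pga - pes,
            "flow": flow,
            "sync": sync,
        },
    )
    truth = GroundTruth(
        onset_t=onsets,
        peak_t=onsets + ti,
        end_t=onsets + periods,
        exdi=exdi,
        pcvdi=exdi * np.pi / (2 * ti),
        pdi_peak=pdi_amp,
        vt=vt,
        artifact_intervals=artifact_intervals,
        pdi_exdi_r=phenotype.expected_pdi_exdi_r,
    )
    return record, truth


@dataclass
class PatientDataset:
    """One simulated patient session: waveforms, truth, snapshot pairs."""

    patient_id: str
    outcome: str
    record: WaveformRecord
    truth: GroundTruth
    snapshots: pd.DataFrame  # patient_id, phase, metric, value_continuous, value_snapshot
    sbt_start_s: float
    sbt_end_s: float
    poor_agreement: bool = False


def _snapshot_rows(
    truth: GroundTruth,
    metric_values: dict[str, np.ndarray],
    mask: np.ndarray,
    take_last: bool,
    rng: np.random.Generator,
    bias: float,
    noise_sd: float,
    offset: float,
    patient_id: str,
    phase: str,
) -> list[dict]:
    """Paired continuous/snapshot values from 10 consecutive true breaths."""
    idx = np.nonzero(mask)[0]
    idx = idx[-10:] if take_last else idx[:10]
    rows = []
    ref_exdi = float(np.mean(metric_values["exdi"][idx]))
    for metric, vals in metric_values.items():
        cont = float(np.mean(vals[idx]))  # 5% trim of n=10 drops nothing
        scale = cont / ref_exdi if ref_exdi > 0 else 1.0
        snap = cont + scale * (bias + offset + rng.normal(0, noise_sd))
        rows.append(
            dict(
                patient_id=patient_id,
                phase=phase,
                metric=metric,
                value_continuous=cont,
                value_snapshot=snap,
            )
        )
    return rows


def simulate_patient(
    params: CohortParams,
    outcome: str,
    seed: int | np.random.Generator,
    patient_id: str = "P000",
    poor_agreement: bool = False,
    exdi_multiplier: float = 1.0,
) -> PatientDataset:
    """Simulate one patient session (baseline, SBT, recovery).

    Failure patients keep the failure phenotype throughout and terminate the
    SBT early, uniformly between minute 3 and the nominal SBT length.  Two
    paired continuous-vs-snapshot measurements per metric are produced, one
    just before the SBT and one just after, each the mean of 10 consecutive
    true breath values; the snapshot adds the configured bias and Gaussian
    noise, plus a patient-level offset for designated poor-agreement
    patients.
    """
    if outcome not in ("success", "failure"):
        raise InvalidParameterError(f"unknown outcome label {outcome!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    phen = params.failure_phenotype if outcome == "failure" else params.success_phenotype
    phen = replace(phen, mean_exdi=phen.mean_exdi * exdi_multiplier)

    sbt_dur = params.sbt_min
    if outcome == "failure":
        sbt_dur = rng.uniform(min(3.0, params.sbt_min), params.sbt_min)
    sbt_start = params.baseline_min * 60.0
    sbt_end = sbt_start + sbt_dur * 60.0
    total = sbt_end + params.recovery_min * 60.0

    record, truth = simulate_breath_train(phen, total, params.fs, rng)
    record = replace(
        record,
        patient_id=patient_id,
        phases={
            "baseline": (0.0, sbt_start),
            "sbt": (sbt_start, sbt_end),
            "recovery": (sbt_end, record.duration),
        },
    )
    truth.outcome = outcome

    # a poor-agreement patient carries an extra offset on ONE of the two
    # snapshot sessions (a transient state change between recordings), which
    # pushes that difference outside the pooled +/-2 SD limits without
    # inflating the overall difference SD in both phases
    offset_pre = offset_post = 0.0
    if poor_agreement:
        offset = rng.choice([-1.0, 1.0]) * 3.0 * max(params.snapshot_noise_sd, 0.1)
        if rng.random() < 0.5:
            offset_pre = offset
        else:
            offset_post = offset
    metric_values = {"exdi": truth.exdi, "pcvdi": truth.pcvdi}
    rows = _snapshot_rows(
        truth, metric_values, truth.end_t <= sbt_start, True, rng,
        params.snapshot_bias, params.snapshot_noise_sd, offset_pre, patient_id, "pre",
    )
    rows += _snapshot_rows(
        truth, metric_values, truth.onset_t >= sbt_end, False, rng,
        params.snapshot_bias, params.snapshot_noise_sd, offset_post, patient_id, "post",
    )
    return PatientDataset(
        patient_id=patient_id,
        outcome=outcome,
        record=record,
        truth=truth,
        snapshots=pd.DataFrame(rows),
        sbt_start_s=sbt_start,
        sbt_end_s=sbt_end,
        poor_agreement=poor_agreement,
    )


@dataclass
class Cohort:
    """A simulated cohort plus its patient-level table."""

    params: CohortParams
    patients: list[PatientDataset]

    @property
    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "patient_id": [p.patient_id for p in self.patients],
                "outcome": [p.outcome for p in self.patients],
                "poor_agreement": [p.poor_agreement for p in self.patients],
                "sbt_start_s": [p.sbt_start_s for p in self.patients],
                "sbt_end_s": [p.sbt_end_s for p in self.patients],
            }
        )

    def snapshot_pairs(self) -> pd.DataFrame:
        return pd.concat([p.snapshots for p in self.patients], ignore_index=True)


def cohort_labels(params: CohortParams) -> list[str]:
    """Deterministic stratified outcome labels: round(n x prevalence) failures."""
    n_fail = int(round(params.n_patients * params.failure_prevalence))
    labels = np.array(["failure"] * n_fail + ["success"] * (params.n_patients - n_fail))
    order = np.random.default_rng(
        np.random.SeedSequence([params.seed, 0x1ABE15])
    ).permutation(params.n_patients)
    return list(labels[order])


def simulate_cohort(params: CohortParams) -> Cohort:
    """Simulate a full cohort; per-patient seeds derive from the master seed.

    The failure count is assigned exactly (stratified), not by Bernoulli
    draws, so cohort-level tests are not flaky.  Poor-agreement patients are
    the first round(fraction x n) in a seed-determined shuffle.
    """
    labels = cohort_labels(params)
    n_poor = int(round(params.poor_agreement_fraction * params.n_patients))
    poor_order = np.random.default_rng(
        np.random.SeedSequence([params.seed, 0x9D00B])
    ).permutation(params.n_patients)
    poor = np.zeros(params.n_patients, dtype=bool)
    poor[poor_order[:n_poor]] = True

    master = np.random.SeedSequence(params.seed)
    patients = []
    for i, child in enumerate(master.spawn(params.n_patients)):
        rng = np.random.default_rng(child)
        phen = params.failure_phenotype if labels[i] == "failure" else params.success_phenotype
        mult = float(_lognormal(rng, 1.0, phen.between_patient_cv, ()))
        patients.append(
            simulate_patient(
                params,
                labels[i],
                rng,
                patient_id=f"P{i:03d}",
                poor_agreement=bool(poor[i]),
                exdi_multiplier=mult,
            )
        )
    return Cohort(params=params, patients=patients)


def simulate_rmcorr_pairs(
    n_subjects: int,
    n_pairs: int,
    r: float,
    seed: int | np.random.Generator = 0,
    x_mean: float = 1.2,
    x_sd: float = 0.25,
    y_slope: float = 10.0,
    between_sd: float = 5.0,
) -> pd.DataFrame:
    """Paired within-subject observations with a common correlation ``r``.

    Emulates minute-level (Pdi-derived, excursion-derived) pairs: each subject
    has a random intercept (``between_sd``) and within-subject Gaussian noise
    sized so the within-subject Pearson correlation equals ``r`` exactly in
    expectation.  Used to validate repeated-measures correlation recovery.
    """
    if not -1 < r < 1 or r == 0:
        if abs(r) >= 1:
            raise InvalidParameterError("r must lie strictly inside (-1, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    signal_sd = abs(y_slope) * x_sd
    noise_sd = signal_sd * np.sqrt(1 / r**2 - 1) if r != 0 else None
    rows = []
    for j in range(n_subjects):
        icpt = rng.normal(0, between_sd)
        x = rng.normal(x_mean, x_sd, n_pairs)
        if r == 0:
            y = icpt + rng.normal(0, signal_sd, n_pairs)
        else:
            y = icpt + np.sign(r) * y_slope * x + rng.normal(0, noise_sd, n_pairs)
        rows.append(pd.DataFrame({"subject": f"S{j:03d}", "x": x, "y": y}))
    return pd.concat(rows, ignore_index=True)
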