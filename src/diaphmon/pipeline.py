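"""End-to-end study orchestration: simulate -> breaths -> summaries ->
agreement / prediction / repeated-measures correlation.

A single master seed drives every stochastic stage (cohort generation and
the bootstrap), so a run is bit-reproducible: the same config and seed yield
byte-identical report files.  Results are written as machine-readable JSON
plus delimited tables, with a manifest recording the config and seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import agreement as agr
from . import prediction as pred
from .rmcorr import rmcorr as _rmcorr, per_subject_spearman
from .breaths import breath_table, minute_summary, write_breath_table, DEFAULT_TIMEPOINTS
from .errors import ConfigError, InvalidParameterError
from .synthetic import BreathPhenotype, CohortParams, simulate_cohort

__all__ = [
    "StudyConfig",
    "StudyReport",
    "run_study",
    "sample_size_two_proportions",
    "composite_failure_rate",
]

log = logging.getLogger("diaphmon")


@dataclass(frozen=True)
class StudyConfig:
    """Full configuration of one reproducible study run."""

    cohort: CohortParams = field(default_factory=CohortParams)
    timepoints: tuple[int, ...] = DEFAULT_TIMEPOINTS
    prediction_minute: int = 2
    prediction_metrics: tuple[str, ...] = ("exdi_tm", "pcvdi_tm")
    direction: str = "lower"
    bootstrap_B: int = 1000
    rmcorr_pairs: tuple[tuple[str, str], ...] = (
        ("pdi_peak_tm", "exdi_tm"),
        ("pdi_peak_tm", "pcvdi_tm"),
        ("ptpdi_per_min", "exdi_tm"),
        ("ptpdi_per_min", "pcvdi_tm"),
    )
    write_waveforms: bool = False

    @classmethod
    def from_mapping(cls, mapping: dict, seed: int | None = None) -> "StudyConfig":
        m = dict(mapping or {})
        cohort_map = dict(m.pop("cohort", {}))
        try:
            for key in ("success_phenotype", "failure_phenotype"):
                if key in cohort_map:
                    cohort_map[key] = BreathPhenotype(**cohort_map[key])
            if seed is not None:
                cohort_map["seed"] = int(seed)
            cohort = CohortParams(**cohort_map)
            for key in ("timepoints", "prediction_metrics"):
                if key in m:
                    m[key] = tuple(m[key])
            if "rmcorr_pairs" in m:
                m["rmcorr_pairs"] = tuple(tuple(p) for p in m["rmcorr_pairs"])
            return cls(cohort=cohort, **m)
        except (TypeError, InvalidParameterError) as exc:
            raise ConfigError(f"invalid study config: {exc}") from exc

    @classmethod
    def from_yaml(cls, path, seed: int | None = None) -> "StudyConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_mapping(yaml.safe_load(fh) or {}, seed=seed)


@dataclass
class StudyReport:
    """In-memory results of one study run (also serialized to ``outdir``)."""

    config: StudyConfig
    cohort_table: pd.DataFrame
    summaries: pd.DataFrame
    agreement: dict
    prediction: dict
    rmcorr: dict
    outdir: Path | None = None


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return v if math.isfinite(v) else repr(v)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def _dump_json(obj, path: Path) -> None:
    path.write_text(json.dumps(_jsonable(obj), indent=2, sort_keys=True) + "\n")


def _patient_summaries(cohort, timepoints) -> pd.DataFrame:
    """Minute summaries per patient over the full SBT, tagged with outcome."""
    frames = []
    max_minute = int(max(max(timepoints), math.ceil(cohort.params.sbt_min)))
    minutes = tuple(range(1, max_minute + 1))
    for p in cohort.patients:
        table = breath_table(p.record)
        summ = minute_summary(
            table, p.sbt_start_s, timepoints=minutes, end_s=p.sbt_end_s
        )
        summ.insert(0, "patient_id", p.patient_id)
        summ.insert(1, "outcome", p.outcome)
        frames.append(summ)
    return pd.concat(frames, ignore_index=True)


def _agreement_stage(pairs: pd.DataFrame) -> dict:
    out = {}
    for metric, grp in pairs.groupby("metric", sort=True):
        x = grp["value_continuous"].to_numpy()
        y = grp["value_snapshot"].to_numpy()
        ba = agr.bland_altman(x, y)
        diffs = {
            pid: list(g["value_snapshot"] - g["value_continuous"])
            for pid, g in grp.groupby("patient_id", sort=True)
        }
        classes = agr.classify_agreement(diffs, (ba.loa_low, ba.loa_high))
        pb = agr.passing_bablok(x, y)
        rho, p = agr.spearman(x, y)
        out[metric] = {
            "bland_altman": ba,
            "agreement_class": classes,
            "n_poor": sum(v == "poor" for v in classes.values()),
            "passing_bablok": pb,
            "spearman_rho": rho,
            "spearman_p": p,
            "n_pairs": int(len(grp)),
        }
    return out


def _prediction_stage(summaries: pd.DataFrame, config: StudyConfig, seed_seq) -> dict:
    minute = config.prediction_minute
    at_min = summaries[summaries["minute"] == minute].set_index("patient_id")
    labels = (at_min["outcome"] == "failure").to_numpy()
    out = {"minute": minute, "n_patients": int(len(at_min))}
    scores_by_metric = {}
    for i, metric in enumerate(config.prediction_metrics):
        scores = at_min[metric].to_numpy()
        scores_by_metric[metric] = scores
        roc = pred.roc_curve(scores, labels, config.direction)
        cutoff = pred.youden_cutoff(roc)
        diag = pred.diagnostic_metrics(scores, labels, cutoff, config.direction)
        boot = pred.bootstrap_roc(
            scores,
            labels,
            B=config.bootstrap_B,
            seed=np.random.default_rng(seed_seq.spawn(1)[0]),
            direction=config.direction,
        )
        out[metric] = {
            "auc": roc.auc,
            "auc_ci": [boot.auc_ci_low, boot.auc_ci_high],
            "cutoff": cutoff,
            "cutoff_ci": [boot.cutoff_ci_low, boot.cutoff_ci_high],
            "direction": config.direction,
            "diagnostics": diag,
        }
    metrics = list(config.prediction_metrics)
    if len(metrics) >= 2:
        dl = pred.delong_test(
            scores_by_metric[metrics[0]],
            scores_by_metric[metrics[1]],
            labels,
            direction=config.direction,
        )
        out["delong"] = {"metrics": metrics[:2], "result": dl}
    return out


def _rmcorr_stage(summaries: pd.DataFrame, config: StudyConfig) -> dict:
    out = {}
    usable = summaries[summaries["rr"] > 0]
    for xcol, ycol in config.rmcorr_pairs:
        sub = usable.dropna(subset=[xcol, ycol])
        try:
            res = _rmcorr(sub["patient_id"], sub[xcol], sub[ycol])
            per = per_subject_spearman(sub["patient_id"], sub[xcol], sub[ycol])
            out[f"{xcol}~{ycol}"] = {
                "rmcorr": res,
                "per_subject_spearman": per.to_dict(orient="records"),
            }
        except Exception as exc:  # a pair may be absent in reduced configs
            out[f"{xcol}~{ycol}"] = {"error": f"{type(exc).__name__}: {exc}"}
    return out


def run_study(config: StudyConfig, outdir=None) -> StudyReport:
    """Execute the full study pipeline on a simulated cohort.

    Stages: cohort simulation, per-patient breath tables and minute
    summaries, pooled pre+post method agreement, weaning-failure prediction
    at the configured minute, and repeated-measures correlation over SBT
    minutes.  Any stage failure is re-raised with the stage name.
    """
    stage = "simulate"
    try:
        cohort = simulate_cohort(config.cohort)
        stage = "summaries"
        summaries = _patient_summaries(cohort, config.timepoints)
        stage = "agreement"
        agreement = _agreement_stage(cohort.snapshot_pairs())
        stage = "prediction"
        seed_seq = np.random.SeedSequence([config.cohort.seed, 0xB007])
        prediction = _prediction_stage(summaries, config, seed_seq)
        stage = "rmcorr"
        rmcorr_out = _rmcorr_stage(summaries, config)
    except Exception as exc:
        raise type(exc)(f"stage {stage!r} failed: {exc}") from exc

    report = StudyReport(
        config=config,
        cohort_table=cohort.table,
        summaries=summaries,
        agreement=agreement,
        prediction=prediction,
        rmcorr=rmcorr_out,
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        cohort.table.to_csv(outdir / "cohort.csv", index=False)
        write_breath_table(
            summaries, outdir / "summaries.csv",
            provenance={"seed": config.cohort.seed, "n_patients": config.cohort.n_patients},
        )
        _dump_json(agreement, outdir / "agreement.json")
        _dump_json(prediction, outdir / "prediction.json")
        _dump_json(rmcorr_out, outdir / "rmcorr.json")
        _dump_json(
            {"config": config, "seed": config.cohort.seed},
            outdir / "manifest.json",
        )
        report.outdir = outdir
    return report


def composite_failure_rate(
    n_sbt_failures: int, n_reintubated: int, n_evaluable: int
) -> float:
    """Weaning-failure percentage under the composite definition.

    Failure = failing the SBT, or passing it but requiring reintubation
    within 48 h; the rate is the two counts pooled over evaluable patients,
    in percent.
    """
    if n_evaluable <= 0:
        raise InvalidParameterError("n_evaluable must be positive")
    if n_sbt_failures < 0 or n_reintubated < 0:
        raise InvalidParameterError("counts must be non-negative")
    if n_sbt_failures + n_reintubated > n_evaluable:
        raise InvalidParameterError("failures exceed evaluable patients")
    return 100.0 * (n_sbt_failures + n_reintubated) / n_evaluable


def sample_size_two_proportions(
    p1: float, p2: float, alpha: float = 0.05, power: float = 0.8, sided: int = 2
) -> float:
    """Normal-approximation sample size per group for two proportions.

    ``n = ceil((z_alpha*sqrt(2*pbar*qbar) + z_beta*sqrt(p1*q1 + p2*q2))^2
    / (p1 - p2)^2)`` with the pooled ``pbar``.  ``p1 == p2`` returns
    infinity.
    """
    if sided not in (1, 2):
        raise InvalidParameterError("sided must be 1 or 2")
    if not (0 < p2 <= p1 < 1):
        raise InvalidParameterError("require 0 < p2 <= p1 < 1")
    if p1 == p2:
        return float("inf")
    z_a = float(stats.norm.ppf(1 - alpha / sided))
    z_b = float(stats.norm.ppf(power))
    pbar = (p1 + p2) / 2
    num = (z_a * math.sqrt(2 * pbar * (1 - pbar))
           + z_b * math.sqrt(p1 * (1 - p1) + p2 * (1 - p2))) ** 2
    return float(math.ceil(num / (p1 - p2) ** 2))
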