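# diaphmon

Analytics for **continuous ultrasound monitoring of the diaphragm** during
weaning from mechanical ventilation.

In ventilated ICU patients, diaphragm function predicts whether a patient can
be liberated from the ventilator. A continuous, operator-independent
ultrasound monitor samples the craniocaudal displacement of the diaphragm at
200 Hz throughout a spontaneous breathing trial (SBT), alongside esophageal
and gastric balloon pressures and airflow. This package implements the full
analysis such a recording requires, plus a synthetic-data generator with
ground truth for every stage, so each statistical step can be validated
end to end.

## What it computes

**Per-breath signal metrics** (`diaphmon.breaths`). Breaths are segmented at
the positive-going zero crossings of the baseline-corrected
transdiaphragmatic pressure Pdi = Pga − Pes (or of the displacement itself
when no catheter channels exist). Per breath:

- EXdi — maximal diaphragm excursion (cm), displacement rise from onset to
  the in-breath maximum;
- PCVdi — peak contraction velocity (cm/s), max derivative of the smoothed
  displacement during inspiration;
- Pdi,peak (cmH₂O) and PTPdi = ∫ Pdi dt over inspiration (cmH₂O·s), the
  pressure–time product of inspiratory effort;
- VT — tidal volume (mL), half the |flow| integral per breath.

Minute-level summaries use a 10%-trimmed mean (5% off each tail) over each
1-minute window after SBT onset, with derived indices RSBI = RR/VT,
diaphragm RSBI = RR/EXdi and VT/EXdi. Coughs and swallows are flagged
automatically by a rolling median-absolute-deviation rule on breath
amplitude.

**Method agreement** (`diaphmon.agreement`). Continuous-monitor vs snapshot
(hand-held ultrasound) readings: Bland–Altman bias with limits of agreement
(bias ± 2·SD of differences) and a t-based CI of the bias; per-patient
good/poor agreement classification; Passing–Bablok rank regression (the
K-shifted median of all pairwise slopes) with its CUSUM linearity test;
Spearman correlation.

**Weaning-failure prediction** (`diaphmon.prediction`). ROC curves with an
explicit direction (low EXdi predicts failure), Youden-optimal cutoffs,
Clopper–Pearson exact CIs for sensitivity/specificity/PPV/NPV,
class-stratified bootstrap CIs, and the DeLong structural-component test for
comparing correlated AUCs.

**Repeated-measures correlation** (`diaphmon.rmcorr`). The common
within-subject association between minute-level effort (Pdi,peak, PTPdi) and
motion (EXdi, PCVdi) series via the shared-slope ANCOVA model
y = subject-intercepts + b·x, with
r_rm = sign(b)·√(SS_effect/(SS_effect+SS_error)) on
df = N − k − 1.

**Synthetic cohorts** (`diaphmon.synthetic`). Raised-cosine/exponential
breath trains at 200 Hz with outcome-dependent phenotypes, exact
Pga − Pes = Pdi conservation, configurable Pdi–EXdi coupling noise, cough
artifacts with a ground-truth log, paired continuous/snapshot measurements,
and stratified cohorts fully determined by one seed.

## Worked example

```python
from diaphmon import StudyConfig, run_study
from diaphmon.synthetic import CohortParams

cfg = StudyConfig(
    cohort=CohortParams(n_patients=12, seed=7, baseline_min=2.0,
                        sbt_min=5.0, recovery_min=2.0),
    timepoints=(1, 2, 3, 4, 5),
    bootstrap_B=200,
)
report = run_study(cfg, outdir="demo")
```

prints, via the snippets in the docstrings:

```
exdi agreement: bias -0.01 cm, LoA [-0.76, 0.73], n=24
Passing-Bablok: slope 1.34 (1.03-2.34), intercept -0.33
Spearman rho 0.79
minute-2 EXdi: AUC 0.91 (95% CI 0.71-1.00), Youden cutoff 1.00 cm
sens 1.00 (0.59-1.00), spec 0.80 (0.28-0.99)
rmcorr Pdi,peak~EXdi: r 0.39 (95% CI 0.08-0.63), df 37, p 0.0144
```

Reading this: the two "devices" agree with negligible bias and limits of
agreement of about ±0.75 cm over 24 paired measurements; the minute-2
excursion separates failure from success patients (AUC 0.91) with an optimal
cutoff near 1 cm; and after absorbing between-patient differences the
within-patient coupling between inspiratory pressure and excursion is
moderate (r = 0.39) in this small 12-patient cohort. At the full study scale
the generator is calibrated so this coupling is weak (r ≈ 0.2).

The same pipeline is scriptable from a shell:

```bash
diaphmon run --config study.yaml --seed 1 --out results/
diaphmon simulate --out sim/ --seed 1
diaphmon breaths --in sim/P000.csv --sbt-start 900 --out breaths/
```

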