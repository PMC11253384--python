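# Methods

This note records the models, numerical choices and known limitations behind
`diaphmon`, in the order data flows through the pipeline.

## Synthetic waveforms

Each breath is deterministic given its drawn parameters: the displacement
rises from the current baseline by the breath's excursion A along a raised
cosine over the inspiratory fraction of the period, then relaxes
exponentially toward zero with time constant τ = 0.4 × expiratory duration.
The raised cosine is smooth at both ends of inspiration and has peak velocity
A·π/(2·Ti), so the generator's "true PCVdi" has a closed form. The active
transdiaphragmatic pressure is a half-sine over inspiration with amplitude

    P = gain × A + ε,   ε ~ N(0, σ_P²),  clipped at 0.5 cmH₂O,

which makes the within-subject Pearson correlation between Pdi,peak and EXdi
exactly gain·sd(A) / √(gain²·sd(A)² + σ_P²). Esophageal and gastric pressure
split the active waveform around fixed resting offsets so Pga − Pes = Pdi
holds to machine precision at every sample. Flow is the analytic derivative
of a volume trace built like the displacement, with per-breath tidal volume
proportional to excursion. The synchronization channel is a 1 Hz rectangular
pulse train (50 ms pulses).

Breath-to-breath excursions and periods, and the patient-level mean-excursion
multiplier, are lognormal: group medians and interquartile ranges of
excursion in weaning cohorts are right-skewed, and lognormal keeps every
scale parameter positive.

### Default phenotypes (the conditions the cohort generator emulates)

| parameter | success | failure | basis |
|---|---|---|---|
| mean EXdi (cm) | 1.4 | 0.8 | group minute-2 medians |
| EXdi CV, within-subject | 0.15 | 0.15 | typical breath-to-breath variability |
| between-patient CV | 0.45 | 0.30 | group IQRs (0.9–2.2 / 0.6–1.0 cm) |
| RR (/min) | 26 | 27 | group medians |
| inspiratory fraction | 0.45 | 0.45 | PCVdi/EXdi ≈ 1.5 s⁻¹ = π/(2·Ti) |
| Pdi gain (cmH₂O/cm) | 10 | 20 | Pdi,peak medians ÷ EXdi medians |
| Pdi amplitude noise σ_P (cmH₂O) | 9.0 | 7.5 | sets within-subject r ≈ 0.23 / 0.30 |
| VT per EXdi (mL/cm) | 300 | 550 | VT medians ÷ EXdi medians |
| artifact rate (/min) | 0.5 | 0.5 | sparse coughs/swallows |

A session is 15 min baseline, 30 min SBT and 15 min recovery at 200 Hz;
failure patients terminate the SBT early, uniform between minute 3 and the
nominal length (the least-informative choice given only a failure count).
Outcome labels are assigned stratified — exactly round(n × prevalence)
failures — so cohort-level tests are not flaky. Cough artifacts are additive
half-sine transients of 0.3–0.8 s at 5× the phenotype's typical amplitude,
logged with their intervals so rejection can be scored against truth.

Paired device measurements: the "continuous" value is the mean of 10
consecutive true breath values (pre-SBT: last 10 baseline breaths; post-SBT:
first 10 recovery breaths); the "snapshot" adds a fixed bias (0.1 cm),
Gaussian noise (0.3 cm), and — for a designated 15% of patients — an extra
±3σ offset on one of the two sessions. The offset-on-one-session design
reproduces a poor-agreement subgroup (one difference outside the ±2 SD
limits) while keeping the pooled difference SD near 0.4 cm, i.e. limits of
agreement near ±0.8 cm. For velocity, bias and noise scale with the
patient's PCVdi/EXdi ratio so both metrics carry comparable relative error.

What the generator does **not** emulate: ventilator–patient asynchrony,
passive displacement under pressure support, sensor drift or loss of signal,
non-stationary breathing patterns, and any within-session evolution of the
phenotype (failure patients breathe with the failure phenotype from minute
zero). Tests passing on this generator therefore establish the correctness
of the estimators under the stated statistical structure, not the clinical
performance of any device.

## Breath segmentation and metrics

Baseline correction subtracts a centered rolling median (window 10 s — much
longer than any breath period, much shorter than a phase). The median is
computed on a ~25 Hz decimated copy and linearly interpolated back, which
keeps the cost linear at 200 Hz; edge windows use circular padding, because a
median over a stretch of quasi-stationary breathing is determined by the
inspiratory duty cycle and reflection would double the local phase and bias
the baseline at the record edges. Onsets are the positive-going zero
crossings of the corrected signal; each breath runs to the next onset (the
last to the record end). Candidates shorter than 0.5 s or smaller than
max(10% of the median breath amplitude, floor) are merged into a neighbor;
the floor is 0.5 cmH₂O for Pdi and 0.05 cm for displacement.

The per-breath metrics locate each channel's own in-breath peak: EXdi and
PCVdi use the displacement maximum, Pdi,peak and PTPdi the Pdi maximum. A
single shared peak index cannot serve both, since Pdi peaks mid-inspiration
(half-sine) while displacement peaks at end-inspiration. PTPdi integrates
the onset-referenced Pdi, negative excursions clipped, over the whole breath:
outside the active effort the integrand is zero by construction, and the
half-sine closed form 2AT/π is reproduced to <0.1% at 200 Hz. PCVdi
differentiates a 50 ms moving-average-smoothed displacement by central
differences — enough smoothing to suppress sample noise without biasing peak
velocity at 200 Hz. VT is half the trapezoidal integral of |flow| over the
breath (inspired plus expired volume, halved); an inspiration-only mode
(positive flow) is available when flow balance cannot be assumed.

Artifact flagging: a breath is invalid when its raw amplitude exceeds the
median of its 3-minute neighborhood by more than k_mad (default 5) robust
SDs, where the robust SD is 1.4826 × MAD, floored at 5% of the median.
The consistency constant matters: with plain MADs, 5 MADs is only ≈3.4
Gaussian SDs and the heavy amplitude noise used to produce weak
pressure–excursion coupling triggers rare false rejections; at ≈7.4 SDs,
honest breaths are essentially never flagged while 5×-amplitude artifacts
are flagged by an order of magnitude. Durations under 0.5 s are also
invalid. Flags only — nothing is deleted.

Minute windows are leading-edge: minute m covers [start+(m−1)·60, start+m·60)
and a window extending past the SBT end (truncated trials) is absent rather
than partial. The trimmed mean drops floor(0.05·n) values per tail, so
windows with fewer than 20 breaths are plain means. Diaphragm RSBI converts
EXdi to millimetres at the summary layer only (RR per mm is the convention
for that index); EXdi is carried in cm everywhere else.

## Agreement statistics

Bland–Altman uses d = y − x with limits of agreement bias ± 2·SD(d) —
the multiplier is 2, not 1.96, and configurable — and a t-based CI for the
bias on n−1 df. Both intervals are always reported because they answer
different questions (spread of individual differences vs precision of the
mean) and are easily conflated. A patient is classified poor-agreement when
at least one of their differences falls strictly outside the pooled limits;
a difference exactly on a limit is good.

Passing–Bablok follows the original 1983 procedure: all pairwise slopes with
0/0 pairs omitted, vertical pairs entered as signed infinities, slopes of
exactly −1 omitted; the estimate is the median shifted by K = #{slopes < −1},
which makes the estimator invariant to swapping the methods. Confidence
bounds come from the rank offsets w = z·√(n(n−1)(2n+5)/18) around the median
rank. Exact swap (b→1/b) and scale (y→cy) equivariance hold when the shifted
median is a single order statistic and no slopes cross −1 under the
transformation; the property tests construct data meeting those conditions.

The CUSUM linearity test accumulates residual signs (+√(M/L) per positive,
−√(L/M) per negative) in order of the score D = y + x/b and compares
max|cusum|/√(L+M) with the Kolmogorov–Smirnov 5% critical value 1.36. Two
calibration facts, both verified by simulation: referenced to a *known* line
(iid signs) the test holds its nominal size (≈5% at n=30); referenced to the
*fitted* line it is strongly conservative (empirical size ≈0.1%), as with
any KS-type test applied after parameter estimation — it is a guard against
gross nonlinearity, not an exact test. A Monte-Carlo permutation p-value
(`cusum_linearity_p`) is available when an explicit p is wanted.

## Prediction statistics

ROC thresholds sit at midpoints between consecutive distinct scores plus
infinite sentinels, and the direction (lower-predicts-positive for
excursion and velocity) is an explicit parameter, never inferred from the
data — the AUC is not forced above 0.5. Ties in FPR are ordered by TPR
before the trapezoid, which is exactly the tie-corrected Mann–Whitney
probability. The Youden cutoff breaks ties toward higher sensitivity
(missing a weaning failure is the costlier error), then toward more positive
calls, so it is deterministic. Proportions carry Clopper–Pearson exact CIs
(beta quantiles); zero-denominator proportions are NaN with CI [0, 1]. The
bootstrap resamples subjects with replacement within each outcome class (both
classes always present at the study's class sizes) and reports percentile
CIs for the AUC and the cutoff. The DeLong comparison uses placement values;
when the difference variance is exactly zero with equal AUCs (one marker a
monotone transform of the other) it reports z = 0, p = 1 rather than NaN.

## Repeated-measures correlation

Within-subject centering of x and y is algebraically identical to least
squares with subject as a categorical factor; the shared slope b and
r_rm = sign(b)·√(SS_eff/(SS_eff+SS_err)) follow from the centered
cross-products, with df = N − k − 1 for k subjects and N complete pairs.
The p-value is from F(1, df) and the CI from Fisher's z with standard error
1/√(df−1); a bootstrap CI was considered and not implemented because the
analytic interval covered the truth in ≥95% of calibration runs at the weak
coupling level (r = 0.22, 30 subjects × 25 pairs). Subjects contribute
whatever complete pairs they have; those with fewer than two are excluded
and counted. Unbalanced designs are the expected case. The implementation
agrees with the independent `pingouin` implementation to 9 decimals on
unbalanced data.

## Utilities and orchestration

The two-proportion sample size uses the standard normal-approximation
formula with pooled variance under the null; at rates 0.40 vs 0.10, α=0.05
two-sided, power 0.8 it gives 32 per group (25 one-sided). Study runs funnel
all randomness through one seed (cohort seeds spawn per-patient generators;
the bootstrap draws a separate child), so every output file is a pure
function of config + seed; the end-to-end test asserts byte-identical
reruns. Seeded validation runs use 46-patient cohorts with 1/3/1-minute
phases — the minute-2 analyses need only the first SBT minutes — while the
library defaults remain the full 15/30/15 session.

## Known limitations

- Detection on the displacement channel locates onsets at the corrected
  signal's zero crossing, which for displacement lags the true onset by a
  fraction of the rise; Pdi-based detection (the default when pressures
  exist) does not have this lag because Pdi rests at baseline between
  efforts.
- The artifact rule is amplitude-based; low-amplitude artifacts (swallows
  barely above the breath amplitude) are not separable from breaths.
- Passing–Bablok assumes comparable error in both methods; when one method
  is nearly noise-free the slope is biased away from 1, as visible in
  simulated device comparisons.
- No modelling of ineffective efforts or double triggering under mechanical
  insufflation.
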