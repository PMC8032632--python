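# Methods

This note records the models implemented in `workhrr`, the choices made
where the underlying field conventions leave room, and what the synthetic
validation does and does not establish.

## Beat-stream quality control (`ibi_qc`)

Raw input is a per-day stream of (timestamp, inter-beat interval, device
error flag). Cleaning is a fixed cascade — physiological range, neighbour
deviation, beat-error exclusion — followed by resampling. The cascade order
matters only at second order (each rule targets a different artifact class);
range first is the convention here because spuriously short/long intervals
would otherwise distort the neighbour comparison.

- **Range rule.** Beats with instantaneous rate below 36 or above 200
  beats/min are discarded. The rule is a strict inequality, so exactly
  36.0 and 200.0 beats/min are retained.
- **Neighbour rule.** A beat deviating by more than 15 % from *both*
  adjacent beats is discarded (isolated ectopics and missed/double
  triggers); edge beats are judged against their single neighbour. The
  deviation base is the symmetric relative difference
  `|a−b| / ((a+b)/2)`. A one-sided base (`|a−b|/b`) is available via
  `mode="previous"`, but the symmetric form is the default because it makes
  the filter idempotent: with an asymmetric base, removing an edge beat can
  newly expose its neighbour on a second pass. Idempotence is enforced by a
  property test.
- **Beat-error rule.** The error rate is evaluated on 60-s epochs; an epoch
  with more than 50 % flagged beats is dropped wholesale, and a measurement
  whose overall flagged fraction exceeds 50 % is invalid as a whole. The
  epoch length is a design choice — the device software that inspired the
  rule does not publish its window — and both the epoch-level and the
  whole-measurement readings are computed and reported separately.
  Individually flagged beats inside retained epochs are kept; the flag
  marks suspicion, the interval value itself is judged by the other rules.
- **Resampling.** Instantaneous heart rate (60000/IBI) is anchored at beat
  timestamps and linearly interpolated on a 4 Hz grid. Interpolation is done
  on heart rate, not on intervals-then-inverted; the two differ at second
  order and the HR-domain choice makes the affine-signal exactness property
  hold by construction. Samples inside beat gaps longer than `max_gap_s`
  (default 10 s) are masked invalid rather than interpolated — bridging a
  dropout would manufacture data.
- **Diary splitting.** Diary intervals are half-open `[start, end)` in
  seconds from local day start; overlapping intervals are a validation
  error naming the offending pair.

## Workload outcomes (`hrr`)

- `HR_min` is the minimum of the 10-beat moving average of instantaneous HR
  over the *whole* multi-day measurement (not per day): the sleeping trough
  is the stable anchor, and pooling days makes it robust to a single
  restless night. Fewer than 10 retained beats invalidates the measurement.
- `HR_max = 208 − 0.7·age` (Tanaka).
- %HRR values are clamped to [0, 100]; clamp events are counted in the QC
  report rather than silently absorbed, since work HR above the
  age-predicted maximum is informative about either the prediction or the
  signal.
- The peak outcome is the largest level x such that *cumulative* valid work
  time at or above x reaches one minute — computed as the value at rank
  ⌈60·4⌉ of the descending sorted samples, and cross-checked against a
  brute-force threshold scan. Cumulative (not contiguous) time is the
  natural reading of "spent at least 1 min"; a contiguous variant would be
  a different statistic and is intentionally not the default.
- The 30 %HRR cut-off composition uses "at or above" for the upper part;
  the two parts close exactly to the total valid work time.
- **Valid day:** ≥ 4 h of valid work-period HR, or ≥ 75 % of the worker's
  mean diary work duration across measured days. A worker needs ≥ 1 valid
  day. Outcomes pool all valid 4 Hz work samples with equal weight
  (sample-weighted), so longer valid days contribute proportionally more;
  a day-mean-of-means alternative would weight days equally regardless of
  coverage, and the sample-weighted form is primary here.

## Fitness estimation (`fitness`)

The Åstrand–Ryhming method extrapolates the linear HR–VO₂ relation at one
submaximal steady state to a sex-specific reference maximal HR. The
implementation uses the method's underlying linear model directly —
`VO2max = VO2(workload) · (HRref − HR0)/(HRss − HR0)` with anchors
(61, 195) beats/min for men and (72, 198) for women, and cycling oxygen
cost `VO2 = 0.002·kpm/min + 0.3` L/min (1 W = 6.12 kpm/min) — rather than a
transcription of the printed nomogram tables; the closed form reproduces
the tabulated cells to about ±0.1 L/min across the tabulated band and keeps
monotonicity and separability exact. Steady-state heart rates are accepted
only inside the tabulated band (120–170 beats/min); outside it the result
is missing, never extrapolated. Age correction uses the published factor
table (1.00 at age 25 down to 0.65 at 65), linearly interpolated and
clamped at the table ends.

Protocol rules: steady state is a change of strictly less than 5 beats/min
between minutes 5 and 6 (and between later consecutive minutes, up to the
10-min cap); a first-minute HR below 110 triggers a power increase
targeting `max(0.6·HRmax_pred, 120)` beats/min. The simulated session
harness inverts the full estimator (including the age factor) to derive the
steady HR a worker's true capacity implies, so a noiseless session
round-trips to the truth up to the convergence gap of the exponential HR
kinetics (τ = 1.2 min, about 1 % at termination).

## Association analysis (`coda_stats`)

- The two-part composition enters models as the ilr balance
  `z = ln(p_above/p_below)/√2`; positive z means more high-load time. A
  part equal to zero is replaced by one 4 Hz sample's worth of time
  (0.25 s / total), closure-preserving. Zeros are rare at realistic
  workloads but synthetic edge cases need a deterministic rule.
- Models are OLS with Wald 95 % CIs. The adjusted model always includes
  age, sex, self-rated health, shift, medication and occupation, retained
  regardless of significance; missing covariates are handled complete-case.
  Single-level factors (e.g. inside a small stratum) are dropped with a
  logged warning rather than failing the fit.
- The fitness × age interaction is the mean-centred product added to the
  adjusted model.
- Strata: age quartiles, occupation, steps/hour quartiles. Quartile
  boundaries come from the analysed sample (NumPy's default, type-7,
  quantiles); `pinned=True` fixes the age bands (≤37, 38–45, 46–51, ≥52)
  and the steps cut-offs (844.6, 1165.9, 1492.7) for replication-style
  runs. The stratifying covariate is removed from its own stratified model;
  strata below 20 workers are flagged unstable.
- The composition effect is reported as
  `Δ% = 100·[p(z̄ + b) − p(z̄)]` — the fitted ilr prediction at covariate
  means (equivalently the mean fitted z̄) moved by a +1 mlO₂/min/kg
  contrast, with CI endpoints mapped through the same curve. Other
  evaluation points or contrast sizes would give slightly different
  numbers for the same ilr slope; this one is the package's documented
  default and is exactly the map the generator inverts when calibrating.

## Synthetic generator (`synth`)

The generator's defaults are the study conditions: 497 workers; age
44 ± 9.8 truncated to 18–68; 41 % women; occupation mix
administration/cleaning/manufacturing/transportation =
15/9/67/8 %; shift mix 80/14/6 %; fitness 32 ± 8.9 mlO₂/min/kg (bounded
10–70) correlated −0.3 with age; 1–4 measured days with median 3 (IQR 2–3);
7.5-h work days with 8 h sleep. Configured means and SDs describe the
*generated sample*: the truncated-normal parameters are solved so the
post-truncation moments equal the configured ones. Outcome targets are
mean %HRR 30 ± 7.4, peak %HRR 57 ± 10.5, and a median 47 % of work time
above the cut-off with the ilr-scale SD (1.077) set from the printed
interquartile range (23–70 %).

Values the cohort description does not pin down were chosen once as
field-plausible and documented here: medication prevalence 25 %; body mass
80 ± 14 kg; steps/hour lognormal with parameters matched to the published
work-pace quartile cut-offs; residual correlations between the three
outcomes (0.5/0.6/0.4) so that a worker's peak load rarely falls below
their mean load; covariate offsets of at most 2 %HRR points for sex,
occupation and shift. Covariates are drawn independently of fitness, so the
unadjusted fitness slope is unbiased for the injected effect — the
condition under which parameter recovery against the injected value is
meaningful. Age has no direct outcome effect by default for the same
reason.

**Effect injection.** Outcomes follow linear models on the generator scale
with slopes −0.32 (mean %HRR), −0.35 (peak %HRR) per mlO₂/min/kg, and an
ilr slope derived by exactly inverting the Δ% back-transform at the
compositional median (Δ% = −1.8 → b_z ≈ −0.0512). Intercepts and residual
SDs are calibrated analytically (total variance minus the systematic parts)
so cohort summaries hit their targets without any post-hoc tuning. The
u-shaped age-interaction scenario assigns band-specific slopes
(−0.29/−0.37/−0.45/−0.28 for mean %HRR across the pinned bands) with
band-specific intercepts keeping every band centred. A separate
linear-interaction scenario (γ = −0.010 %HRR per year·unit on the centred
product) exists for power checks: with the u-shaped profile the *linear*
product term is nearly null by symmetry, so a linear-interaction power test
under that profile would be testing the wrong thing.

**Beat level.** Each day follows a piecewise-constant HR profile: sleep at
the worker's intended HR trough, leisure slightly above it, and a
three-level work block — a 2-min bout at the target peak, a mid level at or
above the cut-off and a low level below it — whose durations and levels are
solved so the derived outcomes equal the worker's targets. Targets outside
the solver's feasible region are projected into it, and the projected
values become that worker's ground truth, so beat streams and truth table
agree by construction. Beat-to-beat jitter is multiplicative lognormal and
defaults to zero: any jitter biases the windowed minimum-HR estimate
downward (a minimum over many noisy window means), which is a real
phenomenon but would confound the pipeline-correctness check the beat level
exists for. The end-to-end agreement requirement is |Δ| < 0.5 %HRR points
per outcome, absorbing resampling and segment-boundary interpolation
effects (measured agreement is ~0.01 points).

**Artifacts.** Injected at configured rates with an exact log of positions:
out-of-range interval values (25 and ~214 beats/min), isolated ectopic
beats (interval scaled ×1.35 or ×0.72 with untouched neighbours, spacing
enforced), runs of device-flagged beats, and non-wear gaps (beats deleted).
Artifact injection rewrites interval values without moving timestamps —
exactly how a device records a spurious interval. The QC suite requires
recall 1.0 on range violations and ≥ 95 % on isolated ectopics.

**What the synthetic validation shows.** That the pipeline computes the
intended quantities and that the analysis recovers known effects at the
study's n under the calibrated conditions. It does not establish robustness
to features real recordings have and the generator omits: genuine HRV
spectra, circadian drift, posture/activity-coupled HR, diary misreporting,
or correlated artifact bursts.

## Problem sizes and numerics

Recovery runs use 20 replicate metric-level cohorts of 497 workers
(seeds derived from one CLI seed); beat-level validation uses 20 workers at
1–4 days each; the ergometer round trip uses 50 workers. Tolerances in the
recovery tests are 2 Monte-Carlo SEs for effect estimates and 3 for cohort
calibration, i.e. scaled to the replicate spread rather than fixed
constants. Quantile conventions: NumPy default (type-7). Exceedance rank
uses `ceil(duration·fs)` so exactly one minute of samples suffices. The
stage RNG streams (cohort/outcomes/beats/artifacts/fitness) are spawned
independently from the scenario seed, so regenerating one stage never
perturbs another.

## Known limitations

- The metric-level fidelity draws outcomes from marginal linear models; it
  does not enforce `peak ≥ mean` per worker (violated in ~0.2 % of draws
  given the residual correlation), which the beat-level path does enforce.
- The Åstrand–Ryhming closed form stands in for the printed nomogram
  tables; absolute estimates can differ from table lookups by ~0.1 L/min.
- The whole-measurement beat-error exclusion and the epoch rule share one
  threshold; recordings with error bursts just under 50 % per epoch pass
  both.
- Day-level structure is fixed (same work window each day); real diaries
  vary, which mainly exercises the ≥ 75 %-of-usual validity arm less than
  real data would.
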