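# Methods

This note documents the models, parameters and numerical choices behind
`neobag`, what the synthetic cohort generator does and does not
emulate, and the known limitations of the statistical procedures.

## Respiration

The impedance-pneumography (IP) trace is expected at 62.5 Hz. Breath
detection runs on a zero-phase Butterworth band-pass (0.1–2 Hz, order
6, `sosfiltfilt`): the lower edge removes baseline wander, the upper
edge attenuates the neonatal cardiac component (~2.3 Hz) by ~86% after
forward-backward filtering. The filter is applied with 15 s of
reflection padding; the 0.1 Hz high-pass otherwise leaves a slow edge
transient that biases breath timing near the recording ends by tens of
milliseconds.

A peak of the filtered trace counts as a breath when its height exceeds
0.4 times the standard deviation of the signal over the span covering
the preceding 15 detected breaths; until 15 breaths exist, the SD of
the first 15 s of signal is used (the cold start is our choice — the
adaptive rule needs a bootstrap window). Two deliberate readings of the
rule:

* the threshold applies to peak *height*, not prominence — within a
  shallow-breathing segment consecutive small peaks have prominences
  about twice their heights, and the height criterion is what keeps
  segments at ≲0.35× the local amplitude undetected;
* the SD window ends at the most recent detected breath rather than at
  the current sample, so a long quiet segment cannot dilute the
  threshold and re-admit its own shallow breaths.

Breath times are refined by parabolic interpolation around the discrete
peak, which brings the inter-breath-interval (IBI) accuracy on clean
synthetic trains to a few milliseconds (well under one 16-ms sample).
Because the threshold is relative, detection is exactly invariant to
amplitude rescaling of the recording.

IBIs are successive breath-time differences. Candidates for central
apnoea are IBIs *strictly* longer than 15 s, measured
breath-peak-to-breath-peak. Each candidate window is screened by a
linear-kernel SVM (standardised features, C=1) using three features
computed on the **raw** trace with 2 s trimmed at each end: the RMS of
the gap interior relative to the surrounding ±15 s, the log variance of
the interior, and the fraction of interior power in the respiratory
band (0.1–2 Hz). During a true central apnoea the residual content is
cardiac artefact and wide-band noise, so all three features fall;
shallow breathing keeps a scaled-down oscillation inside the
respiratory band. The raw trace matters: on the filtered trace the
band-power feature is uninformative by construction. The published
screen's weights are not available, so the classifier is trained on
labelled synthetic candidate windows (balanced apnoea/shallow classes);
its held-out balanced accuracy on that benchmark is 1.0, and it is
reported with the trained object. Candidates rejected as noise/shallow
breathing are discarded entirely — they contribute neither to the
apnoea count nor to the median IBI.

Respiratory rate is 60/median(IBI) breaths/min; apnoea rate is accepted
apnoeas per hour over the span of the IBI series; recordings with fewer
than 100 IBIs after screening fail quality control.

## Desaturation

A desaturation event is a maximal contiguous run of SpO₂ samples
strictly below 80% lasting at least 10 s, one event per run (episodes,
not sliding windows, so events are countable into a rate). Missing
samples break runs. A `min_duration_s`/`threshold_pct` switch exposes
the alternatives.

## Sensory-evoked brain age

EEG is filtered with consecutive zero-phase high-pass (0.05 Hz) and
low-pass (33.75 Hz) Butterworth filters (order 6; ~98% attenuation at
50 Hz after filtfilt). Epochs run from −0.5 to 1.0 s around stimulus
onsets (visual at Oz, tactile at Cz), baseline-corrected by the mean
over [−0.5, 0) s; epochs too close to the recording edge are skipped
with a log entry. Epochs whose pre-stimulus amplitude strictly exceeds
±150 µV are flagged out; the rejection window is the available
pre-stimulus span (−0.5 to 0 s). Occasions with fewer than five
surviving sensory epochs fall back to the resting-state estimate alone.

Woody alignment is a single pass: each epoch is shifted by the
integer-sample lag (|lag| ≤ 50 ms) maximising its cross-correlation
with the template, where the template is the projection of the current
epoch average onto the modality's NRF subspace. Shifts zero-fill the
exposed edge; epoch count never changes.

The neurodynamic response functions (NRFs) are a fixed orthonormal
basis on the epoch grid — four visual, two tactile. The published basis
is not printed anywhere we can draw from, so the default is a synthetic
one: Hermite–Gaussian shapes orthonormalised by QR (deterministic,
pairwise dot products at machine zero). Real-data users must supply
their own basis; everything downstream only assumes orthonormal
waveforms on the epoch grid. Slopes are the joint OLS coefficients of
the *epoch average* onto the modality's NRFs (a `per_epoch=True` switch
fits each epoch and averages instead). The sensory age model is a
linear-kernel SVR (standardised inputs, C=10, ε=0.1) from the
six slopes to age, reported with a K-fold cross-validated MAE.

## Resting-state brain age (surrogate)

The published resting-state estimator is a deep network whose weights
are unavailable; `neobag` substitutes a transparent feature-based
surrogate that preserves the I/O contract exactly: first 20 min of
stimulus-free bipolar C3–C4 at 64 Hz (anti-aliased `resample_poly`;
shorter recordings are marked unavailable), 30-s epochs (40 of them), a
10-member ensemble prediction per epoch, median over members then
median over epochs. Members are ridge regressions (α=1) on per-epoch
features chosen for neonatal maturation plausibility: relative power in
0.5–3, 3–8, 8–15 and 15–30 Hz (normalised over 0.5–30 Hz), 95% spectral
edge frequency, 5th/95th amplitude percentiles, and the burst fraction
(time the 0.25-s smoothed rectified amplitude spends above the midpoint
of its 10th/90th percentile levels — a bimodal reference; a
median-relative threshold self-normalises and loses the maturation
signal). Each member trains on a bootstrap resample of recordings. All
accuracy claims about this estimator are surrogate-level: it reproduces
the aggregation scheme and its median robustness, not the published
network, and no comparison with the published held-out accuracy is
implied.

## Brain age gap

The occasion's brain age is the mean of the available sensory and
resting estimates (either alone when the other is unavailable; both
missing is an error). The age-bias correction is implemented as the
OLS residual of combined brain age on PMA. The verbal description of
the bias step admits two regression directions; the residual form is
the one that provably delivers the stated property — corrected gaps
have exactly zero mean and zero sample correlation with PMA — and it is
invariant to adding any affine function of PMA to the brain ages. A
`correct_bias=False` switch reproduces the raw gap (brain age − PMA).
Gap > 0 is classed mature; exactly 0 is classed immature (arbitrary but
fixed and tested).

## IBI probability densities

Per recording: a histogram of IBIs at 0.1-s resolution on [0, 50) s
(longer IBIs removed), scaled to unit area. Conditional densities along
PMA (31–36 wk) or gap (−3 to +3 wk) are built on a 1-day grid: each
recording is weighted by a Gaussian in its distance (days) from the
grid point — FWHM 13 days, σ = FWHM/(2√(2 ln 2)), hard zero beyond 14
days — and the conditional density is the per-bin *lower weighted
median* (smallest value whose cumulative normalised weight reaches 0.5;
with equal weights this is the ordinary lower median), renormalised to
unit area afterwards. Weighted medians of unit-area curves need not
integrate to 1, so the renormalisation preserves the unit-area
presentation; that choice, and the 1-day grid step, are ours. Grid
points with no recording inside the cutoff are marked empty. A
cumulative distribution accompanies each density for tail (log–log)
presentations, and `tail_mass` gives P(IBI > 15 s) per grid point.

## Association statistics

Four linear mixed-effects models (statsmodels MixedLM, REML, random
intercept per infant): apnoea rate and respiratory rate against PMA and
against the corrected gap. Infection status (no/suspected/treated)
enters every model as a fixed factor; IP data length enters the
apnoea-rate models only. Partial correlations are residual-on-residual:
outcome and predictor are each regressed (OLS, occasion level) on the
fixed covariates and the Pearson correlation of the residuals is
reported with a Fisher-z CI — there is no single canonical partial
correlation for a mixed model, so this construction is ours, computed
at the occasion level without conditioning on the random effect. Q-Q quantile tables are available for residual normality
checks. No multiple-testing correction is applied across the four
pre-specified models.

The predictor comparison bootstraps the apnoea~PMA partial correlation
over occasion resamples (default 10,000; an infant-level cluster
bootstrap sits behind a flag) and takes the one-tailed p as the
proportion of bootstrap coefficients at or below the observed
apnoea~gap coefficient. Degenerate resamples are redrawn and counted.
**Known limitation:** this is a point-versus-CI comparison; under a
null where both predictors carry an equal true association and are
independent, its one-sided rejection rate is Φ(−1.645/√2) ≈ 0.12 rather
than the nominal 0.05 (our simulations measure 0.15). The package
implements the procedure as described rather than the jointly
bootstrapped difference that would calibrate it; interpret the
one-tailed p accordingly.

E-values use the closed form E = RR + √(RR(RR−1)) after mapping RR < 1
to its reciprocal; the CI E-value uses the limit closest to the null
and equals 1 when the CI crosses it. Correlations are converted to an
approximate risk ratio via d = 2ρ/√(1−ρ²), RR ≈ exp(0.91·d) — one of
several published routes, provided for sensitivity analysis rather than
as a reproduction of any particular calculator.

The caffeine-stop analysis is an ordinary linear regression of the PMA
at caffeine discontinuation on the gap measured within two weeks
beforehand, with infection as the only fixed factor (no data-length
term: the EEG analysis window is fixed); it requires at least five
infants. The post-caffeine comparison reports mean ± SD apnoea and
desaturation rates in the 7 days after discontinuation by maturity
group, with group sizes per outcome (IP monitoring is not universal)
and no hypothesis test; `percent_reduction` rounds
100·(1 − mature/immature) to the nearest percent.

## Synthetic cohort generator

The generator defines the study conditions for every test: 74 infants,
1–3 occasions each (probabilities 0.38/0.38/0.24, ≈138 occasions), PMA
uniform on 31–36.9 wk, gestational age at birth ~N(31, 2.8²) clipped to
23.6–35.9 wk, infection frequencies 0.442/0.123/0.435. The latent gap
is N(0, 0.91²) marginally, split 50/50 between an infant-level
component and occasion noise — the shared part lets infant-level
quantities (caffeine-stop age, post-caffeine rates) depend on gap.
Expected apnoea rate is max(0, 1.0 − 0.22·gap + infant effect
(SD 0.25/h) + infection effect (0/0.15/0.3)); observed counts are
Poisson over the recording length (gamma-distributed, mean 8.5 h,
SD 8.7 h, clipped to 0.4–24 h). True respiratory rate is
55 − 1.87·(PMA − 34) plus an infant effect (SD 2) and observation noise
(SD 1.5). Caffeine stops at ~N(34 − 0.26·infant gap, 1.2²) wk PMA.
Desaturations couple to half the apnoeas plus a 0.1/h independent rate.
The apnoea-rate baseline (1.0/h), the effect sizes of infection, all
observation-noise scales and the coupling fraction are generator
choices, fixed once as plausible for a moderate/late-preterm cohort.

Signals: IP breath cycles are raised cosines with multiplicative
log-amplitude drift (σ=0.03/cycle), 4% cycle jitter, a cardiac sinusoid
at 2.3 Hz (10% of breath amplitude) and 5% white noise; inserted
apnoeas are breath-free pauses from a thinned Poisson process with
durations 15.2 s + Exp(5 s), so every inserted event satisfies the
>15-s definition. Evoked epochs are slope-weighted NRF sums (slopes
linear in brain age) with per-epoch latency jitter, white noise, and a
configurable fraction of large pre-stimulus artefacts. Resting EEG
alternates bursts (shared between C3 and C4) and inter-burst intervals
whose mean shrinks linearly from 5.5 s at 31 wk to 2.0 s at 36 wk,
with the amplitude of fast (8–25 Hz) continuous activity growing with
age — a documented generator law, a synthetic convention rather than
physiology. A single global seed fans out into per-recording
substreams (`numpy` SeedSequence), so generators are pure functions of
(parameters, seed) and adding a recording never perturbs the others.

What the generator does **not** emulate: obstructive or mixed apnoeas
(no airflow channel exists in the emulated montage), sleep states,
real IP morphology (unpublished), movement artefact structure,
bradycardia coupling, or any realistic EEG microstructure. Passing
recovery tests therefore demonstrates that the pipeline's algebra and
detection logic are correct under the stated generative assumptions —
not that the models would achieve comparable accuracy on clinical
recordings.

## Pipeline and problem sizes

`run_pipeline` composes all stages deterministically from (config,
seed) and writes plain-text artifacts; per-stage failures (e.g. a
caffeine-stop subset below five infants) are recorded in a manifest
while the rest of the run completes. The two brain-age models are
trained within the pipeline against PMA using infant-grouped
cross-validation, so every occasion is predicted by models that never
saw that infant — emulating normative-model transfer — and the bias
correction absorbs the resulting linear calibration error. (The
recovery *benchmark* instead trains against the generator's true brain
ages, emulating training on a normative cohort where brain age and
chronological age coincide; it reports sensory CV MAE ≈ 0.49 wk,
resting ≈ 0.17 wk, predicted-vs-true r ≈ 0.99 at the default
conditions, numbers recomputed by `scripts/acceptance.py`.) Cohorts
with fewer than 30 usable occasions are fitted in-sample, since
held-out folds would fall below the models' 20-occasion minimum.

Default desk-scale problem sizes, chosen as package defaults: IP traces
capped at 2 h per occasion (long enough that apnoea counts carry the
gap signal over Poisson noise), resting EEG generated at 128 Hz and
analysed at 64 Hz, evoked epochs on a 500 Hz grid, 15 visual + 10
tactile epochs per occasion. File mode exchanges two-column CSVs per
signal (EEG as channel-column CSV; no EDF I/O) plus a JSON ground-truth
sidecar and a `metadata.csv`; `validate_inputs` checks the bundle
schema without raising.

## Numerical conventions

* Strict inequalities at decision boundaries: apnoea IBI > 15 s,
  desaturation < 80%, artifact rejection |amp| > 150 µV, maturity
  gap > 0.
* Lower weighted median with a 1e-12 cumulative-weight tolerance
  against floating-point shortfall at exactly 0.5.
* Unit-area checks at 1e-9; bias-correction identities at 1e-10.
* MixedLM: statsmodels default optimiser with a Powell fallback;
  constant responses or predictors raise rather than fit.
* All seeds derive from one integer via SeedSequence substreams; seeds
  passed onward are kept below 2³¹.
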