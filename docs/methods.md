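# Methods

This note documents the models, parameter choices and numerical decisions
behind `divehrv`, and what the synthetic validation does and does not
establish about real data.

## Signal model and preprocessing

The pipeline assumes a single-lead ECG per subject-stage, sampled at
100 Hz, read from two-column CSV (`time_s,mv`).  Conditioning proceeds in
four deterministic steps:

**Baseline removal.** A running median over a 0.6 s window (shrinking at
the edges via nearest-sample padding) is subtracted.  The median tracks
drift below roughly 1/0.6 ≈ 1.7 Hz while passing the narrow R waves almost
unchanged; 0.6 s is long relative to the QRS complex (~0.1 s) and short
relative to respiratory/motion wander.

**Denoising.** A zero-phase 4th-order Butterworth band-pass, default
0.5–40 Hz with the upper edge clipped to 0.9·fs/2.  This stands in for
publication-specific adaptive denoisers with the same contract: peak
times shift by less than one sample on clean signals (verified against
the generator's ground-truth beat times).

**R-peak detection.** The amplitude threshold is half the median of
2-second block maxima, so it adapts to the prevailing R amplitude; a
0.27 s refractory period enforces the physiologic ceiling (~220 bpm).
Parabolic interpolation through the peak and its two neighbours refines
peak times below the sampling period.  At 100 Hz the quantization step is
10 ms — the same order as RMSSD itself — so sub-sample refinement
materially improves the short-term variability features; it can be
disabled (`refine=False`) to emulate acquisition-limited data.

**NN screening.** Intervals outside 270–2000 ms (30–220 bpm) or deviating
more than 30% from the running 5-beat median are replaced by
interpolation over the local median of accepted intervals.  A stage with
more than 20% rejected intervals raises `UnanalyzableStageError` and is
excluded, the automated analogue of excluding technically failed stages.
These thresholds are common HRV practice, not fitted values, and are
exposed as arguments.

**Instantaneous HR.** Beat times are resampled to 4 Hz by the Berger
method: the cumulative beat-count function (piecewise linear, slope 1/RR
within each interval) is differenced over a window of width 2/fs centered
on each output sample.  Constant RR maps to exactly constant HR, and the
integral of HR/60 conserves the beat count.  The analysis series then
discards the first 90 s of each 300 s stage (gas wash-in), anti-alias
filters (zero-phase 6th-order Butterworth at 0.45 Hz) and decimates to
1 Hz, removes trends below 0.01 Hz (a cut-off that preserves VLF content
above 0.01 Hz for the VLF feature) and subtracts the mean, yielding a
210-sample series.  A 120 s wash-in is supported for designs that
specify one; 90 s is the default because it matches the 210 s analysis
window arithmetic of a 5-minute stage.

## HRV features

Time-domain features are computed from the cleaned NN list restricted to
the analysis window; AR(2) features from the evenly sampled 1 Hz series.
Conventions worth stating:

* *NN50 family*: "more than 50 ms" is strict; `NN50count1` counts
  successive lengthenings, `NN50count2` shortenings, `NN50count` their
  sum.  The split into lengthenings and shortenings follows toolkit
  convention since the three counts are otherwise indistinguishable.
* *Poincaré*: SD1 is computed without mean subtraction,
  SD1 = √(mean((NNᵢ − NNᵢ₊₁)²)/2), so SD1 ≡ RMSSD/√2 holds exactly at
  lag 1; SD2 uses the sample variance of the rotated sum coordinate.
  The plot lag (default 1) is a parameter of `poincare`.
* *Approximate entropy*: Pincus ApEn with m = 2, r = 0.2·SD, Chebyshev
  distance, self-matches included.  Verified against a naive
  template-counting oracle.
* *AR(2)*: Burg estimation (stable on 210-sample series; Yule–Walker
  would need longer records for comparable bias), innovation variance
  normalized by the signal variance so white noise maps to ≈ 1.

Spectral features use `scipy.signal.welch` with 128-point Hann segments,
50% overlap and per-segment linear detrending; at 1 Hz this gives the
0.0078125 Hz bin spacing.  Band powers are trapezoidal integrals with the
exact band edges interpolated between bins, which makes adjacent bands
tile the spectrum exactly (VLF + LF + HF + 0.4–0.5 Hz residual = total to
machine precision).  Normalized units are defined as LF/(LF+HF) and
HF/(LF+HF); the alternative LF/(total−VLF) coincides when the 0.4–0.5 Hz
residual is negligible.  PowerRatio (power below vs above 0.6 Hz) is
computed on the 4 Hz Berger series because a 1 Hz series has no content
above 0.5 Hz; total power includes VLF.

## Principal dynamic modes

The HR series delayed by one sample serves as input u and the undelayed
series as output y of a second-order Volterra model expanded on 8
discrete orthonormal Laguerre functions with memory 60 samples (60 s at
1 Hz, a physiologic autonomic horizon — this is also why the 1 Hz series,
not the 4 Hz one, is the PDM substrate).  The Laguerre decay parameter
α = 0.5 makes every basis function fall below 5% of its peak within the
memory length; it is configurable.  The 45-parameter least-squares fit
carries a small ridge (λ = 10⁻⁶ × mean diagonal of the normal equations,
intercept unpenalized) because 210-sample series support the quadratic
fit only marginally.

The combined kernel matrix Q = [[c₀, c₁ᵀ/2], [c₁/2, C₂]] is symmetric;
its eigenvectors, constant component dropped and mapped through the
basis, are the unit-norm mode kernels.  Modes are sorted by |eigenvalue|
and the smallest prefix reaching 90% cumulative |eigenvalue| share is
selected (typically ≤ 4 modes).  Determinism is enforced by fixing each
eigenvector's sign so its largest-magnitude component is positive.

Band assignment uses the spectrum of each mode's *output* (the input
projected onto the mode, |K(f)|²S_u(f)) rather than the bare kernel
spectrum: one-step-prediction kernels are nearly all-pass, so only the
output spectrum localizes the band of dynamics a mode actually carries.
A mode peaking in 0.04–0.15 Hz is sympathetic, in 0.15–0.4 Hz
parasympathetic, otherwise unassigned.  The scalar features are
eigenvalue-weighted band-magnitude sums over the assigned modes:
Symp = Σ|λᵢ|·(LF magnitude of mode i), PSymp likewise over HF.  This
scalarization is explicit and versioned here; it is one reasonable
definition among several, chosen because it responds monotonically to
injected HF modulation amplitude (verified across seeded grids).  For
directly constructed kernels (no identification input) the kernel
spectrum is used instead.  When no mode is assigned to a band the
feature is exactly zero, and a zero baseline then makes the
percent-change value missing — so the PDM features legitimately carry
more missingness than the rest of the panel.

## Impairment scoring and normalization

A subtask is impaired when (baseline − score)/baseline ≥ 0.30, boundary
inclusive ("30% or more adverse change"); higher scores mean better
performance throughout.  The stage impairment score is the 0–4 count of
impaired subtasks; 1–4 collapse to the binary impaired label.  The
baseline is each subject's observed air-breathing resting stage
(group 01_air).  Stages with any missing subtask are dropped from
scoring.  `threshold_sensitivity` reproduces the threshold-selection
analysis: for each candidate threshold (15/30/45%), each subtask's
continuous score is regressed on the resulting stage score and the four
R² values reported.

HRV features are normalized to 100·(value − baseline)/|baseline|; the
absolute-value denominator preserves the sign of change for
negative-valued baselines (e.g. AR coefficients), and zero baselines
yield missing values rather than infinities.

## Association analysis

"Repeated-measures linear regression" is implemented as a linear mixed
model with a per-subject random intercept; a GEE with exchangeable
working correlation is selectable (`method="gee"`) as the other standard
reading.  The 0–4 score is treated as numeric, matching linear effect
estimates per covariate.  Each feature is tested in its own model
controlling for exercise and the high-N₂/CO₂/O₂ indicators; covariates
constant within a stratum are dropped automatically, and collinear
designs raise an error naming the offending columns.  Optimizer
fallback (lbfgs → bfgs → cg → powell) handles boundary variance
estimates.  Bonferroni adjustment multiplies by the number of features
tested in the family (25 for the full panel).  The interaction screen
fits one model with all 15 main-effect and product terms of the four
binary covariates — identified because the pooled design is a full 2⁴
factorial — reporting Wald F (1 df) per term.

Calibration (run in the test suite and the acceptance script): under a
null generator with subject random intercepts, the feature test's type-I
error at nominal 0.05 falls in [0.025, 0.085] over 200 cohorts of 37
subjects, and injected additive exposure effects of magnitudes
0.33/0.72/0.56/0.21 score units are recovered with correct sign and
within two pooled standard errors.

## Machine-learning evaluation

Folds are leave-one-subject-out.  Everything fitted — the z-score
standardizer, the SMOTE balancer, hyperparameter tuning — sees training
rows only (a sentinel test poisons the held-out subject and asserts the
training artifacts are bit-identical).  SMOTE is implemented in-repo:
each synthetic sample interpolates uniformly between a minority point and
one of its k = 5 nearest minority neighbours (Euclidean distance on
z-scored features, interpolation in original feature space), originals
preserved, classes balanced to the majority count; k is lowered with a
warning when the minority class is smaller than k + 1.  Grid search
(10-fold, F1) on the first training fold fixes hyperparameters for all
folds: SVM C ∈ {10⁻³…10³} (7 values), KNN k ∈ {2…5}, random forest
estimators ∈ {20,30,50,70,100} × depth ∈ {3,5,10,15,20}.  The canonical
operating point (KNN k = 3, SVM C = 1, RF 30 × 5) is contained in every
grid and can be passed directly via `params=` to skip tuning.  F1 uses
the impaired class for binary labels, macro averaging for the 0–4
multiclass surface; single-class test folds are excluded from the F1
mean.  The default 15-feature subset for ML is the time-domain panel —
the subset with the most direct physiological reading — and is
overridable.

## The synthetic cohort generator

The generator defines the study conditions for every test:

* **Design**: 16 pooled gas × exercise groups (8 resting, 8 exercising),
  instantiated once per 37 subjects by default (592 stages; optional
  random dropout emulates attrition to ~432 analyzable stages).  Partial
  pressures are fraction × pressure rounded to 2 decimals; where a
  printed design row is internally inconsistent, N₂ is treated as the
  balance gas so fractions sum to 1.  High-N₂ groups pool two chamber
  pressures (4.7/5.8 ATA), alternated across subjects.
* **RR series**: RR(t) = mean_rr + A_LF·sin(2π·0.1t) + A_HF·sin(2π·0.25t)
  + N(0, jitter²).  Additive sinusoids (rather than an integral pulse
  frequency modulation model) are the simplest mechanism with
  controllable band power, which is all the spectral/PDM validation
  requires; band power scales with amplitude².  Exposure maps to
  autonomic parameters with textbook directions: exercise shortens
  mean RR (−250 ms) and withdraws vagal modulation (HF ×0.35, LF ×0.6);
  CO₂ raises HF (×1.25) and shortens RR; O₂ raises HF mildly (×1.15) and
  lengthens RR; N₂ damps both bands (×0.8–0.9).  Defaults: mean RR
  900 ms ± 60 ms between subjects, A_LF = 35 ms, A_HF = 30 ms,
  jitter 10 ms.
* **ECG**: one stylized beat template (R spike with Q/S deflections,
  ~100 ms QRS whose energy sits below the 40 Hz conditioning edge) per
  beat time, plus sub-0.5 Hz sinusoidal wander and white noise; a 0.5 s
  pre-roll keeps the first beat fully rendered.  Peak recovery is the
  only contract — morphology, respiration coupling and arterial signals
  are not modeled.
* **MATB scores**: four subtask scores per stage, higher = better
  (polarity is a convention of this generator, stated explicitly).
  Expected fractional decrement is β·covariates applied multiplicatively
  to a per-subject baseline with multiplicative Gaussian noise
  (σ = 0.10).  Default betas (exercise 0.12, N₂ 0.10, CO₂ 0.08,
  O₂ 0.03) were chosen so the thresholded score distributions show the
  assumed pattern — resting stages mostly 0 with mild impairment,
  exercising stages spread over 1–4 — which is what makes the
  rest-vs-exercise classification contrast reproducible.  Decrement
  betas live on the fractional-performance scale; score-scale effect
  magnitudes (0.33/0.72/0.56/0.21) are exercised by the separate linear
  calibration generator `simulate_score_frame`, because a thresholded
  count cannot carry arbitrary linear effects additively.

What passing tests on this generator shows: the estimators recover known
injected structure (band powers, AR parameters, kernels, effect sizes)
and the statistical machinery is calibrated.  What it does not show:
performance on real diving ECG, which carries motion/respiratory
artifacts, ectopy, non-sinusoidal autonomic dynamics and
exposure-response heterogeneity that the generator deliberately omits.
In particular, feature–impairment coupling here flows entirely through
the shared exposure covariates, so conditional (covariate-adjusted)
feature associations are null by construction in the default cohort —
useful for calibration, but weaker than what a real autonomic pathway
might produce, and the synthetic SVR R² is accordingly modest.

## Numerical and degenerate-input policy

Zero-variance series: ApEn = 0, Poincaré r_RR missing, AR features
missing.  HF band power 0 makes LF/HF missing; an empty supra-0.6 Hz
band makes PowerRatio missing.  Q = 0 selects no modes and Symp = PSymp
= 0.  Fewer than 3 detected peaks, > 20% rejected intervals, or an
analysis window under 60 s mark the stage unanalyzable.  Welch refuses
series shorter than one segment rather than silently zero-padding.  All
preprocessing is RNG-free; every stochastic component (generators,
SMOTE, tuning) takes an explicit seed.

## Known limitations

Percent-change normalization is undefined for zero baselines (most often
the PDM features); the mixed models drop missing rows per feature, so
per-feature n varies.  The interaction screen reports Wald F with 1
numerator df rather than any specific repeated-measures
denominator-df method.  The PDM scalarization is one explicit choice,
not a canonical definition.  The exposure-to-autonomic parameter map is
plausible but schematic; its purpose is validation, not physiological
simulation.
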