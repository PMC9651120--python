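# Methods

This note documents the models and procedures implemented in `mhrv`, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical choices that matter when results
are compared across implementations.

## RR preprocessing

An R-peak series (seconds from recording start, strictly increasing) is
differenced into a tachogram: interval *i* spans `[peak_i, peak_{i+1})`, is
timed at its onset, and is stored in milliseconds. Three rejection rules
run in a fixed order and assign mutually exclusive flags:

1. **Range** — intervals outside 0.4–2 s are rejected. The bounds are read
   inclusively ("outside" taken strictly), so 400 ms and 2000 ms survive;
   both bounds are configurable.
2. **Successive difference** — an interval differing by strictly more than
   20% from the reference preceding interval is rejected. After a
   rejection, the reference stays at the most recent accepted interval
   (default), so one ectopic beat does not cascade into rejecting the rest
   of the recording; comparing against the raw predecessor is available via
   `reference="previous"` for sensitivity analyses.
3. **Neighbour** — a still-valid interval whose two immediate neighbours
   were both rejected by rules 1–2 is rejected too. This runs as a single
   pass (no fixed-point iteration; iterating changes results only on
   pathological inputs), and the first/last intervals, having one
   neighbour, are never rejected by this rule.

`clean()` recomputes flags from the interval values, so it is idempotent.
A recording is **usable** when at most 25% of intervals are rejected
(strictly-more-than-25% excluded).

For stages that need a uniformly sampled signal, the RR-versus-time
function anchored at valid-interval onsets is linearly interpolated across
rejected gaps and resampled at 4 Hz (configurable; 4 Hz is the common
choice for spectral/EMD tachogram analysis and comfortably oversamples the
0.1–0.5 Hz breathing band). Grid samples falling inside rejected intervals
are marked unreliable so downstream windows can be vetoed.

Median heart rate is the median of 60000/RR over valid intervals only,
consistent with the exclusion of unreliable data elsewhere.

## HRV features

- **SDNN**: sample standard deviation (n−1 denominator, as an estimator of
  the population SD from a finite recording) of valid intervals.
- **RMSSD**: RMS of differences between intervals *adjacent in the original
  tachogram* with both members valid; pairs spanning a rejected interval
  are excluded rather than differenced across the gap.
- **SampEn**: −ln(A/B) with embedding dimension m = 2 and tolerance
  r = 0.2 × SD of the analysed series (field-standard defaults; both
  configurable). A and B count ordered template pairs (i ≠ j) of lengths
  m+1 and m within Chebyshev distance r, both over the same N−m template
  set, distance ≤ r counting as a match. When either count is zero the
  entropy is undefined and reported as missing (NaN), never infinity.
  SampEn is computed on the ordered valid RR intervals, not on the
  interpolated series — interpolation manufactures regularity and would
  bias entropy downward. An option computes it on the instantaneous
  heart-rate series 60000/RR instead, since monotone pointwise transforms
  can change SampEn and the published description is ambiguous on this
  point.
- **Modelling transforms**: SDNN and RMSSD are right-skewed across
  measurements and enter the models as natural logs; SampEn is left-skewed
  and enters squared. Transforms are recorded and invertible.

## Breathing-rate estimation

The tachogram is an amplitude/frequency-modulated composite; respiratory
sinus arrhythmia is its highest-frequency physiological component, so the
first intrinsic mode function (IMF) of the 4 Hz resampled tachogram is
taken as the respiratory modulation.

- **Sifting**: upper/lower cubic-spline envelopes through local
  maxima/minima, with the two outermost extrema mirror-extended past each
  end to suppress spline end swings; the envelope mean is subtracted until
  the Cauchy-type criterion Σ(h_prev − h)² / Σ h_prev² < 0.2 (Huang-style
  convention) or 50 iterations. Decomposition stops when the residue has
  fewer than two extrema of either kind; the residue is defined as input
  minus extracted IMFs, so reconstruction is exact by construction.
- **Instantaneous frequency**: analytic-signal phase (Hilbert transform),
  unwrapped, differentiated by central differences, scaled by fs/2π; the
  first and last 2 samples are discarded as edge effects.
- **Segmentation**: 120 s windows advancing by 60 s (50% overlap); a
  partial trailing window is dropped rather than zero-padded (padding
  distorts low-frequency content). Windows with more than 5% unreliable
  samples are excluded.
- **Band limiting and the per-segment estimate**: instantaneous-frequency
  samples outside 0.1–0.5 Hz are discarded (the literal reading of
  filtering out out-of-band information), and the per-segment breathing
  rate is the **median of the in-band samples** × 60. An
  amplitude-weighted histogram mode (0.01 Hz bins) is available via
  `estimator="weighted_mode"`, but it is not the default: on resampled
  tachograms the beat-rate interpolation ripple phase-modulates the IMF,
  spreading the instantaneous frequency over ±0.05 Hz, and the mode of
  that jittered distribution lands one to two bins off (errors up to
  ~2 brpm at 18 brpm in validation), while the median stays within
  0.9 brpm across 9–24 brpm. The median is also what the recovery tests
  and acceptance checks exercise.
- **Per-measurement value and fallback**: median over OK segments; when a
  measurement has no usable segment it inherits the mean of the subject's
  other per-measurement medians (flagged `fallback_used`); a subject with
  no estimate at all is dropped from breathing-rate-dependent models and
  logged.

## Statistical models

All dependent variables are the transformed features. Covariates: age
(years), BMI (kg/m²), gestational age (decimal weeks, weeks + days/7),
parity (binary, 0 nulliparous / 1 parous; a numeric-parity mode keeps
counts), median HR (bpm), median BR (brpm), and optionally the fetal-CHD
flag during the screening step.

- **MLR**: ordinary least squares with intercept; overall F-test against
  the intercept-only model; adjusted R² = 1 − (1 − R²)(n − 1)/(n − p − 1).
- **LMM**: random-intercept model estimated by **maximum likelihood, not
  REML**, so the likelihood-ratio test against the fixed-effects-only model
  is valid (both models then maximise the same likelihood family). The LRT
  statistic 2Δlogℓ is clipped at zero and referred to the 50:50 mixture of
  a point mass at zero and χ²₁, the correct asymptotic null when a variance
  component sits on its boundary; the naive χ²₁ p-value is reported
  alongside for comparability with software that does not apply the
  correction.
- **ICC** = σ²_b/(σ²_b + σ²_e), the fraction of covariate-adjusted variance
  attributable to stable inter-subject differences.
- **Adjusted R² for the LMM** is not uniquely defined; this package reports
  the fixed-effects convention applied to conditional (random-effects-
  included) fitted values, 1 − (SSE/SST)(n − 1)/(n − p − 1) — it equals 1
  when residuals vanish — plus the Nakagawa-style marginal/conditional
  pseudo-R² pair, each labelled.
- **Diagnostics**: VIF per covariate (1/(1 − R²_j) with intercept; exact
  collinearity reported as infinite), leverage (hat diagonal; sums to
  p + 1), Cook's distance, normal-QQ series of residuals,
  fitted-vs-residual pairs, and the per-subject intercept estimates for the
  mixed model. Influential-row removal flags rows with D > 1.0 (an
  advisory list at D > 4/n is also reported), removes at most 2, refits,
  and itemises the before/after coefficients. The threshold is a default
  for a step the original analysis performed by visual contour inspection.
- **Effect curves**: each covariate swept over its empirical 5th–95th
  percentile range (binary covariates over {0, 1}) with the others at
  sample medians; pointwise 95% bands from the coefficient covariance
  (t-critical for OLS, normal for the LMM); the covariate p-value is
  attached for annotation when p < 0.05.
- **CHD screen**: each feature's MLR is fitted with and without the CHD
  flag; the flag is kept only when significant at α = 0.05. A constant CHD
  column makes the screen unidentifiable and it is skipped with a notice.
- **Multiple testing**: no correction is applied across the three features;
  reports state this.

## Synthetic data: what it emulates and what it does not

**Cohort level.** Ages are truncated normal (mean 31, SD 4.5, bounds
18–45); BMI is lognormal with median 22.8 and log-SD 0.17 (truncated above
15); the single design draws one gestational age near 20.4 weeks; the
repeated design walks the 10-visit schedule 14–40 weeks with independent
per-visit dropout (default 0.2, yielding a median of ~8 visits) and a
small within-week visit-day jitter. Parity and CHD are Bernoulli with
published prevalences (45.5% parous / 26.9% CHD for the single design;
34.5% / 0% for the repeated design). These settings reproduce the
published cohort medians and interquartile ranges; they are calibration
targets, not fitted quantities.

**Feature level.** y = β₀ + Xβ + b_subject + ε with b ~ N(0, σ²_b),
ε ~ N(0, σ²_e). Default effect sizes point the directions the analysis
found (HR dominant and negative on the time-domain features, GA negative,
BMI and parity null) with magnitudes chosen once so that, at the published
median covariates (HR 78 bpm, BR 14 brpm), the mean transformed response
matches the published feature medians; the default variance splits equal
the published Dataset-2 ICCs (0.48 / 0.68 / 0.28). Measurement-level
HR/BR covariates are truncated normals centred on the published medians.

**Signal level.** RR(t) = base + A_rsa·sin(2π f_br t) + A_lf·sin(2π·0.1
t + φ) + N(0, σ), advanced beat by beat (next peak = current + RR/1000).
Defaults: 1800 s, base 770 ms (≈78 bpm), A_rsa 30 ms, f_br 0.23 Hz
(≈14 brpm), A_lf 50 ms, σ 10 ms — chosen so SDNN/RMSSD land in the
published ranges and clean beats never violate the acceptance band.
Artifacts: per interval with a configurable probability, either a missed
beat (two intervals merged into one long RR) or a spurious beat (one
interval split at its midpoint); a truth mask marks corrupted intervals of
the output series.

**Limitations.** The RR model is additive-sinusoidal, not an
integral-pulse-frequency-modulation model: it provides analytic ground
truth for breathing rate and variance but does not reproduce the 1/f
spectral background, circadian drift, or HR-dependent RSA amplitude of
real recordings. The artifact model covers missed/spurious detections
only, not waveform-level noise. Consequently a green recovery test
establishes that the pipeline correctly extracts what the generator put in
(rates, variances, coefficients, corrupted beats); it does not certify
accuracy on clinical abdominal-ECG data, whose acquisition and R-peak
detection are out of scope here.

## Known estimator limitation: ML bias of the ICC at 29 subjects

Maximum-likelihood variance components are biased downward in small
samples because ML does not account for the degrees of freedom spent on
fixed effects (REML's purpose). With 29 subjects, an intercept plus five
further covariates of which roughly six directions carry between-subject
information, the between-subject variance is shrunk by roughly
(29 − 6)/29, giving E[ICC-hat] − ICC ≈ −0.04 to −0.05 at generating ICCs
0.28–0.68 (measured: −0.043, −0.048, −0.052 at 0.28, 0.68, 0.48 over 1000
replicates; the fit was verified against a direct profile-likelihood
optimisation, so this is the exact MLE, not an optimiser artifact). The
recovery tolerance of ±0.05 is therefore met for the RMSSD and SampEn
settings but marginally exceeded at generating ICC 0.48; the corresponding
acceptance test is left failing rather than widened, since the bias is a
property of the mandated ML estimator, not an implementation defect.
Switching the variance-component estimate to REML would remove the bias
but would invalidate the likelihood-ratio comparison as specified.

## Numerical conventions

- Times in seconds, intervals in milliseconds, rates in bpm/brpm; interval
  *i* spans `[peak_i, peak_{i+1})`.
- CSV interchange with 12-significant-digit floats; absent values (e.g. an
  unresolved breathing rate) serialised as empty fields.
- All generators are pure functions of their configuration including the
  seed; the CLI threads one base seed through every stage and the run
  manifest records it together with a configuration hash and exclusion
  counts that reconcile (rows into each model = usable measurements −
  missing-covariate drops − influential removals).
- Degenerate inputs fail loudly and specifically: fewer than two peaks,
  non-monotone peak times, zero-variance SampEn input, rank-deficient
  designs (offending columns named), non-convergent mixed fits.
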