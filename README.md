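# mhrv — maternal heart-rate-variability analysis

`mhrv` implements an end-to-end analysis pipeline for maternal heart-rate
variability (mHRV) in pregnancy: it turns per-measurement R-peak times into
cleaned tachograms, computes time-domain and entropy HRV features, estimates
the breathing rate from the tachogram itself, and fits the regression models
that separate the influence of demographics, cardiorespiratory state, and
stable inter-subject differences on mHRV.

It is aimed at researchers studying autonomic regulation in pregnancy —
for example when evaluating mHRV as a screening signal for pregnancy
complications — who need a tested, reproducible reference implementation of
the standard processing chain, together with a synthetic-data generator so
every stage can be validated without access to clinical recordings.

## The pipeline

1. **RR preprocessing** (`mhrv.preprocess`). R-peak times are differenced
   into a tachogram. An RR interval is rejected when it lies outside the
   physiological range 0.4–2 s, when it differs from the reference preceding
   interval by more than 20%, or when both of its immediate neighbours were
   rejected by the first two rules. Recordings with more than 25% rejected
   intervals are excluded. For stages that need a continuous signal, valid
   intervals are linearly interpolated across gaps and resampled at 4 Hz.

2. **HRV features** (`mhrv.features`). Per measurement: SDNN (standard
   deviation of all NN intervals), RMSSD (root mean square of successive
   NN differences), and sample entropy

   SampEn = −ln(A/B),

   where B counts template pairs of length m within Chebyshev tolerance
   r = 0.2·SD and A the same for length m+1 (m = 2, self-matches excluded).
   For modelling, SDNN and RMSSD are log-transformed and SampEn is squared.

3. **Breathing rate** (`mhrv.emd`). Respiratory sinus arrhythmia is the
   fastest oscillation in heart rate, so the first intrinsic mode function
   of the resampled tachogram (empirical mode decomposition, cubic-spline
   envelopes, Cauchy stop criterion) carries the respiratory modulation.
   Its Hilbert instantaneous frequency, restricted to 0.1–0.5 Hz, gives a
   breathing rate per 2-minute segment (50% overlap; segments with >5%
   unreliable samples are discarded); the per-measurement value is the
   median over segments, with a subject-average fallback.

4. **Statistical models** (`mhrv.models`). For each transformed feature y:

   - fixed effects only (multiple linear regression):
     y = β₀ + Xβ + ε, with X = (age, BMI, GA, parity, median HR, median BR);
   - random intercept (linear mixed model, fitted by maximum likelihood):
     y_ij = β₀ + X_ij β + b_i + ε_ij, b_i ~ N(0, σ²_b), ε_ij ~ N(0, σ²_e).

   The intra-class correlation ICC = σ²_b / (σ²_b + σ²_e) is the fraction
   of residual variance attributable to inter-subject differences. The two
   models are compared with a likelihood-ratio test using the boundary-
   corrected 50:50 χ²₀/χ²₁ mixture. Diagnostics include VIF, leverage,
   Cook's distance (with an itemised influential-row removal step), normal
   QQ series, and 5th–95th-percentile effect curves at covariate medians.

5. **Synthetic data** (`mhrv.simulate`). Cohort tables matching the
   published demographics, feature-level data from the generating mixed
   model above, and beat-by-beat RR series with RSA at a known breathing
   rate, slow modulation, noise, and missed/spurious-beat artifacts with a
   truth mask.

Estimator classes (`TachogramCleaner`, `HRVFeatureExtractor`,
`BreathingRateEstimator`, `HRVLinearModel`, `HRVMixedModel`) follow
scikit-learn conventions (`fit`/`transform`/`predict`, `get_params`,
fitted attributes with trailing underscores) and compose with sklearn
tooling; the module-level functions they wrap are the primary API.

## Worked example

Recovering a known variance decomposition from synthetic repeated
measurements (29 subjects, 8 visits each, generating ICC 0.68):

```python
from mhrv.simulate import CohortConfig, sample_cohort, simulate_features, DEFAULT_EFFECTS
from mhrv.models import frame_from_simulation, fit_lmm, fit_mlr, lrt

cohort = sample_cohort(CohortConfig.dataset2_like(
    seed=0, dropout_prob=0.0, ga_schedule=(14, 18, 22, 26, 30, 34, 38, 40)))
sim, truth = simulate_features(cohort, DEFAULT_EFFECTS["rmssd"], seed=0)
frame = frame_from_simulation(sim, "rmssd")
lmm, mlr = fit_lmm(frame), fit_mlr(frame)
test = lrt(lmm, mlr)
```

prints (via the obvious `print` statements):

```
generating ICC  : 0.68
estimated ICC   : 0.730
sigma2_b, sigma2_e: 0.2006, 0.0744
LRT statistic   : 212.9  (p = 1.6e-48)
median HR effect: -0.0292  (true -0.0300)
adjusted R2 (conditional): 0.82
```

A single replicate scatters around the generating value (here 0.73 vs
0.68); averaged over 200 replicates the estimate recovers the generating
ICC to within ±0.05 (see the acceptance suite). The likelihood-ratio test
decisively prefers the mixed model, and the fixed effect of median heart
rate is recovered close to its generating value.

The same analysis runs from the shell on CSV inputs:

```bash
mhrv simulate --config cfg.yaml --seed 1 --out data
mhrv run --rpeaks data/rpeaks.csv --cohort data/cohort.csv \
         --config cfg.yaml --seed 1 --out results
mhrv report --model-report results/model_report.json
```

which ends with a per-feature summary like

```
DV         F-stat  adjR2 MLR  adjR2 LMM    ICC
rmssd       349.2       0.96       0.97   0.08
sampen        6.8       0.31       0.31   0.00
sdnn          0.5      -0.04      -0.04   0.00
```

(in this small signal-level demo the subjects' baseline heart-rate
differences are absorbed by the median-HR covariate, so the residual ICC is
small — the feature-level generator above is the tool for studying the
variance decomposition itself). `results/` also contains the cleaned
tachograms, features, per-segment breathing rates, effect curves,
diagnostic series, and a manifest whose exclusion counts reconcile across
stages.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from scratch, the headline recovery quantity: it generates
repeated-measures feature data (29 subjects × 8 measurements) with the
between-subject variance fraction set to the published Dataset-2 RMSSD ICC,
fits the random-intercept mixed model by maximum likelihood in each of 200
seeded replicates, and writes the mean estimated ICC to the JSON file.

## Layout

```
src/mhrv/        preprocess, features, emd, models, simulate, io, cli
tests/           unit + property tests and the acceptance suite
docs/methods.md  models, assumptions, parameter defaults, limitations
scripts/         acceptance.py
```
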