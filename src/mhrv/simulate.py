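"""Synthetic cohorts, HRV features and RR series with known ground truth.

The clinical datasets behind this pipeline are not public, so every stage
is exercised on generated data instead.  Two levels are emulated:

* **feature level** — covariates drawn to match the published cohort
  characteristics (age median 31 years IQR 28–34, BMI median ~22.8,
  gestational schedule 14–40 weeks for the repeated design) and transformed
  HRV features drawn from a linear model with a per-subject random
  intercept, ``y = b0 + X beta + b_subj + eps``, so that mixed-model
  recovery of coefficients and the intra-class correlation can be checked
  against the generating truth;
* **signal level** — beat-by-beat RR series with respiratory sinus
  arrhythmia at a known breathing rate, a slow (0.1 Hz) modulation, white
  beat-to-beat noise, and optional missed-beat / spurious-beat artifacts
  with a truth mask, exercising the rejection rules and the EMD
  breathing-rate estimator.

The RR model is additive-sinusoidal rather than an integral-pulse-
frequency-modulation model: it gives analytic ground truth for breathing
rate and variance, which is what the tests need.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
import numpy as np
import pandas as pd

from .preprocess import RPeakSeries

__all__ = [
    "CohortConfig",
    "EffectConfig",
    "SignalConfig",
    "DEFAULT_EFFECTS",
    "sample_cohort",
    "simulate_features",
    "simulate_rr",
    "inject_artifacts",
]

#: gestational-age visit schedule of the repeated-measurements design, weeks
GA_SCHEDULE = (14, 18, 22, 24, 26, 30, 34, 36, 38, 40)


@dataclass(frozen=True)
class CohortConfig:
    """Generative parameters for cohort demographics.

    Defaults emulate the single-measurement cohort (290 women measured once
    around 20 weeks, 26.9% fetal-CHD); :meth:`dataset2_like` switches to the
    repeated design (29 women, ten scheduled visits with dropout).
    """

    n_subjects: int = 290
    design: str = "single"  # or "repeated"
    ga_schedule: tuple = GA_SCHEDULE
    dropout_prob: float = 0.2
    age_mean: float = 31.0
    age_sd: float = 4.5
    bmi_median: float = 22.8
    bmi_log_sd: float = 0.17
    parity_prob: float = 0.455  # P(parous); 54.5% nulliparous
    chd_prob: float = 0.269
    ga_single_mean: float = 20.4
    ga_single_sd: float = 1.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.design not in ("single", "repeated"):
            raise ValueError("design must be 'single' or 'repeated'")
        if not 0 <= self.dropout_prob < 1:
            raise ValueError("dropout_prob must be in [0, 1)")
        if self.age_sd <= 0 or self.bmi_log_sd <= 0:
            raise ValueError("dispersion parameters must be positive")

    @classmethod
    def dataset2_like(cls, seed: int = 0, dropout_prob: float = 0.2,
                      **kw) -> "CohortConfig":
        return cls(n_subjects=29, design="repeated", parity_prob=0.345,
                   chd_prob=0.0, dropout_prob=dropout_prob, seed=seed, **kw)


@dataclass(frozen=True)
class EffectConfig:
    """Generating linear model for one transformed DV.

    ``beta`` is keyed by covariate name on the transformed scale;
    ``sigma2_b`` and ``sigma2_e`` are the between-subject (random intercept)
    and residual variances, so the implied ICC is
    sigma2_b / (sigma2_b + sigma2_e).
    """

    dv_name: str
    intercept: float
    beta: dict
    sigma2_b: float
    sigma2_e: float

    def __post_init__(self) -> None:
        if self.sigma2_b < 0 or self.sigma2_e < 0:
            raise ValueError("variances must be non-negative")

    @property
    def icc(self) -> float:
        tot = self.sigma2_b + self.sigma2_e
        return self.sigma2_b / tot if tot > 0 else 0.0

    def with_icc(self, icc: float) -> "EffectConfig":
        """Re-split the total variance to hit a target ICC (total kept)."""
        if not 0 <= icc < 1:
            raise ValueError("icc must be in [0, 1)")
        tot = self.sigma2_b + self.sigma2_e
        return replace(self, sigma2_b=icc * tot, sigma2_e=(1 - icc) * tot)


# Effect sizes and variances calibrated once to the published medians
# (SDNN 47 ms, RMSSD 22.5 ms, SampEn 1.2 at HR ~78 bpm, BR ~14 brpm) and
# the published Dataset-2 ICCs (0.48 / 0.68 / 0.28); see docs/methods.md.
DEFAULT_EFFECTS = {
    "sdnn": EffectConfig(
        dv_name="sdnn",
        intercept=6.46,
        beta={"age": -0.008, "bmi": 0.0, "ga": -0.005, "parity": 0.0,
              "median_hr": -0.025, "median_br": -0.02},
        sigma2_b=0.48 * 0.15,
        sigma2_e=0.52 * 0.15,
    ),
    "rmssd": EffectConfig(
        dv_name="rmssd",
        intercept=6.23,
        beta={"age": -0.01, "bmi": 0.0, "ga": -0.012, "parity": 0.0,
              "median_hr": -0.03, "median_br": -0.01},
        sigma2_b=0.68 * 0.25,
        sigma2_e=0.32 * 0.25,
    ),
    "sampen": EffectConfig(
        dv_name="sampen",
        intercept=2.64,
        beta={"age": -0.005, "bmi": 0.0, "ga": -0.02, "parity": 0.0,
              "median_hr": -0.01, "median_br": 0.02},
        sigma2_b=0.28 * 0.5,
        sigma2_e=0.72 * 0.5,
    ),
}


@dataclass(frozen=True)
class SignalConfig:
    """Beat-by-beat RR generator parameters.

    RR(t) = base + rsa_amp sin(2 pi br t) + lf_amp sin(2 pi 0.1 t + phi)
            + N(0, noise_sd), milliseconds.  Defaults emulate a ~30-minute
    measurement at median HR ~78 bpm with breathing near 14 brpm.
    """

    duration_s: float = 1800.0
    base_rr_ms: float = 770.0
    rsa_amp_ms: float = 30.0
    br_hz: float = 0.23
    lf_amp_ms: float = 50.0
    noise_sd_ms: float = 10.0
    artifact_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 400 < self.base_rr_ms < 2000:
            raise ValueError("base_rr_ms must be in (400, 2000)")
        if not 0.1 <= self.br_hz <= 0.5:
            raise ValueError("br_hz must be within the breathing band [0.1, 0.5]")
        if not 0 <= self.artifact_rate <= 0.3:
            raise ValueError("artifact_rate must be in [0, 0.3]")
        worst = self.base_rr_ms - self.rsa_amp_ms - self.lf_amp_ms \
            - 6 * self.noise_sd_ms
        if worst <= 0:
            raise ValueError("modulation amplitudes allow non-positive RR")


def sample_cohort(cfg: CohortConfig) -> pd.DataFrame:
    """Draw a cohort table, one row per (subject, measurement).

    Ages are normal truncated to [18, 45]; BMI is lognormal around the
    target median, truncated above 15.  The single design draws one GA per
    subject near 20 weeks; the repeated design walks the visit schedule and
    thins visits independently with ``dropout_prob`` (keeping at least two
    visits per subject so mixed models stay identifiable).
    """
    rng = np.random.default_rng(cfg.seed)
    rows = []
    for s in range(cfg.n_subjects):
        sid = f"S{s + 1:03d}"
        age = _trunc_normal(rng, cfg.age_mean, cfg.age_sd, 18.0, 45.0)
        bmi = _trunc_lognormal(rng, math.log(cfg.bmi_median), cfg.bmi_log_sd, 15.0)
        parity = int(rng.random() < cfg.parity_prob)
        chd = int(rng.random() < cfg.chd_prob)
        if cfg.design == "single":
            ga = _trunc_normal(rng, cfg.ga_single_mean, cfg.ga_single_sd,
                               12.0, 42.0)
            rows.append((sid, f"{sid}_M01", age, bmi, ga, parity, chd))
        else:
            keep = rng.random(len(cfg.ga_schedule)) >= cfg.dropout_prob
            if keep.sum() < 2:  # keep the design identifiable
                keep[rng.choice(len(keep), size=2, replace=False)] = True
            m = 0
            for ga_w, k in zip(cfg.ga_schedule, keep):
                if not k:
                    continue
                m += 1
                ga = ga_w + rng.integers(0, 7) / 7.0  # visit day jitter
                rows.append((sid, f"{sid}_M{m:02d}", age, bmi, ga, parity, chd))
    return pd.DataFrame(
        rows,
        columns=["subject_id", "measurement_id", "age", "bmi", "ga",
                 "parity", "chd"],
    )


def _trunc_normal(rng, mean, sd, lo, hi) -> float:
    while True:
        v = rng.normal(mean, sd)
        if lo <= v <= hi:
            return float(v)


def _trunc_lognormal(rng, mu, sigma, lo) -> float:
    while True:
        v = rng.lognormal(mu, sigma)
        if v > lo:
            return float(v)


def simulate_features(
    cohort: pd.DataFrame,
    effects: EffectConfig,
    seed: int = 0,
    hr_mean: float = 78.0,
    hr_sd: float = 9.0,
    br_mean: float = 14.0,
    br_sd: float = 1.5,
) -> tuple[pd.DataFrame, dict]:
    """Transformed DV values from the generating linear mixed model.

    Measurement-level HR and BR covariates are drawn from truncated normals
    centred on the published medians when the cohort table does not already
    carry them.  Returns the feature table (transformed DV column named
    ``y``) and a truth record with all parameters and the per-subject
    random intercepts.
    """
    missing = [c for c in effects.beta if c not in cohort.columns
               and c not in ("median_hr", "median_br")]
    if missing:
        raise ValueError(f"cohort lacks covariates for beta: {missing}")
    rng = np.random.default_rng(seed)
    df = cohort.copy()
    n = len(df)
    if "median_hr" not in df.columns:
        df["median_hr"] = np.clip(rng.normal(hr_mean, hr_sd, n), 50.0, 120.0)
    if "median_br" not in df.columns:
        df["median_br"] = np.clip(rng.normal(br_mean, br_sd, n), 6.0, 30.0)

    subjects = df["subject_id"].unique()
    b = dict(zip(subjects,
                 rng.normal(0.0, math.sqrt(effects.sigma2_b), len(subjects))))
    eps = rng.normal(0.0, math.sqrt(effects.sigma2_e), n)
    # binary parity coding on the generating side as well
    Xp = df.assign(parity=(df["parity"].astype(float) > 0).astype(float))
    lin = np.full(n, effects.intercept)
    for name, coef in effects.beta.items():
        lin = lin + coef * Xp[name].to_numpy(dtype=float)
    y = lin + df["subject_id"].map(b).to_numpy() + eps
    out = df.assign(y=y)
    truth = {
        "dv_name": effects.dv_name,
        "intercept": effects.intercept,
        "beta": dict(effects.beta),
        "sigma2_b": effects.sigma2_b,
        "sigma2_e": effects.sigma2_e,
        "icc": effects.icc,
        "b_by_subject": {k: float(v) for k, v in b.items()},
        "seed": seed,
    }
    return out, truth


def simulate_rr(cfg: SignalConfig, subject_id: str = "SYN",
                measurement_id: str = "SYN_M01") -> RPeakSeries:
    """Beat-by-beat RR series: next peak time advances by RR(t)/1000."""
    rng = np.random.default_rng(cfg.seed)
    phi = rng.uniform(0, 2 * math.pi)
    peaks = [0.0]
    t = 0.0
    while True:
        rr = (
            cfg.base_rr_ms
            + cfg.rsa_amp_ms * math.sin(2 * math.pi * cfg.br_hz * t)
            + cfg.lf_amp_ms * math.sin(2 * math.pi * 0.1 * t + phi)
            + rng.normal(0.0, cfg.noise_sd_ms)
        )
        if rr <= 0:
            raise ValueError("generated non-positive RR; check amplitudes")
        t += rr / 1000.0
        if t > cfg.duration_s:
            break
        peaks.append(t)
    series = RPeakSeries(subject_id=subject_id, measurement_id=measurement_id,
                         peak_times=np.array(peaks))
    if cfg.artifact_rate > 0:
        series, _ = inject_artifacts(series, cfg.artifact_rate,
                                     seed=cfg.seed + 1)
    return series


def inject_artifacts(
    peaks: RPeakSeries, rate: float, seed: int = 0
) -> tuple[RPeakSeries, np.ndarray]:
    """Corrupt a clean series with missed beats and spurious beats.

    Each interval independently triggers an artifact with probability
    ``rate``: a missed beat merges it with the next interval (one long RR),
    a spurious beat splits it at the midpoint (two short RRs).  The returned
    truth mask marks corrupted intervals of the *output* series.
    """
    if not 0 <= rate <= 0.3:
        raise ValueError("rate must be in [0, 0.3]")
    rng = np.random.default_rng(seed)
    rr = np.diff(peaks.peak_times)
    out_rr: list[float] = []
    mask: list[bool] = []
    i = 0
    while i < len(rr):
        if rate > 0 and rng.random() < rate:
            if rng.random() < 0.5 and i + 1 < len(rr):  # missed beat
                out_rr.append(rr[i] + rr[i + 1])
                mask.append(True)
                i += 2
                continue
            out_rr.append(rr[i] / 2)  # spurious beat at the midpoint
            out_rr.append(rr[i] / 2)
            mask.extend([True, True])
            i += 1
            continue
        out_rr.append(rr[i])
        mask.append(False)
        i += 1
    new_peaks = peaks.peak_times[0] + np.concatenate(
        [[0.0], np.cumsum(out_rr)]
    )
    return (
        RPeakSeries(subject_id=peaks.subject_id,
                    measurement_id=peaks.measurement_id,
                    peak_times=new_peaks),
        np.asarray(mask, dtype=bool),
    )
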