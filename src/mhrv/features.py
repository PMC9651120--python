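"""Time-domain and entropy HRV features, plus the distribution-normalising
transforms used by the regression layer.

SDNN and RMSSD are computed on accepted (NN) intervals; SampEn is computed
on the ordered sequence of accepted RR intervals (not the interpolated
series, which would manufacture regularity and bias entropy downward).
SDNN and RMSSD are right-skewed across measurements and are log-transformed
before modelling; SampEn is left-skewed and is squared.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.base import BaseEstimator, TransformerMixin

from .preprocess import Tachogram, median_hr

__all__ = [
    "SampEnParams",
    "HRVFeatures",
    "TransformedDV",
    "HRVFeatureExtractor",
    "sdnn",
    "rmssd",
    "sampen",
    "sampen_match_counts",
    "transform_dv",
    "inverse_transform_dv",
    "DV_TRANSFORMS",
]

#: transform applied to each dependent variable before regression
DV_TRANSFORMS = {"sdnn": "log", "rmssd": "log", "sampen": "square"}


@dataclass(frozen=True)
class SampEnParams:
    """Sample-entropy parameters: embedding dimension ``m`` and tolerance
    ``r_frac`` as a fraction of the series standard deviation (Richman &
    Moorman defaults m=2, r=0.2*SD)."""

    m: int = 2
    r_frac: float = 0.2

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.r_frac <= 0:
            raise ValueError("r_frac must be positive")


@dataclass(frozen=True)
class HRVFeatures:
    subject_id: str
    measurement_id: str
    sdnn_ms: float
    rmssd_ms: float
    sampen: float  # NaN when undefined (no template matches)
    median_hr_bpm: float
    median_br_brpm: float = math.nan  # filled by the breathing-rate stage
    usable: bool = True


@dataclass(frozen=True)
class TransformedDV:
    dv_name: str
    raw: float
    transformed: float
    transform: str


def sdnn(nn_intervals_ms) -> float:
    """Sample standard deviation (n-1 denominator) of accepted intervals, ms."""
    x = np.asarray(nn_intervals_ms, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 accepted intervals for SDNN")
    return float(np.std(x, ddof=1))


def rmssd(t: Tachogram) -> float:
    """Root mean square of successive differences between adjacent VALID
    intervals; pairs spanning a rejected interval are excluded."""
    valid = t.valid_mask
    pair_ok = valid[:-1] & valid[1:]
    if not np.any(pair_ok):
        raise ValueError("no admissible successive pair for RMSSD")
    d = np.diff(t.intervals_ms)[pair_ok]
    return float(np.sqrt(np.mean(d**2)))


def sampen_match_counts(
    series, params: SampEnParams = SampEnParams()
) -> tuple[int, int]:
    """Template match counts (A, B) for sample entropy.

    A counts ordered pairs (i != j) of length-(m+1) templates within Chebyshev
    distance r = r_frac * SD(series); B counts the same for length m.  Both
    use the N-m templates starting at 0..N-m-1 so the counts are comparable
    (self-matches excluded).
    """
    x = np.asarray(series, dtype=float)
    m = params.m
    n = len(x)
    if n <= m + 1:
        raise ValueError("series too short for the embedding dimension")
    sd = float(np.std(x, ddof=1))
    if sd == 0:
        raise ValueError("zero-variance series: tolerance degenerate")
    r = params.r_frac * sd

    n_templ = n - m
    em = sliding_window_view(x, m)[:n_templ]
    em1 = sliding_window_view(x, m + 1)[:n_templ]

    b = a = 0
    block = 256  # bound peak memory on long recordings
    for lo in range(0, n_templ, block):
        hi = min(lo + block, n_templ)
        dm = np.max(np.abs(em[lo:hi, None, :] - em[None, :, :]), axis=2)
        dm1 = np.max(np.abs(em1[lo:hi, None, :] - em1[None, :, :]), axis=2)
        b += int(np.sum(dm <= r))
        a += int(np.sum(dm1 <= r))
    # remove self-matches (distance 0 <= r, one per template)
    return a - n_templ, b - n_templ


def sampen(series, params: SampEnParams = SampEnParams()) -> float:
    """Sample entropy -ln(A/B); NaN (undefined, reported missing) when no
    template pair matches at either length."""
    a, b = sampen_match_counts(series, params)
    if a == 0 or b == 0:
        return math.nan
    return float(-np.log(a / b))


def transform_dv(value: float, dv_name: str) -> TransformedDV:
    """Normalising transform: natural log for SDNN/RMSSD, square for SampEn."""
    name = dv_name.lower()
    if name not in DV_TRANSFORMS:
        raise ValueError(f"unknown dependent variable: {dv_name!r}")
    kind = DV_TRANSFORMS[name]
    if kind == "log":
        if value <= 0:
            raise ValueError(f"{dv_name} must be positive for log transform")
        out = math.log(value)
    else:
        out = value**2
    return TransformedDV(dv_name=name, raw=value, transformed=out, transform=kind)


def inverse_transform_dv(transformed: float, dv_name: str) -> float:
    kind = DV_TRANSFORMS[dv_name.lower()]
    if kind == "log":
        return math.exp(transformed)
    return math.sqrt(transformed)


class HRVFeatureExtractor(BaseEstimator, TransformerMixin):
    """Compute per-measurement HRV features from cleaned tachograms.

    ``transform`` accepts a cleaned :class:`Tachogram` or a sequence of them
    and returns :class:`HRVFeatures` records. SampEn is computed on the
    accepted RR intervals by default; set ``sampen_on="hr"`` to use the
    instantaneous heart-rate series 60000/RR instead (monotone pointwise
    transforms can change SampEn, so the choice is explicit).
    """

    def __init__(
        self,
        sampen_m: int = 2,
        sampen_r_frac: float = 0.2,
        sampen_on: str = "rr",
        max_unreliable_fraction: float = 0.25,
    ):
        self.sampen_m = sampen_m
        self.sampen_r_frac = sampen_r_frac
        self.sampen_on = sampen_on
        self.max_unreliable_fraction = max_unreliable_fraction

    def fit(self, X, y=None):
        if self.sampen_on not in ("rr", "hr"):
            raise ValueError("sampen_on must be 'rr' or 'hr'")
        self.n_features_in_ = 1
        return self

    def transform(self, X):
        if isinstance(X, Tachogram):
            return self._extract(X)
        return [self._extract(t) for t in X]

    def _extract(self, t: Tachogram) -> HRVFeatures:
        from .preprocess import reliability

        rep = reliability(t, max_fraction=self.max_unreliable_fraction)
        nn = t.nn_intervals_ms
        series = nn if self.sampen_on == "rr" else 60000.0 / nn
        params = SampEnParams(m=self.sampen_m, r_frac=self.sampen_r_frac)
        try:
            se = sampen(series, params)
        except ValueError:
            se = math.nan
        return HRVFeatures(
            subject_id=t.subject_id,
            measurement_id=t.measurement_id,
            sdnn_ms=sdnn(nn),
            rmssd_ms=rmssd(t),
            sampen=se,
            median_hr_bpm=median_hr(t),
            usable=rep.usable,
        )
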