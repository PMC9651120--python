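"""Breathing-rate estimation from the tachogram via empirical mode
decomposition (EMD) and Hilbert instantaneous frequency.

Respiratory sinus arrhythmia is the highest-frequency oscillation in heart
rate, so the first intrinsic mode function (IMF) of the uniformly resampled
tachogram carries the respiratory modulation.  The instantaneous frequency
of that IMF, restricted to the plausible breathing band 0.1–0.5 Hz, yields a
breathing-rate estimate per 2-minute segment; the per-measurement estimate
is the median over segments.  Segments with more than 5% unreliable samples
are discarded, and measurements with no usable segment fall back to the
subject's average median breathing rate.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import hilbert
from sklearn.base import BaseEstimator, TransformerMixin

from .preprocess import UniformSeries

__all__ = [
    "MonotoneSignal",
    "IMFSet",
    "SegmentStatus",
    "SegmentBR",
    "BREstimate",
    "BreathingRateEstimator",
    "sift",
    "emd",
    "inst_freq",
    "segment_br",
    "median_br",
    "fallback_br",
]


class MonotoneSignal(Exception):
    """Raised when a signal has fewer than 2 interior extrema and cannot be
    sifted further; the caller stops the decomposition."""


@dataclass(frozen=True)
class IMFSet:
    """Ordered IMFs (highest frequency first) and the residual trend.

    The element-wise sum of all IMFs plus the residue reproduces the input;
    the residue is defined as input minus the extracted IMFs, so the
    reconstruction identity holds to machine precision by construction.
    """

    imfs: list[np.ndarray]
    residue: np.ndarray

    def reconstruct(self) -> np.ndarray:
        out = self.residue.copy()
        for imf in self.imfs:
            out += imf
        return out


class SegmentStatus(str, enum.Enum):
    OK = "OK"
    EXCLUDED_UNRELIABLE = "EXCLUDED_UNRELIABLE"
    EXCLUDED_NO_BAND = "EXCLUDED_NO_BAND"


@dataclass(frozen=True)
class SegmentBR:
    seg_index: int
    start_s: float
    end_s: float
    br_brpm: Optional[float]
    status: SegmentStatus


@dataclass(frozen=True)
class BREstimate:
    subject_id: str
    measurement_id: str
    segments: tuple[SegmentBR, ...]
    median_br_brpm: Optional[float]
    n_used: int
    fallback_used: bool = False


def _extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of strict local maxima and minima (interior samples)."""
    d = np.diff(x)
    maxima = np.flatnonzero((d[:-1] > 0) & (d[1:] < 0)) + 1
    minima = np.flatnonzero((d[:-1] < 0) & (d[1:] > 0)) + 1
    return maxima, minima


def _envelope(x: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Cubic-spline envelope through extrema, with mirror extension of the
    two outermost extrema past each end to suppress spline end swings."""
    n = len(x)
    t = idx.astype(float)
    v = x[idx]
    if len(idx) >= 2:
        # reflect about the first and last sample
        t_pre = 2 * 0.0 - t[1::-1][: min(2, len(t))]
        v_pre = v[1::-1][: min(2, len(v))]
        t_post = 2 * (n - 1) - t[-1:-3:-1]
        v_post = v[-1:-3:-1]
        t = np.concatenate([t_pre, t, t_post])
        v = np.concatenate([v_pre, v, v_post])
    cs = CubicSpline(t, v)
    return cs(np.arange(n, dtype=float))


def sift(
    signal: np.ndarray,
    sd_threshold: float = 0.2,
    max_iter: int = 50,
) -> np.ndarray:
    """Extract one IMF by iterative envelope-mean subtraction.

    Stops when the Cauchy-type criterion sum((h_prev - h)^2)/sum(h_prev^2)
    drops below ``sd_threshold`` or after ``max_iter`` sifting passes.
    """
    h = np.asarray(signal, dtype=float).copy()
    maxima, minima = _extrema(h)
    if len(maxima) + len(minima) < 2 or len(maxima) < 2 or len(minima) < 2:
        raise MonotoneSignal("fewer than 2 interior extrema")
    for _ in range(max_iter):
        maxima, minima = _extrema(h)
        if len(maxima) < 2 or len(minima) < 2:
            break
        mean_env = 0.5 * (_envelope(h, maxima) + _envelope(h, minima))
        h_new = h - mean_env
        denom = float(np.sum(h**2))
        if denom == 0:
            h = h_new
            break
        sd = float(np.sum((h - h_new) ** 2)) / denom
        h = h_new
        if sd < sd_threshold:
            break
    return h


def emd(signal: np.ndarray, max_imfs: int = 10, sd_threshold: float = 0.2,
        max_iter: int = 50) -> IMFSet:
    """Full decomposition: sift successive residues until the residue is
    monotone (no two interior extrema) or ``max_imfs`` is reached."""
    residue = np.asarray(signal, dtype=float).copy()
    imfs: list[np.ndarray] = []
    while len(imfs) < max_imfs:
        try:
            imf = sift(residue, sd_threshold=sd_threshold, max_iter=max_iter)
        except MonotoneSignal:
            break
        imfs.append(imf)
        residue = residue - imf
    return IMFSet(imfs=imfs, residue=residue)


def inst_freq(
    imf: np.ndarray, fs_hz: float, return_amplitude: bool = False
):
    """Instantaneous frequency (Hz) of an IMF via the analytic signal.

    The analytic phase is unwrapped, differentiated (central differences)
    and scaled by fs/2pi; the first and last 2 samples are discarded as
    Hilbert edge effects.  Optionally also returns the analytic amplitude
    on the same trimmed support.
    """
    x = np.asarray(imf, dtype=float)
    if len(x) < 8:
        raise ValueError("IMF too short for instantaneous frequency")
    if np.allclose(x, 0):
        raise ValueError("degenerate (all-zero) IMF")
    analytic = hilbert(x)
    phase = np.unwrap(np.angle(analytic))
    freq = np.gradient(phase) * fs_hz / (2 * np.pi)
    if return_amplitude:
        return freq[2:-2], np.abs(analytic)[2:-2]
    return freq[2:-2]


def _dominant_frequency(
    freq: np.ndarray,
    amp: np.ndarray,
    band_hz: tuple[float, float],
    bin_width_hz: float = 0.01,
    estimator: str = "median",
) -> Optional[float]:
    """Dominant in-band frequency: amplitude-weighted histogram mode (bin
    centre returned) or the plain median of in-band samples."""
    in_band = (freq >= band_hz[0]) & (freq <= band_hz[1])
    if not np.any(in_band):
        return None
    f = freq[in_band]
    if estimator == "median":
        return float(np.median(f))
    w = amp[in_band]
    edges = np.arange(band_hz[0], band_hz[1] + bin_width_hz / 2, bin_width_hz)
    hist, _ = np.histogram(f, bins=edges, weights=w)
    k = int(np.argmax(hist))
    return float(0.5 * (edges[k] + edges[k + 1]))


def segment_br(
    u: UniformSeries,
    window_s: float = 120.0,
    overlap: float = 0.5,
    band_hz: tuple[float, float] = (0.1, 0.5),
    max_unreliable: float = 0.05,
    estimator: str = "median",
) -> list[SegmentBR]:
    """Per-window breathing rate from IMF-1 instantaneous frequency.

    2-minute windows advance by ``window_s * (1 - overlap)``; a partial
    trailing window is dropped.  Windows with more than ``max_unreliable``
    unreliable samples are excluded; windows with no in-band instantaneous
    frequency are excluded as no-band.
    """
    win = int(round(window_s * u.fs_hz))
    step = int(round(window_s * (1 - overlap) * u.fs_hz))
    n = len(u.values_ms)
    segments: list[SegmentBR] = []
    seg_index = 0
    for start in range(0, n - win + 1, step):
        sl = slice(start, start + win)
        start_s = u.t0_s + start / u.fs_hz
        end_s = start_s + window_s
        unreliable = 1.0 - float(np.mean(u.reliable_mask[sl]))
        if unreliable > max_unreliable:
            segments.append(SegmentBR(seg_index, start_s, end_s, None,
                                      SegmentStatus.EXCLUDED_UNRELIABLE))
            seg_index += 1
            continue
        x = u.values_ms[sl]
        x = x - np.mean(x)
        br_hz: Optional[float] = None
        try:
            imf1 = sift(x)
            freq, amp = inst_freq(imf1, u.fs_hz, return_amplitude=True)
            br_hz = _dominant_frequency(freq, amp, band_hz, estimator=estimator)
        except (MonotoneSignal, ValueError):
            br_hz = None
        if br_hz is None:
            segments.append(SegmentBR(seg_index, start_s, end_s, None,
                                      SegmentStatus.EXCLUDED_NO_BAND))
        else:
            segments.append(SegmentBR(seg_index, start_s, end_s, br_hz * 60.0,
                                      SegmentStatus.OK))
        seg_index += 1
    return segments


def median_br(
    segments: Sequence[SegmentBR],
    subject_id: str = "",
    measurement_id: str = "",
) -> BREstimate:
    """Median breathing rate over OK segments; absent (None) when none."""
    ok = [s.br_brpm for s in segments if s.status == SegmentStatus.OK]
    med = float(np.median(ok)) if ok else None
    return BREstimate(
        subject_id=subject_id,
        measurement_id=measurement_id,
        segments=tuple(segments),
        median_br_brpm=med,
        n_used=len(ok),
    )


def fallback_br(estimates: Sequence[BREstimate]) -> list[BREstimate]:
    """Fill absent per-measurement medians of one subject with the mean of
    that subject's non-absent medians.

    If the subject has no non-absent median at all the estimates are
    returned unchanged (still absent); the orchestrator drops those
    measurements from breathing-rate-dependent models and logs them.
    """
    present = [e.median_br_brpm for e in estimates if e.median_br_brpm is not None]
    if not present:
        return list(estimates)
    mean_br = float(np.mean(present))
    out = []
    for e in estimates:
        if e.median_br_brpm is None:
            out.append(replace(e, median_br_brpm=mean_br, fallback_used=True))
        else:
            out.append(e)
    return out


class BreathingRateEstimator(BaseEstimator, TransformerMixin):
    """Transformer mapping a uniformly resampled tachogram to a per-
    measurement breathing-rate estimate."""

    def __init__(
        self,
        window_s: float = 120.0,
        overlap: float = 0.5,
        band_hz: tuple[float, float] = (0.1, 0.5),
        max_unreliable: float = 0.05,
        estimator: str = "median",
    ):
        self.window_s = window_s
        self.overlap = overlap
        self.band_hz = band_hz
        self.max_unreliable = max_unreliable
        self.estimator = estimator

    def fit(self, X, y=None):
        self.n_features_in_ = 1
        return self

    def transform(self, X):
        if isinstance(X, UniformSeries):
            return self._estimate(X)
        return [self._estimate(u) for u in X]

    def _estimate(self, u: UniformSeries, subject_id: str = "",
                  measurement_id: str = "") -> BREstimate:
        segs = segment_br(
            u,
            window_s=self.window_s,
            overlap=self.overlap,
            band_hz=tuple(self.band_hz),
            max_unreliable=self.max_unreliable,
            estimator=self.estimator,
        )
        return median_br(segs, subject_id=subject_id,
                         measurement_id=measurement_id)
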