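"""RR-interval preprocessing: tachogram construction, artifact rejection,
reliability gating, and uniform resampling.

The cleaning rules mirror standard HRV practice for maternal abdominal-ECG
recordings: an RR interval is rejected when it falls outside the
physiological range 0.4–2 s, when it differs from the reference preceding
interval by more than 20%, or when both of its immediate neighbours were
rejected by the first two rules.  A recording is usable only when at most
25% of its intervals are rejected.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "BeatFlag",
    "RPeakSeries",
    "Tachogram",
    "ReliabilityReport",
    "UniformSeries",
    "TachogramCleaner",
    "build_tachogram",
    "flag_range",
    "flag_delta",
    "flag_neighbor",
    "clean",
    "reliability",
    "interpolate",
    "median_hr",
]


class BeatFlag(enum.IntEnum):
    """Per-interval status.  Flags are mutually exclusive and exhaustive."""

    VALID = 0
    REJECT_RANGE = 1
    REJECT_DELTA = 2
    REJECT_NEIGHBOR = 3


@dataclass(frozen=True)
class RPeakSeries:
    """R-peak occurrence times for one measurement, seconds from start."""

    subject_id: str
    measurement_id: str
    peak_times: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "peak_times", np.asarray(self.peak_times, dtype=float)
        )


@dataclass(frozen=True)
class Tachogram:
    """RR durations (ms) with onset times (s) and per-interval flags."""

    subject_id: str
    measurement_id: str
    intervals_ms: np.ndarray
    onset_times_s: np.ndarray
    flags: np.ndarray  # BeatFlag codes, int

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "intervals_ms", np.asarray(self.intervals_ms, dtype=float)
        )
        object.__setattr__(
            self, "onset_times_s", np.asarray(self.onset_times_s, dtype=float)
        )
        object.__setattr__(self, "flags", np.asarray(self.flags, dtype=int))
        if not (
            len(self.intervals_ms) == len(self.onset_times_s) == len(self.flags)
        ):
            raise ValueError("intervals, onsets and flags must be same length")

    def __len__(self) -> int:
        return len(self.intervals_ms)

    @property
    def valid_mask(self) -> np.ndarray:
        return self.flags == BeatFlag.VALID

    @property
    def nn_intervals_ms(self) -> np.ndarray:
        """Accepted (NN) intervals in original order."""
        return self.intervals_ms[self.valid_mask]


@dataclass(frozen=True)
class ReliabilityReport:
    n_total: int
    n_unreliable: int
    unreliable_fraction: float
    usable: bool


@dataclass(frozen=True)
class UniformSeries:
    """Tachogram resampled on a uniform grid.

    ``reliable_mask`` is False for grid samples whose time falls inside an
    interval rejected by the cleaning rules (i.e. values manufactured by
    interpolation rather than measured).
    """

    values_ms: np.ndarray
    fs_hz: float
    reliable_mask: np.ndarray
    t0_s: float = 0.0

    @property
    def times_s(self) -> np.ndarray:
        return self.t0_s + np.arange(len(self.values_ms)) / self.fs_hz


def build_tachogram(peaks: RPeakSeries) -> Tachogram:
    """Difference consecutive R-peak times into a tachogram.

    Interval ``i`` spans ``[peak_i, peak_{i+1})`` and is timed at its onset.
    All flags start VALID.
    """
    t = peaks.peak_times
    if len(t) < 2:
        raise ValueError("need at least 2 R-peaks to form an interval")
    if np.any(t < 0):
        raise ValueError("R-peak times must be non-negative")
    d = np.diff(t)
    if np.any(d <= 0):
        raise ValueError("R-peak times must be strictly increasing")
    return Tachogram(
        subject_id=peaks.subject_id,
        measurement_id=peaks.measurement_id,
        intervals_ms=d * 1000.0,
        onset_times_s=t[:-1].copy(),
        flags=np.zeros(len(d), dtype=int),
    )


def flag_range(t: Tachogram, lo_ms: float = 400.0, hi_ms: float = 2000.0) -> Tachogram:
    """Reject intervals outside the physiological range (bounds inclusive-accept)."""
    if lo_ms >= hi_ms:
        raise ValueError("lo_ms must be below hi_ms")
    flags = t.flags.copy()
    bad = (t.intervals_ms < lo_ms) | (t.intervals_ms > hi_ms)
    flags[bad] = BeatFlag.REJECT_RANGE
    return replace(t, flags=flags)


def flag_delta(
    t: Tachogram, rel_tol: float = 0.20, reference: str = "last_accepted"
) -> Tachogram:
    """Reject intervals differing by strictly more than ``rel_tol`` from the
    preceding reference interval.

    ``reference="last_accepted"`` (default) compares against the most recent
    interval not yet rejected, so a single ectopic beat does not cascade;
    ``reference="previous"`` compares against the raw predecessor.
    """
    if reference not in ("last_accepted", "previous"):
        raise ValueError(f"unknown reference mode: {reference!r}")
    flags = t.flags.copy()
    x = t.intervals_ms
    ref: float | None = None
    for i in range(len(x)):
        if flags[i] == BeatFlag.REJECT_RANGE:
            if reference == "previous":
                ref = x[i]
            continue
        if ref is not None and abs(x[i] - ref) / ref > rel_tol:
            flags[i] = BeatFlag.REJECT_DELTA
            if reference == "previous":
                ref = x[i]
            continue
        ref = x[i]
    return replace(t, flags=flags)


def flag_neighbor(t: Tachogram) -> Tachogram:
    """Reject still-valid intervals whose two immediate neighbours were both
    rejected by the range/delta rules.  Single pass; first and last intervals
    have only one neighbour and are never flagged here."""
    flags = t.flags.copy()
    rejected = t.flags != BeatFlag.VALID
    for i in range(1, len(flags) - 1):
        if flags[i] == BeatFlag.VALID and rejected[i - 1] and rejected[i + 1]:
            flags[i] = BeatFlag.REJECT_NEIGHBOR
    return replace(t, flags=flags)


def clean(
    t: Tachogram,
    lo_ms: float = 400.0,
    hi_ms: float = 2000.0,
    rel_tol: float = 0.20,
    reference: str = "last_accepted",
) -> Tachogram:
    """Apply range -> delta -> neighbour rejection in order.

    Flags are recomputed from interval values, so the operation is idempotent.
    """
    fresh = replace(t, flags=np.zeros(len(t), dtype=int))
    out = flag_range(fresh, lo_ms=lo_ms, hi_ms=hi_ms)
    out = flag_delta(out, rel_tol=rel_tol, reference=reference)
    return flag_neighbor(out)


def reliability(t: Tachogram, max_fraction: float = 0.25) -> ReliabilityReport:
    """Fraction of rejected intervals; usable iff not more than ``max_fraction``."""
    n = len(t)
    if n == 0:
        raise ValueError("empty tachogram")
    n_bad = int(np.sum(t.flags != BeatFlag.VALID))
    frac = n_bad / n
    return ReliabilityReport(
        n_total=n, n_unreliable=n_bad, unreliable_fraction=frac,
        usable=frac <= max_fraction,
    )


def interpolate(t: Tachogram, fs_hz: float = 4.0) -> UniformSeries:
    """Linearly interpolate across rejected gaps and resample uniformly.

    The RR-versus-time function is anchored at VALID interval onsets only and
    resampled at ``fs_hz`` on [first VALID onset, last VALID onset].  Grid
    samples inside rejected intervals are marked unreliable.
    """
    valid = t.valid_mask
    if int(valid.sum()) < 2:
        raise ValueError("need at least 2 VALID intervals to interpolate")
    xt = t.onset_times_s[valid]
    xv = t.intervals_ms[valid]
    n_grid = int(np.floor((xt[-1] - xt[0]) * fs_hz)) + 1
    grid = xt[0] + np.arange(n_grid) / fs_hz
    values = np.interp(grid, xt, xv)

    reliable = np.ones(n_grid, dtype=bool)
    for i in np.flatnonzero(~valid):
        start = t.onset_times_s[i]
        end = start + t.intervals_ms[i] / 1000.0
        reliable[(grid >= start) & (grid < end)] = False
    return UniformSeries(values_ms=values, fs_hz=fs_hz, reliable_mask=reliable,
                         t0_s=float(xt[0]))


def median_hr(t: Tachogram) -> float:
    """Median heart rate in bpm over VALID intervals (60000 / RR_ms)."""
    nn = t.nn_intervals_ms
    if len(nn) == 0:
        raise ValueError("no VALID intervals")
    return float(np.median(60000.0 / nn))


class TachogramCleaner(BaseEstimator, TransformerMixin):
    """Stateless transformer applying the three rejection rules to tachograms.

    Parameters
    ----------
    lo_ms, hi_ms : float
        Physiological range bounds in ms; values exactly at a bound are kept.
    rel_tol : float
        Relative-difference threshold for the successive-difference rule.
    reference : {"last_accepted", "previous"}
        Reference interval for the delta rule after a rejection.
    """

    def __init__(
        self,
        lo_ms: float = 400.0,
        hi_ms: float = 2000.0,
        rel_tol: float = 0.20,
        reference: str = "last_accepted",
    ):
        self.lo_ms = lo_ms
        self.hi_ms = hi_ms
        self.rel_tol = rel_tol
        self.reference = reference

    def fit(self, X, y=None):
        self.n_features_in_ = 1
        return self

    def transform(self, X):
        """Clean a Tachogram, an RPeakSeries, or a sequence of either."""
        if isinstance(X, (Tachogram, RPeakSeries)):
            return self._clean_one(X)
        return [self._clean_one(x) for x in X]

    def _clean_one(self, x):
        t = build_tachogram(x) if isinstance(x, RPeakSeries) else x
        return clean(
            t,
            lo_ms=self.lo_ms,
            hi_ms=self.hi_ms,
            rel_tol=self.rel_tol,
            reference=self.reference,
        )
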