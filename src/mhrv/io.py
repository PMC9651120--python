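"""CSV and configuration I/O for the pipeline.

All interchange formats are plain UTF-8 CSV with headers; numbers are
serialised with 12 significant digits so write -> read round trips are
lossless at working precision.  Absent values (e.g. a measurement with no
breathing-rate estimate) are serialised as empty fields.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from .preprocess import BeatFlag, RPeakSeries, Tachogram

__all__ = [
    "RunConfig",
    "RunManifest",
    "read_rpeaks_csv",
    "write_rpeaks_csv",
    "read_tachogram_csv",
    "write_tachogram_csv",
    "read_table",
    "write_table",
]

FLOAT_FMT = "%.12g"


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")


def read_rpeaks_csv(path) -> list[RPeakSeries]:
    """Read R-peak (or RR) rows grouped into per-measurement series.

    Exactly one of ``peak_time_s`` / ``rr_ms`` must be present; RR rows are
    cumulated into peak times starting at 0.
    """
    df = pd.read_csv(path)
    _require_columns(df, ["subject_id", "measurement_id"], path)
    has_peak = "peak_time_s" in df.columns
    has_rr = "rr_ms" in df.columns
    if has_peak == has_rr:
        raise ValueError(
            f"{path}: exactly one of 'peak_time_s' or 'rr_ms' must be present"
        )
    out = []
    for (sid, mid), g in df.groupby(["subject_id", "measurement_id"],
                                    sort=False):
        if has_peak:
            times = g["peak_time_s"].to_numpy(dtype=float)
        else:
            times = np.concatenate(
                [[0.0], np.cumsum(g["rr_ms"].to_numpy(dtype=float)) / 1000.0]
            )
        out.append(RPeakSeries(subject_id=str(sid), measurement_id=str(mid),
                               peak_times=times))
    return out


def write_rpeaks_csv(series: list[RPeakSeries], path) -> None:
    frames = [
        pd.DataFrame(
            {"subject_id": s.subject_id, "measurement_id": s.measurement_id,
             "peak_time_s": s.peak_times}
        )
        for s in series
    ]
    pd.concat(frames, ignore_index=True).to_csv(
        path, index=False, float_format=FLOAT_FMT
    )


def write_tachogram_csv(tachograms: list[Tachogram], path) -> None:
    frames = [
        pd.DataFrame(
            {
                "subject_id": t.subject_id,
                "measurement_id": t.measurement_id,
                "onset_s": t.onset_times_s,
                "rr_ms": t.intervals_ms,
                "flag": [BeatFlag(f).name for f in t.flags],
            }
        )
        for t in tachograms
    ]
    pd.concat(frames, ignore_index=True).to_csv(
        path, index=False, float_format=FLOAT_FMT
    )


def read_tachogram_csv(path) -> list[Tachogram]:
    df = pd.read_csv(path)
    _require_columns(df, ["subject_id", "measurement_id", "onset_s", "rr_ms",
                          "flag"], path)
    out = []
    for (sid, mid), g in df.groupby(["subject_id", "measurement_id"],
                                    sort=False):
        out.append(
            Tachogram(
                subject_id=str(sid),
                measurement_id=str(mid),
                intervals_ms=g["rr_ms"].to_numpy(dtype=float),
                onset_times_s=g["onset_s"].to_numpy(dtype=float),
                flags=np.array([BeatFlag[f] for f in g["flag"]], dtype=int),
            )
        )
    return out


def read_table(path, required=()) -> pd.DataFrame:
    df = pd.read_csv(path)
    if required:
        _require_columns(df, required, path)
    return df


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


# -- run configuration -------------------------------------------------------

_DEFAULT_CONFIG = {
    "schema_version": 1,
    "seed": 0,
    "preprocess": {
        "lo_ms": 400.0,
        "hi_ms": 2000.0,
        "rel_tol": 0.20,
        "reference": "last_accepted",
        "fs_hz": 4.0,
        "max_unreliable_fraction": 0.25,
    },
    "sampen": {"m": 2, "r_frac": 0.2, "on": "rr"},
    "br": {
        "window_s": 120.0,
        "overlap": 0.5,
        "band_lo_hz": 0.1,
        "band_hi_hz": 0.5,
        "max_unreliable": 0.05,
        "estimator": "median",
    },
    "models": {
        "dv_names": ["sdnn", "rmssd", "sampen"],
        "include_chd_screen": True,
        "parity_numeric": False,
        "cooks_threshold": 1.0,
        "max_removals": 2,
        "n_grid": 50,
    },
    "simulate": {
        "design": "repeated",
        "n_subjects": 29,
        "dropout_prob": 0.2,
        "duration_s": 1800.0,
        "base_rr_ms": 770.0,
        "rsa_amp_ms": 30.0,
        "br_hz": 0.23,
        "lf_amp_ms": 50.0,
        "noise_sd_ms": 10.0,
        "artifact_rate": 0.02,
    },
}


@dataclass
class RunConfig:
    """Validated run configuration; unknown keys are rejected."""

    data: dict = field(default_factory=lambda: json.loads(
        json.dumps(_DEFAULT_CONFIG)))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            user = yaml.safe_load(fh) or {}
        return cls.from_dict(user)

    @classmethod
    def from_dict(cls, user: dict) -> "RunConfig":
        merged = json.loads(json.dumps(_DEFAULT_CONFIG))
        _merge_validate(merged, user, [])
        return cls(data=merged)

    def __getitem__(self, key):
        return self.data[key]

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.data, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _merge_validate(base: dict, user: dict, trail: list) -> None:
    for key, val in user.items():
        if key not in base:
            raise ValueError(
                f"unknown config key: {'.'.join(trail + [str(key)])}"
            )
        if isinstance(base[key], dict) and isinstance(val, dict):
            _merge_validate(base[key], val, trail + [str(key)])
        else:
            base[key] = val


@dataclass
class RunManifest:
    """Per-run exclusion accounting; counts must reconcile so that
    rows into each model = usable measurements - missing-covariate drops -
    influential removals."""

    config_hash: str
    software_version: str
    seed: int
    n_measurements_in: int = 0
    n_excluded_reliability: int = 0
    n_br_fallbacks: int = 0
    n_br_unresolved: int = 0
    per_dv: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
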