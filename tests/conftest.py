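import numpy as np
import pytest

from mhrv.preprocess import RPeakSeries, Tachogram, build_tachogram, clean


@pytest.fixture
def toy_peaks():
    return RPeakSeries("S001", "S001_M01", np.array([0.0, 0.8, 1.6, 2.4]))


def make_tachogram(rr_ms, subject="S001", measurement="S001_M01"):
    """Tachogram with consistent onset times and all-VALID flags."""
    rr = np.asarray(rr_ms, dtype=float)
    onsets = np.concatenate([[0.0], np.cumsum(rr[:-1]) / 1000.0])
    return Tachogram(subject, measurement, rr, onsets,
                     np.zeros(len(rr), dtype=int))


@pytest.fixture
def toy_tachogram():
    return make_tachogram([850, 300, 860, 1100, 870, 2500, 865])


@pytest.fixture
def clean_rsa_series():
    """10-min artifact-free RR series with breathing at 15 brpm."""
    from mhrv.simulate import SignalConfig, simulate_rr

    cfg = SignalConfig(duration_s=600, base_rr_ms=800, rsa_amp_ms=30,
                       br_hz=0.25, lf_amp_ms=10, noise_sd_ms=2, seed=7)
    return simulate_rr(cfg)


@pytest.fixture
def clean_rsa_tachogram(clean_rsa_series):
    return clean(build_tachogram(clean_rsa_series))
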