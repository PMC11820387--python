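"""Shared fixtures: all test data is generated, none stored."""

from __future__ import annotations

import numpy as np
import pytest

import dyadsync as ds
from dyadsync.preprocess import perfect_quality


@pytest.fixture(scope="session")
def clean_pair():
    """One simulated dyad's ground-truth interval series (no artifacts)."""
    cfg = ds.SimConfig(seed=11)
    return ds.simulate_rr_pair(cfg)


@pytest.fixture(scope="session")
def clean_recording(clean_pair):
    """A rendered 300-s, 250-Hz waveform from the first partner."""
    ibi, _ = clean_pair
    return ds.render_ppg(ibi, fs=250.0, duration_s=300.0,
                         rng=np.random.default_rng(12))


@pytest.fixture(scope="session")
def artifact_recording(clean_recording):
    """The clean waveform with the default motion-artifact load injected."""
    return ds.inject_artifacts(clean_recording, rate_per_min=6.0,
                               duration_s=2.0, amplitude=4.0, seed=13)


@pytest.fixture(scope="session")
def constant_rr_recording():
    """A noise-free perfectly periodic waveform (RR = 800 ms, 300 s)."""
    rr = np.full(374, 800.0)
    onset = np.concatenate([[0.0], np.cumsum(rr)[:-1]]) / 1000.0
    ibi = ds.IbiSeries(interval_ms=rr, onset_s=onset)
    return ds.render_ppg(ibi, fs=250.0, duration_s=300.0, noise_sd=0.0)


@pytest.fixture(scope="session")
def full_quality():
    return perfect_quality(300.0)


def random_ibi(rng: np.random.Generator, duration_s: float = 300.0,
               mean_ms: float = 850.0, sd_ms: float = 45.0) -> ds.IbiSeries:
    """A plain white-noise interval series for oracle comparisons."""
    n = int(duration_s * 1000 / mean_ms) + 10
    rr = np.clip(rng.normal(mean_ms, sd_ms, n), 320.0, 2900.0)
    onset = np.concatenate([[0.0], np.cumsum(rr)[:-1]]) / 1000.0
    keep = onset < duration_s
    return ds.IbiSeries(interval_ms=rr[keep], onset_s=onset[keep])
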