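"""Shared fixtures: small synthetic records and derived series.

Session-scoped because simulation + the full index chain dominate test
runtime; all fixtures are seeded and deterministic.
"""

from __future__ import annotations

import numpy as np
import pytest

from edapain.preprocess import preprocess_eda
from edapain.records import SimulationConfig, UniformSeries
from edapain.simulate import generate_subject
from edapain.vfcdm import vfcdm_decompose


@pytest.fixture(scope="session")
def short_config() -> SimulationConfig:
    """A compact session: 5 stimuli, ~4.5 min — enough for every stage."""
    return SimulationConfig(
        n_subjects=1,
        n_stimuli_per_subject=5,
        isi_range=(40.0, 50.0),
        lead_in=60.0,
        lead_out=30.0,
        seed=0,
    )


@pytest.fixture(scope="session")
def subject(short_config):
    return generate_subject(short_config, 0)


@pytest.fixture(scope="session")
def preprocessed(subject):
    record, _, _ = subject
    return preprocess_eda(record)


@pytest.fixture(scope="session")
def decomposition(preprocessed):
    return vfcdm_decompose(preprocessed)


@pytest.fixture(scope="session")
def tone_series() -> UniformSeries:
    """300 s unit sinusoid at 0.12 Hz (center of VFCDM band 2), 2 Hz."""
    t = np.arange(0, 300, 0.5)
    return UniformSeries(values=np.sin(2 * np.pi * 0.12 * t), rate=2.0)


@pytest.fixture(scope="session")
def broadband_series() -> UniformSeries:
    """300 s band-limited (0.05-0.85 Hz) random tone mixture at 2 Hz."""
    rng = np.random.default_rng(0)
    t = np.arange(0, 300, 0.5)
    freqs = rng.uniform(0.05, 0.85, 25)
    amps = rng.uniform(0.1, 1.0, 25)
    phases = rng.uniform(0, 2 * np.pi, 25)
    x = np.zeros_like(t)
    for f, a, p in zip(freqs, amps, phases):
        x += a * np.cos(2 * np.pi * f * t + p)
    return UniformSeries(values=x, rate=2.0)
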