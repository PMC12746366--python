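"""Shared fixtures: small synthetic datasets reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from downfield_mrs.processing import process_scan
from downfield_mrs.synthetic import (
    AcquisitionProtocol,
    SubjectTruth,
    default_truth,
    generate_saturation_series,
)


@pytest.fixture(scope="session")
def truth() -> SubjectTruth:
    return default_truth()


@pytest.fixture(scope="session")
def protocol() -> AcquisitionProtocol:
    return AcquisitionProtocol()


@pytest.fixture(scope="session")
def noiseless_protocol() -> AcquisitionProtocol:
    return AcquisitionProtocol(noise_sigma=0.0)


@pytest.fixture(scope="session")
def noiseless_subject(truth, noiseless_protocol):
    """One subject with no noise: every stage should be near-exact on it."""
    return generate_saturation_series(truth, noiseless_protocol, seed=1)


@pytest.fixture(scope="session")
def noisy_subject(truth, protocol):
    """One subject at the calibrated in-vivo-like SNR."""
    return generate_saturation_series(truth, protocol, seed=3)


@pytest.fixture(scope="session")
def fixed_channel_weights() -> np.ndarray:
    rng = np.random.default_rng(99)
    mags = rng.uniform(0.5, 1.0, 8)
    phis = rng.uniform(-np.pi, np.pi, 8)
    return mags * np.exp(1j * phis)


@pytest.fixture(scope="session")
def combined_noiseless_m0(noiseless_subject):
    return process_scan(noiseless_subject.m0, noiseless_subject.water_ref)
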