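"""Shared fixtures: synthetic subjects, banks and calibrated models.

Everything is generated programmatically at session start; no stored data.
"""

from __future__ import annotations

import numpy as np
import pytest

from armkin.kinematics import calibrate_landmarks
from armkin.markers import DEFAULT_MARKER_SET
from armkin.simulate import (
    SimulationConfig,
    generate_reference_bank,
    simulate_child_trial,
)

#: deviation-free, noise-free study conditions (bank variability zeroed so
#: the bank mean IS the template)
NULL_CONFIG = SimulationConfig(
    marker_noise=0.0, deviation_scale=0.0, slope_sd=0.0,
    bank_offset_sd=0.0, bank_amp_sd=0.0, bank_shift_sd=0.0,
)

#: study noise level (1 mm), still deviation-free
NOISY_CONFIG = SimulationConfig(
    marker_noise=0.001, deviation_scale=0.0, slope_sd=0.0,
    bank_offset_sd=0.0, bank_amp_sd=0.0, bank_shift_sd=0.0,
)


@pytest.fixture(scope="session")
def null_bank():
    bank, templates = generate_reference_bank(NULL_CONFIG)
    return bank, templates


@pytest.fixture(scope="session")
def null_child():
    """Noiseless deviation-free MACS I subject."""
    return simulate_child_trial("I", NULL_CONFIG, seed=2)


@pytest.fixture(scope="session")
def null_model(null_child):
    static, _, _ = null_child
    return calibrate_landmarks(static, DEFAULT_MARKER_SET)


@pytest.fixture(scope="session")
def noisy_child():
    """1 mm marker noise, deviation-free MACS I subject."""
    return simulate_child_trial("I", NOISY_CONFIG, seed=11)


@pytest.fixture(scope="session")
def noisy_model(noisy_child):
    static, _, _ = noisy_child
    return calibrate_landmarks(static, DEFAULT_MARKER_SET)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
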