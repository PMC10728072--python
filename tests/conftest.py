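"""Shared fixtures: small synthetic recordings generated at test time."""

import warnings

import numpy as np
import pytest

from resposc.config import AnalysisConfig, SimulationConfig
from resposc.simulate import generate_participant


@pytest.fixture(scope="session")
def small_participant():
    """One 10-min synthetic participant with the default channel layout."""
    cfg = SimulationConfig(duration_s=600.0, n_participants=2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rec, truth = generate_participant(cfg, participant_seed=3, participant="p00")
    return cfg, rec, truth


@pytest.fixture(scope="session")
def validation_config():
    """Analysis settings with the optional amplitude criteria enabled."""
    return AnalysisConfig.for_synthetic_validation()


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
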