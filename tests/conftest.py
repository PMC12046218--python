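"""Shared fixtures: simulated sessions are generated once per test run."""
import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from loomphot.pipeline import AnalysisConfig
from loomphot.simulate import (BehaviorSimParams, CouplingParams,
                               PhotometrySimParams, simulate_session)


@pytest.fixture(scope="session")
def default_phot():
    return PhotometrySimParams()


@pytest.fixture(scope="session")
def default_behav():
    return BehaviorSimParams()


@pytest.fixture(scope="session")
def default_coupling():
    return CouplingParams()


@pytest.fixture(scope="session")
def config():
    return AnalysisConfig()


@pytest.fixture(scope="session")
def escaper_session(default_phot, default_behav, default_coupling):
    """One seeded escaper session (recording, track, train, ground truth)."""
    return simulate_session(default_phot, default_behav, default_coupling)


@pytest.fixture(scope="session")
def short_behav():
    """Behavior template with a shortened exploration, for fast cohorts."""
    return BehaviorSimParams(exploration_duration=60.0, post_duration=30.0)


@pytest.fixture(scope="session")
def short_config():
    return AnalysisConfig(exploration_min=60.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
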