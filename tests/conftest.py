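import numpy as np
import pytest

from fbcsp import (EventPairDecoder, SimulationConfig, published_accuracies,
                   simulate_recording)

# The simulated sessions reproduce the emulated study's conditions: 14
# channels at 128 Hz, hour-long sessions, cue intervals N(150 s, 60 s)
# (~20-25 events).  Heavy fixtures are session-scoped so the full-pipeline
# properties and the acceptance checks share one computation.


@pytest.fixture(scope="session")
def effect_session():
    """Session with a strong alpha-band effect (3x source amplitude post-cue)."""
    cfg = SimulationConfig(effect_ratio=3.0, seed=11)
    return simulate_recording(cfg)


@pytest.fixture(scope="session")
def null_session():
    """Session with no class structure (effect_ratio = 1)."""
    cfg = SimulationConfig(effect_ratio=1.0, seed=12)
    return simulate_recording(cfg)


@pytest.fixture(scope="session")
def effect_results(effect_session):
    rec, events, _ = effect_session
    return EventPairDecoder(rec, events, classifier="LDA", seed=0).fit()


@pytest.fixture(scope="session")
def null_results(null_session):
    rec, events, _ = null_session
    return EventPairDecoder(rec, events, classifier="LDA", seed=0).fit()


@pytest.fixture(scope="session")
def short_session():
    """A cheaper session (~8 events) for structural pipeline tests."""
    cfg = SimulationConfig(duration=1400.0, effect_ratio=3.0, seed=21)
    return simulate_recording(cfg)


@pytest.fixture(scope="session")
def published():
    return published_accuracies()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
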