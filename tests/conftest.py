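import sys
from pathlib import Path

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

sys.path.insert(0, str(Path(__file__).parent))  # for the _oracles module

from repform import SynthConfig, build_signal_set, generate_session

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


ZERO_NOISE = dict(noise_sd_acc=0.0, noise_sd_gyro=0.0, noise_sd_mag=0.0, tempo_jitter=0.0)


@pytest.fixture(scope="session")
def clean_session():
    """Zero-noise 5-repetition session with its ground truth."""
    cfg = SynthConfig(n_reps=5, seed=11, **ZERO_NOISE)
    stream, truth = generate_session(cfg)
    return cfg, stream, truth


@pytest.fixture(scope="session")
def clean_signals(clean_session):
    _, stream, _ = clean_session
    return build_signal_set(stream)


@pytest.fixture(scope="session")
def noisy_session():
    """Default-noise 5-repetition session (study-like conditions)."""
    cfg = SynthConfig(n_reps=5, seed=21)
    stream, truth = generate_session(cfg)
    return cfg, stream, truth


@pytest.fixture(scope="session")
def labeled_db():
    """20 acceptable + 20 aberrant repetitions, strong separation."""
    from repform import generate_labeled_dataset

    cfg_ok = SynthConfig(n_reps=20, seed=0)
    cfg_bad = SynthConfig(n_reps=20, seed=0, deviation="frontal_wobble", deviation_magnitude=0.8)
    return generate_labeled_dataset(cfg_ok, cfg_bad, seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
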