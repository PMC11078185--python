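import numpy as np
import pytest

from cordtrace.config import GeneratorConfig, SessionConfig
from cordtrace import synth


def make_noiseless(cfg: GeneratorConfig) -> GeneratorConfig:
    cfg.white_sigma_uV = 0.0
    cfg.ecg_amplitude_uV = 0.0
    cfg.resp_amplitude_uV = 0.0
    cfg.line_amplitude_uV = 0.0
    cfg.stim_artifact_amplitude_uV = 0.0
    cfg.amplitude_jitter = 0.0
    return cfg


@pytest.fixture
def tiny_gen() -> GeneratorConfig:
    """Short low-rate session config for fast unit tests."""
    return GeneratorConfig(sample_rate_hz=2000.0, duration_s=8.0)


@pytest.fixture
def tiny_noiseless(tiny_gen) -> GeneratorConfig:
    return make_noiseless(tiny_gen)


@pytest.fixture
def layout32():
    return synth.make_layout(32, 1.0)


@pytest.fixture
def small_session(tiny_gen):
    """One noisy 8-event session at 2 kHz with ground truth."""
    rec, events, truth = synth.simulate_session(tiny_gen, seed=7)
    return rec, events, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
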