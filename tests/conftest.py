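import numpy as np
import pytest

from perispike.config import AnalysisConfig
from perispike.synth import SynthConfig, generate_session


@pytest.fixture(scope="session")
def ac() -> AnalysisConfig:
    return AnalysisConfig()


@pytest.fixture(scope="session")
def quiet_session():
    """Baseline-only pre-regime unit at 40 sp/s: no ramp, no oscillation,
    no response."""
    cfg = SynthConfig(seed=101, regime="pre", n_trials=30, baseline_rate=40.0,
                      response_type="none")
    return generate_session(cfg)


@pytest.fixture(scope="session")
def responding_session():
    """Strong movement-locked increase response on a 40-sp/s baseline."""
    cfg = SynthConfig(seed=202, regime="pre", n_trials=80, baseline_rate=40.0,
                      response_type="incr", response_amp=60.0,
                      response_sigma=0.08, lock_lambda=1.0,
                      onset_offset=-0.15, refractory=0.002)
    return generate_session(cfg)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
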