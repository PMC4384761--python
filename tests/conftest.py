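import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

from thetaloop import (DetectorConfig, LfpGenConfig, generate_lfp,
                       offline_phase, run_closed_loop)


@pytest.fixture(scope="session")
def clean_cosine():
    """Noise-free symmetric 8 Hz theta, 20 s."""
    cfg = LfpGenConfig(noise_amp=0.0, hg_amp=0.0, asym=1.0)
    return cfg, generate_lfp(cfg, 20.0)


@pytest.fixture(scope="session")
def default_session():
    """Default synthetic LFP (30 s) with its offline phase and both pulse
    trains from the closed-loop detector."""
    cfg = LfpGenConfig(seed=3)
    trace = generate_lfp(cfg, 30.0)
    phase = offline_phase(trace)
    trains = {mode: run_closed_loop(trace, DetectorConfig(mode=mode))
              for mode in ("peak", "trough")}
    return cfg, trace, phase, trains
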