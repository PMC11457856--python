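import numpy as np
import pytest
from hypothesis import settings as hyp_settings

import ventwave as vw

hyp_settings.register_profile("ci", derandomize=True, max_examples=50,
                              deadline=None)
hyp_settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_settings():
    return vw.VentilatorSettings(bias_flow=8.0, set_PIP=22.0, set_PEEP=8.0,
                                 Ti=0.5, rate=60.0, PIP_max=40.0,
                                 circuit_compliance=0.1)


@pytest.fixture(scope="session")
def default_lung():
    return vw.LungModelParams(C_rs=1.5, R_aw=0.025, weight=3.0)


@pytest.fixture(scope="session")
def rec_clean(default_settings, default_lung):
    """Noise-free 10 s steady-ventilation recording."""
    return vw.simulate_ventilation(default_settings, default_lung, 10.0,
                                   sample_rate=200.0)


@pytest.fixture(scope="session")
def rec_noisy(default_settings, default_lung):
    """Recording with instrument-level sensor noise."""
    return vw.simulate_ventilation(default_settings, default_lung, 10.0,
                                   sample_rate=200.0, seed=42,
                                   noise_sd=(0.1, 0.1, 0.1))


@pytest.fixture(scope="session")
def segs_clean(rec_clean):
    return vw.segment_breaths(rec_clean)


def make_recording(time, pressure, flow, volume, sample_rate=200.0, **kw):
    """Build a recording from plain arrays (test fixture helper)."""
    return vw.WaveformRecording(
        time=np.asarray(time, float), pressure=np.asarray(pressure, float),
        flow=np.asarray(flow, float), volume=np.asarray(volume, float),
        sample_rate=sample_rate, **kw)
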