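import numpy as np
import pytest

from wormdyn import CalciumTraceSet, DFFTraceSet


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_traces(rng):
    """3 neurons x 200 frames at 2 Hz with positive fluorescence."""
    values = 100.0 + 10.0 * rng.random((3, 200))
    return CalciumTraceSet(values=values, sampling_rate=2.0,
                           trial_id="t0", condition="test")


@pytest.fixture
def sinusoid_dff():
    """4 neurons: sin, -sin, sin, -sin at 0.05 Hz, 2 Hz sampling."""
    t = np.arange(1200) / 2.0
    s = np.sin(2 * np.pi * 0.05 * t)
    dff = np.vstack([s, -s, s, -s])
    return DFFTraceSet(dff=dff + 2.0, f0=np.ones(4), mode="trace_mean",
                       sampling_rate=2.0)
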