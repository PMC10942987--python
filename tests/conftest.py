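import numpy as np
import pytest

from vasomotion import synthetic as syn
from vasomotion.traces import TraceSeries


@pytest.fixture
def radius_spec():
    """A standard noiseless 0.1 Hz, 3% oscillation around 20 um."""
    return syn.OscillationSpec(
        base_level=20.0, frequency_hz=0.1, amplitude_frac=0.03, noise_sd=0.0, seed=0
    )


@pytest.fixture
def noisy_trace():
    """A noisy oscillating radius trace (peak deviation / noise SD = 5)."""
    spec = syn.OscillationSpec(
        base_level=20.0, frequency_hz=0.1, amplitude_frac=0.03, noise_sd=0.12, seed=1
    )
    return syn.make_radius_trace(spec)


def make_trace(values, dt=1.0, kind="radius"):
    return TraceSeries(values=np.asarray(values, dtype=float), sampling_interval_s=dt, kind=kind)


@pytest.fixture
def random_traces():
    """A reproducible set of random traces of assorted lengths (N in [20, 200])."""
    rng = np.random.default_rng(12345)
    traces = []
    for _ in range(50):
        n = int(rng.integers(20, 201))
        values = 10.0 + rng.normal(0, 1.0, n).cumsum() * 0.1 + rng.normal(0, 0.5, n)
        traces.append(make_trace(values, dt=float(rng.uniform(0.5, 2.0))))
    return traces
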