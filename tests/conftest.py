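import numpy as np
import pytest

from seismogait import SeismicTrace, StructuringElement


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def flat_se3():
    """Flat SE of length 3 (radius one sample at 100 Hz)."""
    return StructuringElement(radius=0.01, fs=100.0, shape="flat")


@pytest.fixture
def spherical_se():
    """The pipeline-default spherical SE: 0.2 s radius at 100 Hz, length 41."""
    return StructuringElement(radius=0.2, fs=100.0, shape="spherical")


def make_trace(samples, fs=100.0, t0=0.0, sensor_id="s1"):
    return SeismicTrace(sensor_id=sensor_id, t0=t0, fs=fs, samples=np.asarray(samples, float))


@pytest.fixture
def trace_factory():
    return make_trace
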