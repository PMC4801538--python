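import numpy as np
import pytest

from spadflim import DecayMap, SensorConfig


@pytest.fixture
def config():
    """Default sensor: 16x16, 4 TDCs per 8x8, t_p = 360 ps, h = 97.6 ps."""
    return SensorConfig()


@pytest.fixture
def one_subarray_config():
    """A single 8x8 sub-array, convenient for readout-level tests."""
    return SensorConfig(n_rows=8, n_cols=8)


@pytest.fixture
def ideal_config():
    """Readout with no contention: no dead time, one TDC per pixel,
    full 10-bit code range."""
    return SensorConfig(
        dead_time_tp=0.0,
        n_tdc_per_subarray=64,
        tdc_code_max=1024,
    )


def uniform_decay(config: SensorConfig, tau: float, p0: float | None = None) -> DecayMap:
    return DecayMap.uniform(config, tau, p0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
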