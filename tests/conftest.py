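import numpy as np
import pytest

from crackling import (
    NetworkConfig,
    SpikeRaster,
    extract_avalanches,
    network_activity,
    simulate_branching_network,
)


@pytest.fixture(scope="session")
def critical_raster() -> SpikeRaster:
    """One near-critical recording: 100 neurons, 25 min at 50 ms resolution."""
    config = NetworkConfig(
        n_neurons=100,
        branching_parameter=1.0,
        drive_rate=0.001,
        connectivity_degree=10,
        n_bins=30_000,
        bin_width=0.05,
        seed=7,
    )
    return simulate_branching_network(config)


@pytest.fixture(scope="session")
def critical_avalanches(critical_raster):
    """Avalanches of the critical recording at native resolution."""
    return extract_avalanches(network_activity(critical_raster, critical_raster.bin_width))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
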