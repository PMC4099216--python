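import numpy as np
import pytest
from hypothesis import settings

from aselnc.simulate import SimulationConfig, simulate_bundle, write_bundle

# property tests must replay identically on every machine
settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_bundle_data():
    """A modest synthetic dataset shared across tests (40 regions, 188 samples)."""
    cfg = SimulationConfig(seed=11, n_regions=40)
    return simulate_bundle(cfg)


@pytest.fixture(scope="session")
def small_bundle_dir(tmp_path_factory, small_bundle_data):
    out = tmp_path_factory.mktemp("bundle")
    write_bundle(small_bundle_data, out)
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
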