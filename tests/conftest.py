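import numpy as np
import pytest

from rbcforecast import SynthSpec, generate_dataset, split_replicates
from rbcforecast.oe_sysid import OEModelSpec


@pytest.fixture(scope="session")
def default_data():
    """Full study-scale synthetic dataset (96 metabolites, 20 replicates)."""
    ds, truth = generate_dataset(SynthSpec(seed=11))
    return ds, truth


@pytest.fixture(scope="session")
def small_data():
    """Small synthetic dataset for fast pipeline-shaped tests."""
    ds, truth = generate_dataset(
        SynthSpec(seed=5, n_signal_targets=12, n_noise_targets=2)
    )
    return ds, truth


@pytest.fixture(scope="session")
def noiseless_data():
    ds, truth = generate_dataset(
        SynthSpec(seed=9, noise_sd=0.0, bag_sd=0.0, n_signal_targets=8, n_noise_targets=2)
    )
    return ds, truth


@pytest.fixture()
def split20(small_data):
    ds, _ = small_data
    return split_replicates(ds, 42)


@pytest.fixture()
def fir_spec():
    return OEModelSpec(n_inputs=5, nb=1, nf=0, nk=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
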