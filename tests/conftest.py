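import pytest

from neurotracer import datasets
from neurotracer.labelsim import SimulationConfig


@pytest.fixture(scope="session")
def reference_summary():
    return datasets.load_reference_summary()


@pytest.fixture(scope="session")
def reference_iso():
    return datasets.reference_isotopomer_table()


@pytest.fixture(scope="session")
def reference_totals():
    return datasets.reference_total_pool_table()


@pytest.fixture
def noiseless_config():
    return SimulationConfig(cv=0.0, n_replicates=2, seed=0)
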