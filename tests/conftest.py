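import pytest

from methylsieve.filter_pipeline import run_pipeline
from methylsieve.synthetic_data import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def default_dataset(default_config):
    return simulate_dataset(default_config)


@pytest.fixture(scope="session")
def pipeline_result(default_dataset):
    ds = default_dataset
    return run_pipeline(ds.psms, ds.spectra, ds.proteins)
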