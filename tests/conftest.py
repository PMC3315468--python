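import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from azanome.footprint import NDRWindow
from azanome.nome_core import annotate_sites
from azanome.synthetic_data import SimulationConfig, example_amplicon


@pytest.fixture(scope="session")
def region():
    return example_amplicon()


@pytest.fixture(scope="session")
def annotation(region):
    return annotate_sites(region)


@pytest.fixture(scope="session")
def window(region):
    return NDRWindow(region.tss - 100, region.tss + 100, label="TSS±100")


@pytest.fixture()
def config():
    return SimulationConfig(n_molecules=300, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(13)
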