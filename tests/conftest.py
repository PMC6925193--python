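import numpy as np
import pytest

from riverdom.pipeline import PipelineConfig, run_pipeline
from riverdom.synth import TransectDesign, generate_ensembles


@pytest.fixture(scope="session")
def default_transect():
    """The default 18-station synthetic transect ensembles + truth."""
    return generate_ensembles(TransectDesign(seed=0))


@pytest.fixture(scope="session")
def small_design():
    """A fast transect for integration tests."""
    return TransectDesign(n_stations=6, confluence_index=3,
                         shared_core_size=300,
                         unique_per_south_station=10, seed=3)


@pytest.fixture(scope="session")
def full_report():
    """One full default-conditions pipeline run, shared across tests."""
    return run_pipeline(PipelineConfig(seed=1), write=False)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
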