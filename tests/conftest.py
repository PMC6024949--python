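import numpy as np
import pandas as pd
import pytest

from aqburden import (
    AssessmentParams,
    CityPanel,
    GeneratorConfig,
    default_endpoint_set,
    generate_panel,
)
from aqburden.panel import PANEL_COLUMNS


@pytest.fixture(scope="session")
def endpoints():
    return default_endpoint_set()


@pytest.fixture(scope="session")
def params():
    return AssessmentParams()


@pytest.fixture()
def tiny_panel():
    """Two cities, two years, hand-set values for exact arithmetic checks."""
    rows = [
        ("alpha", 2014, 60.0, 1_000_000, 3000.0, 8000.0),
        ("alpha", 2015, 50.0, 1_000_000, 3200.0, 8500.0),
        ("beta", 2014, 40.0, 500_000, 2500.0, 6000.0),
        ("beta", 2015, 35.0, 500_000, 2600.0, 6300.0),
    ]
    return CityPanel(pd.DataFrame(rows, columns=PANEL_COLUMNS))


@pytest.fixture(scope="session")
def small_synth_panel():
    """20-city synthetic panel, fixed seed, for oracle comparisons."""
    return generate_panel(GeneratorConfig(n_cities=20, seed=7))


@pytest.fixture(scope="session")
def default_panel():
    """Full default synthetic panel (190 cities x 3 years, seed 42)."""
    return generate_panel(GeneratorConfig())


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
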