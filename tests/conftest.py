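import numpy as np
import pandas as pd
import pytest

from sporecast import covariates as cov
from sporecast import synthetic as syn


@pytest.fixture(scope="session")
def landscape():
    return syn.generate_landscape(30, 30, spatial_range=3.0, seed=11)


@pytest.fixture(scope="session")
def landscape50():
    return syn.generate_landscape(50, 50, spatial_range=3.0, seed=12)


@pytest.fixture(scope="session")
def scaled_cells(landscape):
    cells, scales = cov.standardize(
        landscape.cells, ["spruce_volume", "temperature", "dist_small_roads",
                          "log_population_density"])
    return cells, scales


@pytest.fixture(scope="session")
def recorders():
    return syn.make_recorders(15, n_thorough=4, seed=13)


def toy_colext_data(rng, n_plots=4):
    """A tiny random two-survey dataset for brute-force likelihood checks."""
    return pd.DataFrame({
        "plot_id": np.arange(n_plots),
        "y1": rng.integers(0, 2, n_plots),
        "y2": rng.integers(0, 2, n_plots),
        "interval_years": rng.uniform(5, 15, n_plots),
        "area_ha": rng.uniform(0.1, 0.4, n_plots),
        "cut": rng.random(n_plots) < 0.4,
        "x": rng.standard_normal(n_plots),
    })
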