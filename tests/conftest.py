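import numpy as np
import pandas as pd
import pytest

import forestvar as fv


@pytest.fixture(scope="session")
def params():
    return fv.default_params()


@pytest.fixture(scope="session")
def climate():
    return fv.ClimateConditions(mat=12.0, map=1100.0)


@pytest.fixture(scope="session")
def truth():
    return fv.generate_truth(seed=0)


@pytest.fixture(scope="session")
def small_inventory():
    """A compact two-region dataset used across io/disturbance tests."""
    truth = fv.generate_truth(n_regions=2, seed=3)
    tables = fv.generate_inventory(truth, n_plots=60, mean_trees_per_plot=15, seed=7)
    return truth, tables


def make_tables(trees: pd.DataFrame, plots: pd.DataFrame) -> fv.InventoryTables:
    return fv.InventoryTables(trees=trees, plots=plots)


@pytest.fixture()
def single_plot_tables():
    """One plot, five large recent-period trees with survival data only.

    The tree outcomes inform exactly one effect component
    (``mort_large_recent``), so the marginal posterior of that component has
    a closed 1-D form against which samplers can be checked.
    """
    plots = pd.DataFrame(
        {
            "plot_id": [1],
            "region": ["r1"],
            "mat": [12.0],
            "map": [1100.0],
            "period": ["recent"],
            "meas_year": [2004],
            "interval_yr": [5.0],
            "forestland": [True],
            "harvested": [False],
            "cond_boundary": [False],
        }
    )
    trees = pd.DataFrame(
        {
            "plot_id": 1,
            "subplot_id": 1,
            "size_class": "large",
            "pft": "north_temperate_hardwood",
            "dbh_t0": [20.0, 25.0, 30.0, 18.0, 22.0],
            "dbh_t1": [np.nan] * 5,
            "status_t1": ["dead", "dead", "live", "live", "dead"],
            "period": "recent",
            "shading_cai": [1.0, 0.5, 1.5, 2.0, 1.0],
        }
    )
    return make_tables(trees, plots)
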