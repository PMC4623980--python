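import numpy as np
import pandas as pd
import pytest

import tunabio as tb
from tunabio import fixtures


def make_std(sfl, rwt, **extra) -> pd.DataFrame:
    """Minimal standardized-records frame for fitting functions."""
    df = pd.DataFrame({"sfl_std": np.asarray(sfl, float),
                       "rwt_std": np.asarray(rwt, float)})
    for k, v in extra.items():
        df[k] = v
    return df


@pytest.fixture(scope="session")
def east_ref():
    """Published annual East weight-length fit."""
    return fixtures.reference_wlr(tb.Stock.EAST)


@pytest.fixture(scope="session")
def west_ref():
    return fixtures.reference_wlr(tb.Stock.WEST)


@pytest.fixture(scope="session")
def east_conversions():
    return fixtures.reference_conversions(tb.Stock.EAST)


@pytest.fixture(scope="session")
def east_dataset():
    """Mid-size generator-default Eastern dataset shared across tests."""
    config = tb.GeneratorConfig.default(tb.Stock.EAST, n_fish=30000, seed=3)
    records = tb.generate_dataset(config)
    return config, records


@pytest.fixture(scope="session")
def east_wlr_input(east_dataset, east_conversions):
    _, records = east_dataset
    std = tb.standardize_records(records, east_conversions)
    return tb.wlr_input(std)
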