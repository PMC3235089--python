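"""Shared fixtures: default structure/config and a reduced synthetic dataset.

The reduced dataset is generated once per session at a fixed seed; tests
that need independent replicates generate their own.
"""

import numpy as np
import pytest

from mast.config import default_config
from mast.equilibrium import StockParams, derive_stock_recruit
from mast.movement import MovementParams, build_all_matrices
from mast.synthetic import default_truth, simulate_dataset


@pytest.fixture(scope="session")
def cfg():
    return default_config()


@pytest.fixture(scope="session")
def structure(cfg):
    return cfg.structure


@pytest.fixture(scope="session")
def derived_default(cfg):
    """DerivedStock per stock at the reported leading-parameter magnitudes."""
    agg = cfg.aggregate_selectivity()
    out = {}
    for stock, msy, fmsy in [("west", 3900.0, 0.15), ("east", 25000.0, 0.2)]:
        bio = cfg.biology[stock]
        out[stock] = derive_stock_recruit(
            StockParams(msy, fmsy, bio.M, bio.weight, bio.maturity, agg)
        )
    return out


@pytest.fixture(scope="session")
def matrices_default(cfg):
    return build_all_matrices(
        MovementParams.uniform(cfg.structure, 0.7), cfg.biology, cfg.structure
    )


@pytest.fixture(scope="session")
def reduced_truth():
    return default_truth("reduced", seed=11)


@pytest.fixture(scope="session")
def reduced_dataset(reduced_truth):
    """(catches, bundle, true trajectory) at the session truth."""
    return simulate_dataset(reduced_truth, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def toy_stock_params(msy=1000.0, fmsy=0.3):
    """3-age toy: flat M=0.2, selectivity (0,1,1), weights (1,2,3) kg,
    maturity (0, 0.5, 1)."""
    return StockParams(
        MSY=msy, Fmsy=fmsy,
        M=np.array([0.2, 0.2, 0.2]),
        weight=np.array([1.0, 2.0, 3.0]),
        maturity=np.array([0.0, 0.5, 1.0]),
        selectivity=np.array([0.0, 1.0, 1.0]),
    )
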