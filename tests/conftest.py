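from __future__ import annotations

import pytest

from capss.config import mini_config, toy_config
from capss.pipeline import run_pipeline

TOY_SEED = 11


@pytest.fixture(scope="session")
def toy_result():
    """One full pipeline run on the default simulated benchmark (96 wells,
    500 kb genome, 5 kb inserts, 30x pools, 0.1% error), shared by all
    recovery tests."""
    return run_pipeline(toy_config(seed=TOY_SEED))


@pytest.fixture(scope="session")
def mini_result():
    """A very small run (12 wells) for fast structural checks."""
    return run_pipeline(mini_config(seed=5))


@pytest.fixture()
def truth_by_well(toy_result):
    return {c.well: c for c in toy_result.sim.truth.clones}
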