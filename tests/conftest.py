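import numpy as np
import pytest

import phyloweber as pw
from phyloweber.model import ModelSpec, fit


@pytest.fixture(scope="session")
def desk_data():
    """Desk-scale synthetic dataset: 8 species, 6 studies, 2000 trials."""
    tree = pw.simulate_tree(8, 1)
    config = pw.desk8(seed=1)
    trials, predictors, truth = pw.simulate_dataset(tree, config)
    cov = pw.tree_to_correlation(tree)
    return {
        "tree": tree,
        "config": config,
        "trials": trials,
        "predictors": predictors,
        "truth": truth,
        "cov": cov,
    }


@pytest.fixture(scope="session")
def small_fit(desk_data):
    """One modest predictor fit shared across model/reporting tests."""
    spec = ModelSpec(
        predictor_name="x", chains=2, warmup=300, draws=300, seed=7
    )
    return fit(
        desk_data["trials"], desk_data["predictors"], desk_data["cov"], spec
    )


@pytest.fixture(scope="session")
def small_fit_nopred(desk_data):
    """No-predictor fit for the species Weber summary path."""
    spec = ModelSpec(
        predictor_name=None, chains=2, warmup=300, draws=300, seed=8
    )
    return fit(desk_data["trials"], None, desk_data["cov"], spec)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
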