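import numpy as np
import pandas as pd
import pytest

from isoweb import (
    FoodWeb,
    IsotopeDataset,
    NicheModelConfig,
    make_test_set,
)
from isoweb.model import IsoWebModel

ELEMENTS = ("d13C", "d15N")


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def chain_web():
    """plant -> herbivore -> predator."""
    return FoodWeb(
        ("plant", "herbivore", "predator"),
        (("herbivore", "plant"), ("predator", "herbivore")),
    )


def make_dataset(web, means=None, n=5, sd=1.0, seed=0):
    """Quick Gaussian replicates for every species/element."""
    rng = np.random.default_rng(seed)
    rows = []
    for sp in web.species:
        for e in ELEMENTS:
            m = 0.0 if means is None else means.get((sp, e), 0.0)
            for v in rng.normal(m, sd, n):
                rows.append({"species": sp, "element": e, "value": float(v)})
    return IsotopeDataset(pd.DataFrame(rows))


@pytest.fixture
def dataset_factory():
    return make_dataset


@pytest.fixture(scope="session")
def small_testset():
    """One reusable small simulated experiment (8 species, sigma^2 = 1)."""
    return make_test_set(NicheModelConfig(S=8, C=0.12, seed=2), n=10, variances=1.0, seed=2)


@pytest.fixture(scope="session")
def small_fit(small_testset):
    """A short two-chain fit of the small test set, reused across tests."""
    model = IsoWebModel(small_testset.web, small_testset.data)
    return model.fit(iterations=3000, burn_in=1500, thin=2, chains=2, seed=5)
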