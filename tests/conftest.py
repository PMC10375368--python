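import numpy as np
import pandas as pd
import pytest

from specstruct.phylo import read_newick
from specstruct.popgen import GenotypeMatrix
from specstruct.simulate import SimTreeParams, simulate_bd_tree


@pytest.fixture(scope="session")
def yule_tree():
    """A ~120-tip Yule tree used by signal/PGLS recovery tests."""
    return simulate_bd_tree(
        SimTreeParams(
            lambda_fn=lambda t: 0.2,
            mu_fn=lambda t: 0.0,
            present=23.0,
            min_tips=100,
            seed=7,
        )
    )


@pytest.fixture
def caterpillar():
    return read_newick("((((A:1,B:1):1,C:2):1,D:3):1,E:4);")


def make_genotypes(calls, species="toy"):
    """GenotypeMatrix from a plain list of dosage rows (NaN = missing)."""
    arr = np.asarray(calls, dtype=float)
    n = arr.shape[0]
    coords = pd.DataFrame(
        {
            "individual_id": [f"i{k}" for k in range(n)],
            "species": species,
            "latitude": np.linspace(-19.0, -18.5, n),
            "longitude": np.linspace(47.0, 47.5, n),
        }
    )
    return GenotypeMatrix([f"i{k}" for k in range(n)], arr, species, coords)


@pytest.fixture
def toy_genotypes():
    return make_genotypes
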