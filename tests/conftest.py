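import numpy as np
import pandas as pd
import pytest

from surfclass import (
    PlantedTableSpec,
    SplitSpec,
    StructureSpec,
    make_planted_table,
    make_structure,
    run_protocol,
)

#: small-but-realistic protocol settings used across tests (the library
#: defaults match the full study protocol: 150 iterations, 500 trees)
FAST_SPLIT = SplitSpec(train_fraction=0.70, n_iterations=8)
FAST_RF = {"n_estimators": 100}


@pytest.fixture(scope="session")
def helix15():
    """Ideal poly-Ala alpha-helix, 15 residues."""
    return make_structure(StructureSpec("A" * 15, "helix", 0.0, seed=1))


@pytest.fixture(scope="session")
def mixed_structures():
    """Small set of varied toy structures with labels."""
    recipes = [
        ("ACDEFGHIKLMNPQRSTVWY", "helix", 0.05, 0, "cytosol"),
        ("AAAAACCCCCEEEEELLLLL", "strand", 0.05, 1, "secreted"),
        ("GGGGSSSSDDDDKKKKLLLL", "coil-perturbed", 0.1, 2, "cytosol"),
        ("LLLLKKKKEEEEAAAAGGGG", "helix", 0.1, 3, "secreted"),
        ("MNPQRSTVWYACDEFGHIKL", "extended", 0.05, 4, "cytosol"),
        ("CCLLEEGGKKAASSTTVVYY", "coil-perturbed", 0.1, 5, "secreted"),
    ]
    return [
        (make_structure(StructureSpec(seq, geo, sd, seed)), label)
        for seq, geo, sd, seed, label in recipes
    ]


@pytest.fixture(scope="session")
def planted_table():
    """Default planted-rule table: Glu<9.0 & Cys>1.8 & Leu>5.8, 5% noise."""
    return make_planted_table(PlantedTableSpec(n_per_class=400, seed=7))


@pytest.fixture(scope="session")
def planted_result(planted_table):
    """One protocol run on the planted table (shared across tests)."""
    return run_protocol(planted_table, FAST_SPLIT, FAST_RF, seed=1)


@pytest.fixture(scope="session")
def toy_table():
    """Tiny two-feature linearly separable table."""
    rng = np.random.default_rng(0)
    n = 40
    x = rng.uniform(0, 10, n)
    y = rng.uniform(0, 10, n)
    t = pd.DataFrame({"fa": x, "fb": y})
    t["class"] = np.where(x > 5.0, "secreted", "cytosol")
    t.index = [f"p{i}" for i in range(n)]
    return t
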