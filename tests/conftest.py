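import dendropy
import numpy as np
import pandas as pd
import pytest

from befgrass.data_model import CommunityTable, TraitTable


@pytest.fixture(scope="session")
def toy_community() -> CommunityTable:
    """Three quadrats over two sites, five species, hand-set abundances."""
    rows = [
        # quadrat, site, species, biomass, cover, density
        ("Q1", "S1", "sp1", 3.0, 0.5, 10.0),
        ("Q1", "S1", "sp2", 1.0, 0.5, 30.0),
        ("Q2", "S1", "sp1", 5.0, 0.3, 12.0),
        ("Q2", "S1", "sp3", 2.0, 0.2, 4.0),
        ("Q2", "S1", "sp4", 1.0, 0.1, 2.0),
        ("Q3", "S2", "sp5", 7.5, 0.8, 100.0),
    ]
    data = pd.DataFrame(
        rows, columns=["quadrat_id", "site_id", "species", "biomass", "cover", "density"]
    )
    return CommunityTable(data=data)


@pytest.fixture(scope="session")
def toy_traits() -> TraitTable:
    species = [f"sp{i}" for i in range(1, 6)]
    rng = np.random.default_rng(42)
    data = pd.DataFrame(
        {
            "SLA": 10 * np.exp(rng.normal(0, 0.3, 5)),
            "leaf_size": 3 * np.exp(rng.normal(0, 0.5, 5)),
            "height": 12 * np.exp(rng.normal(0, 0.4, 5)),
            "seed_mass": 1.5 * np.exp(rng.normal(0, 0.6, 5)),
        },
        index=pd.Index(species, name="species"),
    )
    return TraitTable(data=data)


@pytest.fixture(scope="session")
def toy_tree() -> dendropy.Tree:
    """Ultrametric 5-tip tree covering the toy community's species."""
    newick = "(((sp1:5,sp2:5):10,sp3:15):15,(sp4:20,sp5:20):10):0;"
    return dendropy.Tree.get(data=newick, schema="newick")
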