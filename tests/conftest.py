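import numpy as np
import pandas as pd
import pytest

import assemblage as A
from assemblage.io import CountTable, PhyloTree


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def three_tip_tree():
    """((A:1,B:1):1,C:2); — d(A,B)=2, d(A,C)=d(B,C)=4."""
    import io

    return PhyloTree.from_newick(io.StringIO("((A:1,B:1):1,C:2);"))


@pytest.fixture()
def four_tip_tree():
    import io

    return PhyloTree.from_newick(io.StringIO("((A:1,B:1):1,(C:1,D:1):1);"))


def random_tree(n_tips: int, seed: int) -> PhyloTree:
    return A.simulate_tree(n_tips, seed=seed)


def random_table(n_samples: int, n_taxa: int, seed: int, depth: int = 500) -> CountTable:
    rng = np.random.default_rng(seed)
    p = rng.dirichlet(np.ones(n_taxa))
    counts = np.array([rng.multinomial(depth, p) for _ in range(n_samples)])
    return CountTable(
        counts,
        [f"S{i}" for i in range(n_samples)],
        [f"OTU{j + 1:04d}" for j in range(n_taxa)],
    )


@pytest.fixture(scope="session")
def small_bundle():
    """The default small synthetic fixture (60 samples, 150 taxa)."""
    return A.generate(A.preset_config("squirrel-small", seed=11))


@pytest.fixture(scope="session")
def processed_bundle(small_bundle):
    """Fixture after the study's preprocessing (5% prevalence, depth 9724)."""
    table = A.prevalence_filter(small_bundle.table)
    table = A.rarefy(table, 9724, seed=5)
    table, tree, meta = A.align_inputs(table, small_bundle.tree, small_bundle.metadata)
    return table, tree, meta


def small_metadata(sample_ids, seed=0):
    rng = np.random.default_rng(seed)
    n = len(sample_ids)
    land = rng.choice(["campus", "suburban_park", "urban_forest", "rural_forest"], n)
    env = np.where(land == "rural_forest", "rural", "city")
    local = np.where(np.isin(land, ["campus", "suburban_park"]), "built", "forest")
    return pd.DataFrame(
        {
            "sample_id": sample_ids,
            "site": rng.choice(["X1", "X2", "X3"], n),
            "environment": env,
            "land_class": land,
            "local_type": local,
            "phenotype_alleles": rng.choice([0, 1, 2], n),
            "sex": rng.choice(["F", "M"], n),
        }
    )
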