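import sys
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from cryoassembly.io import FeatureTable
from cryoassembly.phylo import patristic_distance_matrix
from cryoassembly.synthetic import ScenarioConfig, simulate_metacommunity


def tree_from_newick(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)


@pytest.fixture(scope="session")
def toy_table() -> FeatureTable:
    """Ten samples x eight taxa with assorted abundances, no zero samples."""
    rng = np.random.default_rng(17)
    counts = rng.integers(0, 30, size=(10, 8))
    counts[:, 0] += 1  # no all-zero samples
    ids = [f"S{i}" for i in range(10)]
    taxa = [f"t{j}" for j in range(8)]
    return FeatureTable(pd.DataFrame(counts, index=ids, columns=taxa))


@pytest.fixture(scope="session")
def mixed_dataset():
    """A small mixed-regime metacommunity with its patristic matrix."""
    ds = simulate_metacommunity(
        ScenarioConfig(n_sites=16, n_taxa=80, depth=600, regime="mixed", seed=42)
    )
    pat = patristic_distance_matrix(ds.tree, ds.table.taxon_ids)
    return ds, pat
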