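import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import atlastools as at


@pytest.fixture(scope="session")
def small_atlas():
    """300 cells, 3 types, planted markers, no cycling signal in type2."""
    spec = at.AtlasSimSpec(
        n_cell_types=3,
        cells_per_type=100,
        n_genes=300,
        markers_per_type=8,
        marker_fold_change=8.0,
        cycling_fraction_per_type=[0.5, 0.2, 0.0],
        seed=11,
    )
    counts, ann, sets, labels = at.simulate_counts(spec)
    return counts, ann, sets, labels


@pytest.fixture(scope="session")
def small_normalized(small_atlas):
    counts, ann, sets, labels = small_atlas
    return at.lognormalize(counts), ann, sets, labels


@pytest.fixture()
def tiny_counts():
    """3 cells x 4 genes with 5 stored entries."""
    mat = sp.csr_matrix(
        np.array([[5, 0, 0, 2], [0, 3, 0, 0], [0, 0, 7, 1]], dtype=int)
    )
    return at.CountMatrix(["c1", "c2", "c3"], ["g1", "g2", "g3", "g4"], mat)


@pytest.fixture(scope="session")
def metabolome_blocks():
    """4 species x 5 replicates, 2 planted correlated blocks, one planted
    species-A high set."""
    spec = at.MetabolomeSimSpec(
        n_metabolites=50,
        planted_high_sets={"speciesA": [f"M{i:04d}" for i in range(5)]},
        block_structure=[
            [f"M{i:04d}" for i in range(10, 16)],
            [f"M{i:04d}" for i in range(20, 26)],
        ],
        block_corr=0.9,
        seed=21,
    )
    return at.simulate_metabolome(spec), spec
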