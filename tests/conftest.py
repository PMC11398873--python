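import numpy as np
import pandas as pd
import pytest

from sigsearch import GeneSignature, ReferencePanel, TaggedSignature


@pytest.fixture
def five_gene_signature():
    return GeneSignature(
        genes=("g1", "g2", "g3", "g4", "g5"),
        stats=(3.0, 2.0, 0.5, -1.0, -2.5),
    )


@pytest.fixture
def four_gene_panel():
    """Single drug column {g1: 3, g2: -2, g3: 1, g4: -0.5}."""
    return ReferencePanel(
        pd.DataFrame({"d1": [3.0, -2.0, 1.0, -0.5]}, index=["g1", "g2", "g3", "g4"])
    )


@pytest.fixture
def descending_panel():
    """Single drug whose descending gene order is exactly g1, g2, g3, g4."""
    return ReferencePanel(
        pd.DataFrame({"d1": [3.0, 2.0, 1.0, 0.5]}, index=["g1", "g2", "g3", "g4"])
    )


def random_panel(rng, n_genes, n_drugs):
    genes = [f"g{i}" for i in range(1, n_genes + 1)]
    drugs = [f"d{i}" for i in range(1, n_drugs + 1)]
    mat = rng.uniform(-5, 5, (n_genes, n_drugs))
    return ReferencePanel(pd.DataFrame(mat, index=genes, columns=drugs))


def random_tagged(rng, panel, n_up, n_down):
    """A tag signature drawn from the panel's gene universe with random stats."""
    genes = rng.permutation(panel.gene_ids)
    assert n_up == n_down
    up = tuple(genes[:n_up])
    down = tuple(genes[n_up : n_up + n_down])
    return TaggedSignature(
        up_tags=up,
        down_tags=down,
        topn=n_up,
        up_stats=tuple(rng.uniform(0.1, 5, n_up)),
        down_stats=tuple(-rng.uniform(0.1, 5, n_down)),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
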