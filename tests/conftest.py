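import numpy as np
import pandas as pd
import pytest

from abacross import InteractionNetwork
from abacross.deg import CONTRASTS


def make_contrast_table(rows: dict) -> pd.DataFrame:
    """Build a contrast table from {gene: {column: value}} with NaN defaults
    filled as clearly non-significant values (log2fc=0, p=1)."""
    table = pd.DataFrame.from_dict(rows, orient="index")
    for c in CONTRASTS:
        for kind, default in (("log2fc", 0.0), ("p", 1.0)):
            col = f"{kind}_{c}"
            if col not in table.columns:
                table[col] = default
            table[col] = table[col].fillna(default)
    table.index.name = "gene_id"
    return table


@pytest.fixture
def toy_cross_net() -> InteractionNetwork:
    """Edges {(a1,b1),(a1,b2),(a2,a3),(b1,b3)} over 6 named genes."""
    return InteractionNetwork.from_gene_pairs(
        [("a1", "b1"), ("a1", "b2"), ("a2", "a3"), ("b1", "b3")],
        nodes=["a1", "a2", "a3", "b1", "b2", "b3"],
    )


@pytest.fixture
def six_cycle() -> InteractionNetwork:
    genes = [f"g{i}" for i in range(1, 7)]
    pairs = [(genes[i], genes[(i + 1) % 6]) for i in range(6)]
    return InteractionNetwork.from_gene_pairs(pairs, nodes=genes)


def brute_force_cross_counts(edges_by_gene, set_A, set_B):
    """Edge-by-edge enumeration oracle: per-gene and total cross counts.

    ``edges_by_gene`` is an iterable of (gene_a, gene_b) pairs.
    """
    per_gene = {g: 0 for g in list(set_A) + list(set_B)}
    total = 0
    for a, b in edges_by_gene:
        if (a in set_A and b in set_B) or (a in set_B and b in set_A):
            per_gene[a] += 1
            per_gene[b] += 1
            total += 1
    return per_gene, total


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
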