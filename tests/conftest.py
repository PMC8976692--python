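import numpy as np
import pytest

from colepop.geno_io import MISSING, GenotypeMatrix
from colepop.synthetic_data import SimulationConfig, simulate_dataset


@pytest.fixture
def tiny_gm() -> GenotypeMatrix:
    """3 accessions × 4 loci, hand-checkable, no missing data."""
    calls = np.array(
        [
            [0, 1, 2, 0],
            [0, 0, 2, 2],
            [2, 2, 0, 1],
        ],
        dtype=np.int8,
    )
    return GenotypeMatrix(
        ["acc1", "acc2", "acc3"],
        np.array(["chr1", "chr1", "chr1", "chr2"], dtype=object),
        np.array([100, 500, 900, 250]),
        calls,
    )


@pytest.fixture(scope="session")
def sim_ds():
    """One reusable desk-scale simulated dataset (8 groups × 12 × 600 loci)."""
    return simulate_dataset(SimulationConfig(n_loci=600, seed=11))


def random_species_tree(labels, rng, internal=(0.15, 0.3), terminal=(0.1, 0.2)):
    """Random rooted binary species tree (Newick) with drift-unit lengths."""
    from colepop import geno_io
    from colepop.species_tree import _edges_to_tree, root_at_outgroup

    n = len(labels)
    edges = [(0, n), (1, n), (2, n)]
    nxt = n + 1
    for leaf in range(3, n):
        ei = int(rng.integers(len(edges)))
        u, v = edges[ei]
        edges = edges[:ei] + edges[ei + 1:] + [(u, nxt), (v, nxt), (leaf, nxt)]
        nxt += 1
    tree = root_at_outgroup(_edges_to_tree(edges, list(labels)), labels[-1])
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        lo, hi = terminal if node.is_leaf() else internal
        node.edge.length = float(rng.uniform(lo, hi))
    return geno_io.tree_to_newick(tree)


def random_gm(rng: np.random.Generator, n_acc: int = 6, n_loci: int = 40,
              missing_rate: float = 0.0) -> GenotypeMatrix:
    """Random valid genotype matrix for round-trip / property tests."""
    calls = rng.integers(0, 3, size=(n_acc, n_loci)).astype(np.int8)
    if missing_rate > 0:
        calls[rng.random(calls.shape) < missing_rate] = MISSING
    n1 = n_loci // 2
    pos = np.concatenate([
        np.sort(rng.choice(10_000, size=n1, replace=False)) + 1,
        np.sort(rng.choice(10_000, size=n_loci - n1, replace=False)) + 1,
    ])
    chrom = np.array(["chr1"] * n1 + ["chr2"] * (n_loci - n1), dtype=object)
    ids = [f"s{i}" for i in range(n_acc)]
    return GenotypeMatrix(ids, chrom, pos, calls)
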