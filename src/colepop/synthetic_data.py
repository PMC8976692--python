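"""Synthetic genotype panels with known population structure.

The generator emulates the statistical design of a reduced-representation
SNP survey of a domesticated crop complex: several morphotype groups that
diverged along a known species tree, one severely bottlenecked lineage (the
cauliflower analogue), modern F1 hybrid accessions that are less diverse than
genebank landraces, sparse markers scattered along chromosomes, and a small
fraction of missing calls.

Allele frequencies drift along the species tree under the Balding–Nichols
beta kernel: a branch of length ``t`` (drift units) turns an incoming
frequency ``p`` into a Beta draw with mean ``p`` and variance
``F·p·(1−p)`` where ``F = 1 − exp(−t)``.  The closed-form moments make the
simulator usable as a ground truth for F_ST parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .errors import ValidationError
from .geno_io import MISSING, UNKNOWN, GenotypeMatrix, read_newick

#: Desk-scale default species tree (branch lengths in drift units).  Eight
#: morphotype-analogue groups: a wild outgroup pair, a kale progenitor grade,
#: a leafy-head side (heading cabbage, Brussels sprouts) and an arrested-
#: inflorescence side (broccoli, cauliflower) plus kohlrabi.
DEFAULT_SPECIES_TREE = (
    "((((((cauliflower:0.10,broccoli:0.10):0.15,kohlrabi:0.25):0.08,"
    "(heading_cabbage:0.18,brussels_sprouts:0.18):0.15):0.08,kale:0.30):0.10,"
    "wild_oleracea:0.40):0.20,wild_C9:0.60);"
)


@dataclass
class SimulationConfig:
    """Parameters of one synthetic dataset.

    Defaults are the desk-scale stand-in for the study design: 8 groups ×
    12 accessions × 2 000 loci on three 1 Mb chromosomes, a 0.2-severity
    bottleneck on the cauliflower analogue, 25% hybrid accessions per group
    and 2% missing calls.
    """

    species_tree: str = DEFAULT_SPECIES_TREE
    n_accessions_per_group: Mapping[str, int] | int = 12
    n_loci: int = 2000
    chromosome_layout: Sequence[tuple[str, int]] = (
        ("chr1", 1_000_000),
        ("chr2", 1_000_000),
        ("chr3", 1_000_000),
    )
    bottleneck_group: str | None = "cauliflower"
    bottleneck_severity: float = 0.2
    hybrid_fraction: float | Mapping[str, float] = 0.25
    missing_rate: float = 0.02
    seed: int = 0
    # gamete-pool sharpening exponent for hybrids (see sample_accessions)
    hybrid_sharpening: float = 2.0

    def tree(self) -> dendropy.Tree:
        return read_newick(self.species_tree)

    def groups(self) -> list[str]:
        t = self.tree()
        return [leaf.taxon.label for leaf in t.leaf_node_iter()]

    def n_for(self, group: str) -> int:
        if isinstance(self.n_accessions_per_group, Mapping):
            return int(self.n_accessions_per_group[group])
        return int(self.n_accessions_per_group)

    def hybrid_fraction_for(self, group: str) -> float:
        if isinstance(self.hybrid_fraction, Mapping):
            return float(self.hybrid_fraction.get(group, 0.0))
        return float(self.hybrid_fraction)

    def validate(self) -> None:
        if not (0 < self.bottleneck_severity <= 1):
            raise ValidationError("bottleneck severity must be in (0, 1]")
        if not (0 <= self.missing_rate < 1):
            raise ValidationError("missing_rate must be in [0, 1)")
        if self.n_loci < 1:
            raise ValidationError("n_loci must be >= 1")
        groups = self.groups()
        if self.bottleneck_group is not None and self.bottleneck_group not in groups:
            raise ValidationError(
                f"bottleneck_group {self.bottleneck_group!r} not a species-tree tip"
            )
        if isinstance(self.n_accessions_per_group, Mapping):
            extra = set(self.n_accessions_per_group) - set(groups)
            if extra:
                raise ValidationError(f"groups {sorted(extra)} not in species tree")
        for g in groups:
            if self.n_for(g) < 2:
                raise ValidationError(f"group {g!r} needs >= 2 accessions")


@dataclass
class SimulatedDataset:
    genotypes: GenotypeMatrix
    meta: pd.DataFrame
    truth_tree: dendropy.Tree
    truth_group_freqs: pd.DataFrame  # groups × locus ids, in [0, 1]


def _drift(p: np.ndarray, t: float, rng: np.random.Generator) -> np.ndarray:
    """Balding–Nichols step: Beta with mean p, variance F p(1-p), F=1-exp(-t)."""
    if not np.isfinite(t) or t < 0:
        raise ValidationError(f"non-finite or negative branch length {t}")
    F = 1.0 - np.exp(-t)
    if F <= 0:
        return p.copy()
    lam = (1.0 - F) / F
    out = p.copy()
    seg = (p > 0) & (p < 1)  # fixed alleles stay fixed
    out[seg] = rng.beta(lam * p[seg], lam * (1.0 - p[seg]))
    return out


def simulate_frequencies(config: SimulationConfig, rng: np.random.Generator | None = None
                         ) -> pd.DataFrame:
    """Drift ancestral allele frequencies down the species tree.

    Ancestral frequencies are Uniform(0.05, 0.95) per locus; each branch
    applies the Balding–Nichols kernel.  The bottleneck group's terminal
    branch has its drift time multiplied by 1/severity, so a smaller severity
    means more drift and less within-group diversity.

    Returns a groups × loci DataFrame of alternate-allele frequencies.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    tree = config.tree()
    anc = rng.uniform(0.05, 0.95, size=config.n_loci)
    freqs: dict[str, np.ndarray] = {}

    def descend(node: dendropy.Node, p: np.ndarray) -> None:
        for child in node.child_nodes():
            t = child.edge.length or 0.0
            if child.is_leaf():
                label = child.taxon.label
                if label == config.bottleneck_group:
                    t = t / config.bottleneck_severity
                freqs[label] = _drift(p, t, rng)
            else:
                descend(child, _drift(p, t, rng))

    descend(tree.seed_node, anc)
    return pd.DataFrame.from_dict(freqs, orient="index")


def _place_loci(config: SimulationConfig, rng: np.random.Generator
                ) -> tuple[np.ndarray, np.ndarray]:
    """Scatter loci uniformly at random along the chromosome layout."""
    layout = list(config.chromosome_layout)
    lengths = np.array([L for _, L in layout], dtype=float)
    n_per = rng.multinomial(config.n_loci, lengths / lengths.sum())
    chroms, positions = [], []
    for (name, length), n in zip(layout, n_per):
        n = min(n, length)  # positions must be unique within the chromosome
        pos = rng.choice(length, size=n, replace=False) + 1
        pos.sort()
        chroms.extend([name] * n)
        positions.extend(pos.tolist())
    return np.array(chroms, dtype=object), np.array(positions, dtype=np.int64)


def sample_accessions(freqs: pd.DataFrame, config: SimulationConfig,
                      rng: np.random.Generator | None = None) -> SimulatedDataset:
    """Draw diploid accessions from group allele frequencies.

    Genebank accessions are binomial(2, p) draws.  Hybrid accessions are
    crosses of two independent gametes drawn from a *sharpened* frequency
    pool p' = p^γ / (p^γ + (1−p)^γ) (γ = ``hybrid_sharpening`` > 1), which
    pushes frequencies toward fixation and gives hybrids lower within-class
    diversity than genebank accessions, mirroring F1 cultivar uniformity.
    Missing calls are applied uniformly at ``missing_rate``.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    if ((freqs.to_numpy() < 0) | (freqs.to_numpy() > 1)).any():
        raise ValidationError("allele frequencies must lie in [0, 1]")
    chroms, positions = _place_loci(config, rng)
    n_loci = positions.size

    ids: list[str] = []
    rows: list[np.ndarray] = []
    meta_rows: list[dict] = []
    gamma = config.hybrid_sharpening
    for group in freqs.index:
        p = freqs.loc[group].to_numpy()[:n_loci]
        n = config.n_for(group)
        n_hybrid = int(round(config.hybrid_fraction_for(group) * n))
        with np.errstate(divide="ignore", invalid="ignore"):
            p_sharp = np.where(
                (p > 0) & (p < 1),
                p**gamma / (p**gamma + (1.0 - p)**gamma),
                p,
            )
        for i in range(n):
            acc = f"{group}_{i:03d}"
            if i < n_hybrid:
                g = rng.binomial(1, p_sharp) + rng.binomial(1, p_sharp)
                source = "hybrid"
            else:
                g = rng.binomial(2, p)
                source = "genebank"
            ids.append(acc)
            rows.append(g.astype(np.int8))
            meta_rows.append(
                dict(accession_id=acc, morphotype=group, subgroup=UNKNOWN,
                     source_class=source, region=UNKNOWN)
            )
    calls = np.stack(rows)
    if config.missing_rate > 0:
        mask = rng.random(calls.shape) < config.missing_rate
        calls[mask] = MISSING
    gm = GenotypeMatrix(ids, chroms, positions, calls)
    meta = pd.DataFrame(meta_rows)
    truth = freqs.iloc[:, :n_loci].copy()
    truth.columns = gm.locus_ids()
    return SimulatedDataset(gm, meta, config.tree(), truth)


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Frequencies + accessions in one call, all randomness from config.seed."""
    rng = np.random.default_rng(config.seed)
    freqs = simulate_frequencies(config, rng)
    return sample_accessions(freqs, config, rng)


@dataclass
class CharacterSimulation:
    tip_states: dict[str, str]
    node_states: dict  # dendropy.Node -> state, includes root and internals
    root_state: str


def simulate_character(truth_tree: dendropy.Tree, states: Sequence[str],
                       rate: float, seed: int) -> CharacterSimulation:
    """Evolve a categorical character along a tree by a Markov jump process.

    Along a branch of length t the state is retained with probability
    exp(−rate·t), otherwise resampled uniformly from the alphabet (so the
    stationary distribution is uniform).  Branches without lengths count as
    length 1.
    """
    if len(states) < 2:
        raise ValidationError("need at least 2 character states")
    if rate < 0:
        raise ValidationError("rate must be >= 0")
    rng = np.random.default_rng(seed)
    states = list(states)
    node_states: dict = {}
    root = truth_tree.seed_node
    node_states[root] = states[rng.integers(len(states))]
    for node in truth_tree.preorder_node_iter():
        if node is root:
            continue
        t = node.edge.length if node.edge.length is not None else 1.0
        parent_state = node_states[node.parent_node]
        if rng.random() < np.exp(-rate * t):
            node_states[node] = parent_state
        else:
            node_states[node] = states[rng.integers(len(states))]
    tips = {n.taxon.label: node_states[n] for n in truth_tree.leaf_node_iter()}
    return CharacterSimulation(tips, node_states, node_states[root])
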