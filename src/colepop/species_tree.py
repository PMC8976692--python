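"""Lineage-level species-tree estimation from SNP matrices by SVD-quartets.

For every quartet of lineages the three possible splits are scored by how
close the quartet's site-pattern *flattening* matrix is to the low rank that
a true species-tree split implies under the multispecies coalescent; the
split of minimum score wins, and the quartet splits are amalgamated into a
species tree (exhaustive search over topologies for ≤ 8 lineages, greedy
stepwise insertion plus NNI hill-climbing above that).  Site-resampling
bootstrap yields per-clade support; edges below a support threshold can be
collapsed.

Diploid dosages are expanded probabilistically: an accession with dosage d
contributes allele weights (1 − d/2, d/2), so heterozygotes are handled
deterministically rather than by random phasing.  Pattern weights are
aggregated over *all* one-accession-per-lineage member combinations: the sum
of product weights over the Cartesian product of lineage members factorises
into a per-site product of per-lineage sums, so the full aggregation is
computed in closed form with no combination cap or subsampling (missing
members simply drop out of the per-lineage sum, which is exactly the
"skip combinations containing a missing member" rule).

The flattening of a k-state alphabet is k²×k²; a true split's flattening has
rank ≤ k(k+1)/2 under the coalescent, so the score is the Frobenius distance
to the best rank-k(k+1)/2 approximation: rank 3 for the binary dosage
default, the canonical rank 10 for 4-state nucleotide encoding.
"""

from __future__ import annotations

import functools
import itertools
import logging
from collections import deque
from dataclasses import dataclass
from typing import Mapping, Sequence

import dendropy
import numpy as np

from .errors import ValidationError
from .geno_io import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

Split = tuple[tuple[str, str], tuple[str, str]]


@dataclass
class LineageAssignment:
    """Map accession → lineage; the lineages are the species-tree taxa."""

    mapping: dict[str, str]

    def __post_init__(self) -> None:
        if len(self.lineages) < 4:
            raise ValidationError("need >= 4 lineages for quartet analysis")

    @property
    def lineages(self) -> list[str]:
        return sorted(set(self.mapping.values()))

    def members(self, lineage: str) -> list[str]:
        return sorted(a for a, l in self.mapping.items() if l == lineage)

    def validate_against(self, gm: GenotypeMatrix) -> None:
        unknown = set(self.mapping) - set(gm.accession_ids)
        if unknown:
            raise ValidationError(f"assigned accessions not in matrix: {sorted(unknown)[:5]}")

    @classmethod
    def from_metadata(cls, meta, column: str = "morphotype") -> "LineageAssignment":
        return cls(dict(zip(meta["accession_id"], meta[column])))


@dataclass
class QuartetScore:
    """SVD scores for the three splits of one lineage quartet."""

    lineages: tuple[str, str, str, str]  # sorted
    scores: dict[str, float]  # split string "a,b|c,d" → score
    chosen: Split
    margin: float  # second-best score − best score

    @property
    def chosen_string(self) -> str:
        (a, b), (c, d) = self.chosen
        return f"{a},{b}|{c},{d}"


# --------------------------------------------------------------------------- #
# pattern profiles and flattenings
# --------------------------------------------------------------------------- #


def lineage_profiles(
    gm: GenotypeMatrix,
    assignment: LineageAssignment,
    ref_alleles: Sequence[str] | None = None,
    alt_alleles: Sequence[str] | None = None,
) -> tuple[list[str], np.ndarray]:
    """Per-lineage per-site allele-weight sums.

    Returns the sorted lineage labels and an array ``S`` of shape
    ``(n_lineages, n_sites, k)`` where ``S[L, s]`` is the sum over
    non-missing members of the accession's allele-probability vector.  With
    the binary default k = 2 (ref, alt); passing per-locus ``ref_alleles`` /
    ``alt_alleles`` nucleotide letters selects the 4-state A,C,G,T encoding
    (k = 4).
    """
    assignment.validate_against(gm)
    labels = assignment.lineages
    if ref_alleles is not None or alt_alleles is not None:
        if ref_alleles is None or alt_alleles is None:
            raise ValidationError("need both ref_alleles and alt_alleles")
        alphabet = "ACGT"
        ref_idx = np.array([alphabet.index(a) for a in ref_alleles])
        alt_idx = np.array([alphabet.index(a) for a in alt_alleles])
        if ref_idx.size != gm.n_loci or alt_idx.size != gm.n_loci:
            raise ValidationError("allele arrays must have one letter per locus")
        k = 4
    else:
        ref_idx = np.zeros(gm.n_loci, dtype=np.intp)
        alt_idx = np.ones(gm.n_loci, dtype=np.intp)
        k = 2
    sites = np.arange(gm.n_loci)
    S = np.zeros((len(labels), gm.n_loci, k))
    for li, lab in enumerate(labels):
        for acc in assignment.members(lab):
            row = gm.calls[gm.accession_ids.index(acc)].astype(np.float64)
            ok = row != MISSING
            p_alt = np.where(ok, row / 2.0, 0.0)
            p_ref = np.where(ok, 1.0 - row / 2.0, 0.0)
            np.add.at(S[li], (sites, ref_idx), p_ref)
            np.add.at(S[li], (sites, alt_idx), p_alt)
    return labels, S


def site_pattern_flattening(
    gm: GenotypeMatrix,
    assignment: LineageAssignment,
    quartet: Sequence[str],
    split: Split,
    weights: np.ndarray | None = None,
    **profile_kwargs,
) -> np.ndarray:
    """The k²×k² site-pattern flattening for one split of one quartet.

    Rows index the joint allele states of the split's left pair, columns the
    right pair; entry mass aggregates over all sites and all one-per-lineage
    member combinations with no missing member.
    """
    if len(set(quartet)) != 4:
        raise ValidationError(f"quartet must contain 4 distinct lineages, got {quartet}")
    (a, b), (c, d) = split
    if sorted((a, b, c, d)) != sorted(quartet):
        raise ValidationError("split lineages do not match the quartet")
    labels, S = lineage_profiles(gm, assignment, **profile_kwargs)
    idx = {lab: i for i, lab in enumerate(labels)}
    for lab in quartet:
        if lab not in idx:
            raise ValidationError(f"lineage {lab!r} not in assignment")
    w = np.ones(gm.n_loci) if weights is None else np.asarray(weights, dtype=np.float64)
    Sa, Sb, Sc, Sd = (S[idx[l]] for l in (a, b, c, d))
    k = S.shape[2]
    left = (Sa[:, :, None] * Sb[:, None, :]).reshape(gm.n_loci, k * k)
    right = (Sc[:, :, None] * Sd[:, None, :]).reshape(gm.n_loci, k * k)
    return (left * w[:, None]).T @ right


def svd_score(flattening: np.ndarray, rank: int | None = None) -> float:
    """Frobenius distance of the normalised flattening to its best low-rank
    approximation.

    ``rank`` defaults to k(k+1)/2 for a k²×k² flattening (3 for binary, 10
    for nucleotide) — the rank bound a true split satisfies under the
    coalescent.
    """
    M = np.asarray(flattening, dtype=np.float64)
    norm = np.linalg.norm(M)
    if norm == 0:
        raise ValidationError("all-zero flattening cannot be scored")
    if rank is None:
        k = int(round(np.sqrt(M.shape[0])))
        if k * k != M.shape[0]:
            raise ValidationError(f"flattening side {M.shape[0]} is not a square of k")
        rank = k * (k + 1) // 2
    sv = np.linalg.svd(M / norm, compute_uv=False)
    return float(np.sqrt(np.sum(sv[rank:] ** 2)))


def _canonical_splits(quartet: tuple[str, ...]) -> list[Split]:
    a, b, c, d = sorted(quartet)
    return [((a, b), (c, d)), ((a, c), (b, d)), ((a, d), (b, c))]


def _score_block(S: np.ndarray, quartet_idx: np.ndarray, weights: np.ndarray | None,
                 rank: int) -> np.ndarray:
    """Scores (n_quartets, 3) for all quartets given profile array S.

    ``quartet_idx`` is (n_quartets, 4) of lineage indices, each row sorted.
    """
    n_lin, n_sites, k = S.shape
    kk = k * k
    # pair products, reused across quartets
    pair_cache: dict[tuple[int, int], np.ndarray] = {}

    def pair(i: int, j: int) -> np.ndarray:
        key = (i, j)
        if key not in pair_cache:
            pair_cache[key] = (S[i][:, :, None] * S[j][:, None, :]).reshape(n_sites, kk)
        return pair_cache[key]

    w = None if weights is None else np.asarray(weights, dtype=np.float64)
    mats = np.empty((quartet_idx.shape[0], 3, kk, kk))
    for qi, (a, b, c, d) in enumerate(quartet_idx):
        for si, ((l1, l2), (r1, r2)) in enumerate(
            (((a, b), (c, d)), ((a, c), (b, d)), ((a, d), (b, c)))
        ):
            left = pair(l1, l2)
            right = pair(r1, r2)
            if w is not None:
                mats[qi, si] = (left * w[:, None]).T @ right
            else:
                mats[qi, si] = left.T @ right
    norms = np.linalg.norm(mats, axis=(2, 3), keepdims=True)
    if (norms == 0).any():
        raise ValidationError("a quartet produced an all-zero flattening")
    sv = np.linalg.svd(mats / norms, compute_uv=False)  # (nq, 3, kk)
    return np.sqrt((sv[:, :, rank:] ** 2).sum(axis=2))


def score_quartet(gm: GenotypeMatrix, assignment: LineageAssignment,
                  quartet: Sequence[str], **profile_kwargs) -> QuartetScore:
    """Score the three splits of one quartet and pick the minimum."""
    labels, S = lineage_profiles(gm, assignment, **profile_kwargs)
    idx = {lab: i for i, lab in enumerate(labels)}
    if len(set(quartet)) != 4:
        raise ValidationError(f"quartet must contain 4 distinct lineages, got {quartet}")
    q = tuple(sorted(quartet))
    k = S.shape[2]
    rank = k * (k + 1) // 2
    scores = _score_block(S, np.array([[idx[l] for l in q]]), None, rank)[0]
    return _to_quartet_score(q, scores)


def _to_quartet_score(q: tuple[str, ...], scores: np.ndarray) -> QuartetScore:
    splits = _canonical_splits(q)
    best = int(np.argmin(scores))  # ties → lexicographically first split
    ordered = np.sort(scores)
    return QuartetScore(
        q,
        {f"{s[0][0]},{s[0][1]}|{s[1][0]},{s[1][1]}": float(v) for s, v in zip(splits, scores)},
        splits[best],
        float(ordered[1] - ordered[0]),
    )


def score_all_quartets(gm: GenotypeMatrix, assignment: LineageAssignment,
                       **profile_kwargs) -> dict[tuple[str, ...], QuartetScore]:
    """Score every C(n,4) lineage quartet."""
    labels, S = lineage_profiles(gm, assignment, **profile_kwargs)
    k = S.shape[2]
    rank = k * (k + 1) // 2
    quartets = list(itertools.combinations(range(len(labels)), 4))
    scores = _score_block(S, np.array(quartets), None, rank)
    out = {}
    for q_idx, sc in zip(quartets, scores):
        q = tuple(labels[i] for i in q_idx)
        out[q] = _to_quartet_score(q, sc)
    return out


# --------------------------------------------------------------------------- #
# topology bookkeeping (edge lists; leaves 0..n-1, internal nodes >= n)
# --------------------------------------------------------------------------- #


def _leaf_distances(edges: list[tuple[int, int]], n_leaves: int) -> np.ndarray:
    adj: dict[int, list[int]] = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    present = [i for i in range(n_leaves) if i in adj]
    dist = np.zeros((n_leaves, n_leaves), dtype=np.int32)
    for a in present:
        seen = {a: 0}
        queue = deque([a])
        while queue:
            u = queue.popleft()
            for v in adj[u]:
                if v not in seen:
                    seen[v] = seen[u] + 1
                    queue.append(v)
        for b in present:
            dist[a, b] = seen[b]
    return dist


def _quartet_split_row(edges: list[tuple[int, int]], n_leaves: int,
                       quartets: list[tuple[int, ...]]) -> np.ndarray:
    """Induced split index (0: ab|cd, 1: ac|bd, 2: ad|bc) per quartet."""
    D = _leaf_distances(edges, n_leaves)
    row = np.empty(len(quartets), dtype=np.int8)
    for i, (a, b, c, d) in enumerate(quartets):
        sums = (D[a, b] + D[c, d], D[a, c] + D[b, d], D[a, d] + D[b, c])
        row[i] = int(np.argmin(sums))
    return row


def _enumerate_topologies(n_leaves: int) -> list[list[tuple[int, int]]]:
    """All (2n−5)!! unrooted binary topologies, by stepwise leaf insertion."""
    base = [[(0, n_leaves), (1, n_leaves), (2, n_leaves)]]
    next_internal = n_leaves + 1
    for leaf in range(3, n_leaves):
        grown = []
        for edges in base:
            for ei in range(len(edges)):
                u, v = edges[ei]
                m = next_internal
                new = edges[:ei] + edges[ei + 1:] + [(u, m), (v, m), (leaf, m)]
                grown.append(new)
        base = grown
        next_internal += 1
    return base


@functools.lru_cache(maxsize=4)
def _topology_tables(n_leaves: int):
    """(topologies, quartet list, split table (n_topo × n_quartets int8))."""
    topologies = _enumerate_topologies(n_leaves)
    quartets = list(itertools.combinations(range(n_leaves), 4))
    table = np.empty((len(topologies), len(quartets)), dtype=np.int8)
    for ti, edges in enumerate(topologies):
        table[ti] = _quartet_split_row(edges, n_leaves, quartets)
    return topologies, quartets, table


def _chosen_arrays(quartet_scores: Mapping[tuple[str, ...], QuartetScore],
                   labels: list[str]) -> tuple[list[tuple[int, ...]], np.ndarray, np.ndarray]:
    """Chosen split index and margin weight per quartet, lexicographic order."""
    idx = {lab: i for i, lab in enumerate(labels)}
    quartets = list(itertools.combinations(range(len(labels)), 4))
    chosen = np.empty(len(quartets), dtype=np.int8)
    weight = np.empty(len(quartets))
    for qi, q_idx in enumerate(quartets):
        q = tuple(labels[i] for i in q_idx)
        if q not in quartet_scores:
            raise ValidationError(f"missing score for quartet {q}")
        qs = quartet_scores[q]
        chosen[qi] = _canonical_splits(q).index(qs.chosen)
        weight[qi] = qs.margin
    return quartets, chosen, weight


def _star_edges(n_leaves: int) -> list[tuple[int, int]]:
    return [(i, n_leaves) for i in range(n_leaves)]


def _greedy_assemble(labels, quartets, chosen, weight) -> list[tuple[int, int]]:
    """Stepwise addition from the best-resolved quartet, then NNI hill-climb."""
    n = len(labels)
    q_order = {q: i for i, q in enumerate(quartets)}
    seed_qi = int(np.argmax(weight))
    a, b, c, d = quartets[seed_qi]
    # build the chosen split's topology on the seed quartet
    perm = [((a, b), (c, d)), ((a, c), (b, d)), ((a, d), (b, c))][chosen[seed_qi]]
    (l1, l2), (r1, r2) = perm
    m1, m2 = n, n + 1
    edges = [(l1, m1), (l2, m1), (r1, m2), (r2, m2), (m1, m2)]
    present = {a, b, c, d}
    next_internal = n + 2

    def objective(e: list[tuple[int, int]], leaves: set[int]) -> float:
        sub = [q for q in itertools.combinations(sorted(leaves), 4)]
        if not sub:
            return 0.0
        rows = _quartet_split_row(e, n, sub)
        return float(sum(weight[q_order[q]] * (r == chosen[q_order[q]])
                         for q, r in zip(sub, rows)))

    for leaf in [i for i in range(n) if i not in present]:
        best_obj, best_edges = -1.0, None
        for ei in range(len(edges)):
            u, v = edges[ei]
            m = next_internal
            cand = edges[:ei] + edges[ei + 1:] + [(u, m), (v, m), (leaf, m)]
            obj = objective(cand, present | {leaf})
            if obj > best_obj:
                best_obj, best_edges = obj, cand
        edges = best_edges
        present.add(leaf)
        next_internal += 1

    # NNI hill-climbing on the full objective
    full = set(range(n))
    current = objective(edges, full)
    improved = True
    while improved:
        improved = False
        best_obj, best_edges = current, None
        for cand in _nni_neighbours(edges, n):
            obj = objective(cand, full)
            if obj > best_obj + 1e-12:
                best_obj, best_edges = obj, cand
        if best_edges is not None:
            edges, current = best_edges, best_obj
            improved = True
    return edges


def _nni_neighbours(edges: list[tuple[int, int]], n_leaves: int):
    adj: dict[int, list[int]] = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    eset = set(map(frozenset, edges))
    for u, v in edges:
        if u < n_leaves or v < n_leaves:
            continue  # only internal edges admit NNI
        others_u = [x for x in adj[u] if x != v]
        others_v = [x for x in adj[v] if x != u]
        a, b = others_u
        c, d = others_v
        for swap_c in (c, d):
            new = []
            for e in edges:
                fe = frozenset(e)
                if fe == frozenset((b, u)):
                    new.append((swap_c, u))
                elif fe == frozenset((swap_c, v)):
                    new.append((b, v))
                else:
                    new.append(e)
            yield new


def assemble_tree(quartet_scores: Mapping[tuple[str, ...], QuartetScore],
                  lineages: Sequence[str]) -> dendropy.Tree:
    """Amalgamate chosen quartet splits into an unrooted species tree.

    Maximises the margin-weighted count of satisfied quartets: exhaustively
    over all topologies for ≤ 8 lineages, by greedy stepwise addition plus
    NNI hill-climbing above that.  If every quartet is unresolved (all
    margins 0) a star tree is returned with a warning.
    """
    labels = sorted(lineages)
    n = len(labels)
    if n < 4:
        raise ValidationError("need >= 4 lineages")
    quartets, chosen, weight = _chosen_arrays(quartet_scores, labels)
    if not (weight > 0).any():
        logger.warning("all quartets unresolved; returning a star tree")
        return _edges_to_tree(_star_edges(n), labels)
    if n == 4:
        edges = _greedy_seed_only(quartets, chosen, n)
    elif n <= 8:
        topologies, _, table = _topology_tables(n)
        obj = ((table == chosen[None, :]) * weight[None, :]).sum(axis=1)
        edges = topologies[int(np.argmax(obj))]
    else:
        edges = _greedy_assemble(labels, quartets, chosen, weight)
    return _edges_to_tree(edges, labels)


def _greedy_seed_only(quartets, chosen, n):
    a, b, c, d = quartets[0]
    (l1, l2), (r1, r2) = [((a, b), (c, d)), ((a, c), (b, d)), ((a, d), (b, c))][chosen[0]]
    return [(l1, n), (l2, n), (r1, n + 1), (r2, n + 1), (n, n + 1)]


def _edges_to_tree(edges: list[tuple[int, int]], labels: list[str]) -> dendropy.Tree:
    """Edge list → unrooted dendropy tree (seed at the first internal node)."""
    n = len(labels)
    adj: dict[int, list[int]] = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    taxa = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=taxa)
    root_id = min(i for i in adj if i >= n) if any(i >= n for i in adj) else 0
    nodes: dict[int, dendropy.Node] = {root_id: tree.seed_node}
    queue = deque([root_id])
    seen = {root_id}
    while queue:
        u = queue.popleft()
        for v in adj[u]:
            if v in seen:
                continue
            seen.add(v)
            child = nodes[u].new_child()
            if v < n:
                child.taxon = taxa.get_taxon(labels[v])
            nodes[v] = child
            queue.append(v)
    tree.is_rooted = False
    return tree


# --------------------------------------------------------------------------- #
# bootstrap and support handling
# --------------------------------------------------------------------------- #


def _bipartitions(edges: list[tuple[int, int]], labels: list[str]) -> set[frozenset]:
    """Canonical non-trivial bipartitions: the side not containing labels[0]."""
    n = len(labels)
    adj: dict[int, set[int]] = {}
    for u, v in edges:
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)
    out = set()
    for u, v in edges:
        if u < n or v < n:
            continue
        # leaves on v's side when edge (u,v) removed
        side = set()
        queue = deque([v])
        seen = {u, v}
        while queue:
            x = queue.popleft()
            if x < n:
                side.add(x)
            for y in adj[x]:
                if y not in seen:
                    seen.add(y)
                    queue.append(y)
        if 0 in side:
            side = set(range(n)) - side
        if 1 < len(side) < n - 1:
            out.add(frozenset(labels[i] for i in side))
    return out


def _tree_bipartitions(tree: dendropy.Tree) -> set[frozenset]:
    all_labels = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    anchor = sorted(all_labels)[0]
    out = set()
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        clade = {leaf.taxon.label for leaf in node.leaf_iter()}
        side = all_labels - clade if anchor in clade else clade
        if 1 < len(side) < len(all_labels) - 1:
            out.add(frozenset(side))
    return out


def svdq_tree(gm: GenotypeMatrix, assignment: LineageAssignment,
              **profile_kwargs) -> dendropy.Tree:
    """Point-estimate species tree (no bootstrap)."""
    scores = score_all_quartets(gm, assignment, **profile_kwargs)
    return assemble_tree(scores, assignment.lineages)


def bootstrap_species_tree(
    gm: GenotypeMatrix,
    assignment: LineageAssignment,
    n_reps: int = 100,
    seed: int = 0,
    outgroup: str | None = None,
    resample: bool = True,
    **profile_kwargs,
) -> dendropy.Tree:
    """Species tree with site-resampling bootstrap supports (percent).

    Each replicate redraws site weights multinomially (with replacement),
    rescores all quartets and reassembles; support of an internal edge of the
    point-estimate tree is the percentage of replicate trees containing the
    same bipartition.  ``resample=False`` scores every replicate on the
    original sites (so supports are 100 everywhere) — a determinism check.
    """
    if n_reps < 1:
        raise ValidationError("n_reps must be >= 1")
    labels, S = lineage_profiles(gm, assignment, **profile_kwargs)
    k = S.shape[2]
    rank = k * (k + 1) // 2
    quartet_idx = list(itertools.combinations(range(len(labels)), 4))
    qi_arr = np.array(quartet_idx)

    def scores_to_map(block: np.ndarray) -> dict:
        out = {}
        for q_idx, sc in zip(quartet_idx, block):
            q = tuple(labels[i] for i in q_idx)
            out[q] = _to_quartet_score(q, sc)
        return out

    point_scores = scores_to_map(_score_block(S, qi_arr, None, rank))
    point_tree = assemble_tree(point_scores, labels)
    point_bips = _tree_bipartitions(point_tree)

    rng = np.random.default_rng(seed)
    counts: dict[frozenset, int] = {bip: 0 for bip in point_bips}
    n_sites = gm.n_loci
    for _ in range(n_reps):
        if resample:
            w = rng.multinomial(n_sites, np.full(n_sites, 1.0 / n_sites)).astype(float)
        else:
            w = None
        rep_scores = scores_to_map(_score_block(S, qi_arr, w, rank))
        rep_tree = assemble_tree(rep_scores, labels)
        for bip in _tree_bipartitions(rep_tree):
            if bip in counts:
                counts[bip] += 1
    supports = {bip: 100.0 * c / n_reps for bip, c in counts.items()}
    if outgroup is not None:
        point_tree = root_at_outgroup(point_tree, outgroup)
    _attach_supports(point_tree, supports)
    return point_tree


def root_at_outgroup(tree: dendropy.Tree, outgroup: str) -> dendropy.Tree:
    node = None
    for leaf in tree.leaf_node_iter():
        if leaf.taxon and leaf.taxon.label == outgroup:
            node = leaf
    if node is None:
        raise ValidationError(f"outgroup {outgroup!r} is not a tip of the tree")
    tree.to_outgroup_position(node, update_bipartitions=False, suppress_unifurcations=True)
    tree.is_rooted = True
    return tree


def _attach_supports(tree: dendropy.Tree, supports: dict[frozenset, float]) -> None:
    all_labels = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    anchor = sorted(all_labels)[0]
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        clade = {leaf.taxon.label for leaf in node.leaf_iter()}
        side = all_labels - clade if anchor in clade else clade
        key = frozenset(side)
        if key in supports:
            node.label = f"{supports[key]:g}"


def collapse_low_support(tree: dendropy.Tree, threshold: float = 50.0) -> dendropy.Tree:
    """Collapse internal edges whose support label is below ``threshold``.

    Nodes without a numeric label are left alone.  Mirrors the convention of
    collapsing bootstrap values < 50% into polytomies.
    """
    tree = tree.clone(depth=1)
    to_collapse = []
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        try:
            support = float(node.label) if node.label is not None else None
        except ValueError:
            support = None
        if support is not None and support < threshold:
            to_collapse.append(node)
    for node in to_collapse:
        node.edge.collapse()
    return tree
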