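"""SVD-quartets: flattenings, split scores, assembly, bootstrap, collapsing."""

import itertools

import numpy as np
import pytest

from colepop.errors import ValidationError
from colepop.geno_io import MISSING, GenotypeMatrix, read_newick
from colepop.species_tree import (
    LineageAssignment, QuartetScore, assemble_tree, bootstrap_species_tree,
    collapse_low_support, score_all_quartets, score_quartet,
    site_pattern_flattening, svd_score, svdq_tree, _greedy_assemble,
    _chosen_arrays, _edges_to_tree, _tree_bipartitions,
)
from colepop.synthetic_data import SimulationConfig, simulate_dataset

from conftest import random_species_tree


def one_per_lineage(gm):
    return LineageAssignment({a: a for a in gm.accession_ids})


def gm_from_calls(calls, ids=None):
    calls = np.asarray(calls, dtype=np.int8)
    n_acc, n_loci = calls.shape
    ids = ids or [f"L{i}" for i in range(n_acc)]
    return GenotypeMatrix(ids, ["chr1"] * n_loci,
                          np.arange(1, n_loci + 1) * 10, calls)


# --------------------------------------------------------------------------- #
# flattening
# --------------------------------------------------------------------------- #


def test_all_homozygous_reference_mass_in_one_cell():
    gm = gm_from_calls(np.zeros((4, 6)))
    asn = one_per_lineage(gm)
    split = (("L0", "L1"), ("L2", "L3"))
    M = site_pattern_flattening(gm, asn, ["L0", "L1", "L2", "L3"], split)
    assert M.shape == (4, 4)
    assert M[0, 0] == pytest.approx(6.0)  # one contribution per site
    assert np.count_nonzero(M) == 1
    assert np.linalg.matrix_rank(M) == 1


def test_flattening_mass_equals_complete_site_combinations():
    rng = np.random.default_rng(0)
    calls = rng.integers(0, 3, (8, 30)).astype(np.int8)
    calls[rng.random(calls.shape) < 0.2] = MISSING
    gm = gm_from_calls(calls)
    # two accessions per lineage
    asn = LineageAssignment({f"L{i}": f"G{i // 2}" for i in range(8)})
    split = (("G0", "G1"), ("G2", "G3"))
    M = site_pattern_flattening(gm, asn, ["G0", "G1", "G2", "G3"], split)
    valid = calls != MISSING
    expect = 0
    for s in range(30):
        per_lineage = [valid[2 * g: 2 * g + 2, s].sum() for g in range(4)]
        expect += np.prod(per_lineage)
    assert M.sum() == pytest.approx(expect)


def test_hand_two_site_flattening():
    # four single-member lineages, all homozygous => deterministic patterns
    # site1 dosages (0,0,2,2) -> pattern (0,0|1,1); site2 (0,2,0,2) -> (0,1|0,1)
    gm = gm_from_calls([[0, 0], [0, 2], [2, 0], [2, 2]])
    asn = one_per_lineage(gm)
    split = (("L0", "L1"), ("L2", "L3"))
    M = site_pattern_flattening(gm, asn, ["L0", "L1", "L2", "L3"], split)
    expect = np.zeros((4, 4))
    expect[0, 3] += 1  # row (0,0)=0, col (1,1)=3
    expect[1, 1] += 1  # row (0,1)=1, col (0,1)=1
    assert np.array_equal(M, expect)


def test_heterozygotes_spread_probabilistic_weight():
    gm = gm_from_calls([[1], [0], [0], [0]])
    asn = one_per_lineage(gm)
    M = site_pattern_flattening(gm, asn, ["L0", "L1", "L2", "L3"],
                                (("L0", "L1"), ("L2", "L3")))
    assert M[0, 0] == pytest.approx(0.5)  # L0 allele 0 w.p. 1/2
    assert M[2, 0] == pytest.approx(0.5)  # L0 allele 1 w.p. 1/2
    assert M.sum() == pytest.approx(1.0)


def test_nucleotide_encoding_gives_16x16_flattening():
    gm = gm_from_calls(np.zeros((4, 5)))
    asn = one_per_lineage(gm)
    M = site_pattern_flattening(
        gm, asn, ["L0", "L1", "L2", "L3"], (("L0", "L1"), ("L2", "L3")),
        ref_alleles=list("ACGTA"), alt_alleles=list("TGCAC"))
    assert M.shape == (16, 16)
    assert M.sum() == pytest.approx(5.0)


def test_duplicated_lineage_in_quartet_rejected(sim_ds):
    asn = LineageAssignment.from_metadata(sim_ds.meta)
    with pytest.raises(ValidationError):
        score_quartet(sim_ds.genotypes, asn,
                      ["kale", "kale", "broccoli", "cauliflower"])


# --------------------------------------------------------------------------- #
# scoring
# --------------------------------------------------------------------------- #


def test_exact_low_rank_flattening_scores_zero():
    u = np.array([1.0, 2.0, 0.5, 1.5])
    M = np.outer(u, u)  # rank 1 <= 3
    assert svd_score(M) == pytest.approx(0.0, abs=1e-12)
    with pytest.raises(ValidationError):
        svd_score(np.zeros((4, 4)))


def test_identical_sister_pairs_select_their_split():
    rng = np.random.default_rng(3)
    seq_ab = rng.integers(0, 3, 60)
    seq_cd = rng.integers(0, 3, 60)
    gm = gm_from_calls([seq_ab, seq_ab, seq_cd, seq_cd], ["A", "B", "C", "D"])
    qs = score_quartet(gm, one_per_lineage(gm), ["A", "B", "C", "D"])
    assert qs.chosen == (("A", "B"), ("C", "D"))
    others = [v for k, v in qs.scores.items() if k != qs.chosen_string]
    assert all(qs.scores[qs.chosen_string] < v for v in others)
    assert qs.margin > 0


def test_score_invariant_under_site_permutation():
    rng = np.random.default_rng(5)
    calls = rng.integers(0, 3, (4, 40)).astype(np.int8)
    gm1 = gm_from_calls(calls, ["A", "B", "C", "D"])
    perm = rng.permutation(40)
    gm2 = GenotypeMatrix(["A", "B", "C", "D"], ["chr1"] * 40,
                         np.arange(1, 41) * 10, calls[:, perm])
    q = ["A", "B", "C", "D"]
    s1 = score_quartet(gm1, one_per_lineage(gm1), q).scores
    s2 = score_quartet(gm2, one_per_lineage(gm2), q).scores
    for k in s1:
        assert s1[k] == pytest.approx(s2[k], rel=1e-9)


def test_score_symmetric_under_split_side_relabelling():
    rng = np.random.default_rng(6)
    calls = rng.integers(0, 3, (4, 50)).astype(np.int8)
    gm = gm_from_calls(calls, ["A", "B", "C", "D"])
    asn = one_per_lineage(gm)
    q = ["A", "B", "C", "D"]
    m1 = site_pattern_flattening(gm, asn, q, (("A", "B"), ("C", "D")))
    m2 = site_pattern_flattening(gm, asn, q, (("B", "A"), ("D", "C")))
    m3 = site_pattern_flattening(gm, asn, q, (("C", "D"), ("A", "B")))
    assert svd_score(m1) == pytest.approx(svd_score(m2), rel=1e-12)
    assert svd_score(m1) == pytest.approx(svd_score(m3), rel=1e-12)


# --------------------------------------------------------------------------- #
# assembly
# --------------------------------------------------------------------------- #


def sim_lineage_dataset(newick, seed, n_loci=800, members=3):
    cfg = SimulationConfig(species_tree=newick, n_accessions_per_group=max(members, 2),
                           n_loci=n_loci, bottleneck_group=None,
                           hybrid_fraction=0.0, missing_rate=0.0, seed=seed)
    ds = simulate_dataset(cfg)
    return ds, LineageAssignment.from_metadata(ds.meta)


def test_four_lineages_tree_is_the_chosen_split():
    ds, asn = sim_lineage_dataset("((A:0.2,B:0.2):0.4,(C:0.2,D:0.2):0.4);", seed=1)
    scores = score_all_quartets(ds.genotypes, asn)
    tree = assemble_tree(scores, asn.lineages)
    (qs,) = scores.values()
    assert qs.chosen == (("A", "B"), ("C", "D"))
    assert _tree_bipartitions(tree) == _tree_bipartitions(ds.truth_tree)


def test_five_lineage_asymmetric_tree_recovered():
    nwk = "((((A:0.15,B:0.15):0.25,C:0.4):0.25,D:0.65):0.2,E:0.85);"
    ds, asn = sim_lineage_dataset(nwk, seed=2)
    tree = svdq_tree(ds.genotypes, asn)
    assert _tree_bipartitions(tree) == _tree_bipartitions(ds.truth_tree)


def test_exhaustive_and_heuristic_assembly_agree():
    rng = np.random.default_rng(11)
    for seed in range(3):
        labels = [chr(ord("A") + i) for i in range(7)]
        nwk = random_species_tree(labels, rng)
        ds, asn = sim_lineage_dataset(nwk, seed=seed, n_loci=600, members=2)
        scores = score_all_quartets(ds.genotypes, asn)
        exhaustive = assemble_tree(scores, asn.lineages)  # n<=8 path
        quartets, chosen, weight = _chosen_arrays(scores, sorted(asn.lineages))
        heuristic = _edges_to_tree(
            _greedy_assemble(sorted(asn.lineages), quartets, chosen, weight),
            sorted(asn.lineages))
        assert _tree_bipartitions(exhaustive) == _tree_bipartitions(heuristic)


def test_uninformative_data_yields_star_tree():
    gm = gm_from_calls(np.zeros((5, 20)))  # no variation at all: scores tie at 0
    asn = one_per_lineage(gm)
    scores = score_all_quartets(gm, asn)
    tree = assemble_tree(scores, asn.lineages)
    assert len(tree.seed_node.child_nodes()) == 5  # star polytomy
    assert _tree_bipartitions(tree) == set()


# --------------------------------------------------------------------------- #
# bootstrap + collapsing
# --------------------------------------------------------------------------- #


def test_bootstrap_without_resampling_gives_full_support():
    ds, asn = sim_lineage_dataset(
        "((A:0.2,B:0.2):0.4,(C:0.2,D:0.2):0.4,E:0.6);", seed=3, n_loci=400)
    tree = bootstrap_species_tree(ds.genotypes, asn, n_reps=1, seed=0,
                                  resample=False)
    labels = [n.label for n in tree.preorder_node_iter()
              if not n.is_leaf() and n.parent_node is not None]
    assert labels and all(l == "100" for l in labels)


def test_bootstrap_is_deterministic_under_a_seed():
    from colepop.geno_io import tree_to_newick
    ds, asn = sim_lineage_dataset(
        "(((A:0.2,B:0.2):0.3,C:0.5):0.3,(D:0.3,E:0.3):0.5);", seed=4, n_loci=300)
    t1 = bootstrap_species_tree(ds.genotypes, asn, n_reps=10, seed=7, outgroup="E")
    t2 = bootstrap_species_tree(ds.genotypes, asn, n_reps=10, seed=7, outgroup="E")
    assert tree_to_newick(t1) == tree_to_newick(t2)


def test_collapse_threshold_50_removes_exactly_the_weak_edge():
    tree = read_newick("(((A,B)40,(C,D)91)73,(E,F));")
    collapsed = collapse_low_support(tree, 50)
    before = sum(1 for n in tree.preorder_internal_node_iter())
    after = sum(1 for n in collapsed.preorder_internal_node_iter())
    assert before - after == 1
    kept = {n.label for n in collapsed.preorder_node_iter() if n.label}
    assert kept == {"91", "73"}
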