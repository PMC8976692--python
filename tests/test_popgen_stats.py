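"""Distances, windowed π / ROD, Weir–Cockerham F_ST and the band classifier."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st_h

from colepop.errors import ValidationError
from colepop.geno_io import MISSING, GenotypeMatrix
from colepop.popgen_stats import (
    FstBand, classify_fst, group_diversity, pairwise_distance, rod_from_pi,
    rod_percent, site_pi, windowed_fst, windowed_pi, _wc_components,
)
from colepop.synthetic_data import SimulationConfig, simulate_dataset

from conftest import random_gm


def meta_for(gm, groups):
    import pandas as pd
    return pd.DataFrame({
        "accession_id": gm.accession_ids,
        "morphotype": groups,
        "subgroup": "UNKNOWN",
        "source_class": "genebank",
        "region": "UNKNOWN",
    })


# --------------------------------------------------------------------------- #
# pairwise distance
# --------------------------------------------------------------------------- #


def test_distance_hand_matrix_and_normalisation(tiny_gm):
    # pencil-and-paper: per-locus |g1-g2|/2 averaged over 4 loci
    # acc1 vs acc2: (0 + .5 + 0 + 1)/4 = 0.375
    # acc1 vs acc3: (1 + .5 + 1 + .5)/4 = 0.75
    # acc2 vs acc3: (1 + 1 + 1 + .5)/4 = 0.875
    dm = pairwise_distance(tiny_gm)
    assert dm.raw[0, 1] == pytest.approx(0.375)
    assert dm.raw[0, 2] == pytest.approx(0.75)
    assert dm.raw[1, 2] == pytest.approx(0.875)
    # one global affine map: min 0 (diagonal), max 0.875 -> 1
    assert dm.normalized.min() == 0.0 and dm.normalized.max() == 1.0
    assert dm.normalized[0, 1] == pytest.approx(0.375 / 0.875)
    assert np.allclose(dm.raw, dm.raw.T) and np.all(np.diag(dm.raw) == 0)
    assert dm.n_shared_loci[0, 1] == 4


def test_identical_and_maximally_different_accessions():
    calls = np.array([[0, 0, 0], [0, 0, 0], [2, 2, 2]], dtype=np.int8)
    gm = GenotypeMatrix(["a", "b", "c"], ["chr1"] * 3, [1, 2, 3], calls)
    dm = pairwise_distance(gm)
    assert dm.raw[0, 1] == 0.0 and dm.normalized[0, 1] == 0.0
    assert dm.raw[0, 2] == 1.0 and dm.normalized[0, 2] == 1.0


def test_distance_requires_shared_loci():
    calls = np.array([[0, MISSING], [MISSING, 2]], dtype=np.int8)
    gm = GenotypeMatrix(["a", "b"], ["chr1", "chr1"], [1, 2], calls)
    with pytest.raises(ValidationError, match="share no non-missing"):
        pairwise_distance(gm)


@pytest.mark.parametrize("seed", range(4))
def test_raw_distance_satisfies_triangle_inequality(seed):
    gm = random_gm(np.random.default_rng(seed), n_acc=7, n_loci=25)
    d = pairwise_distance(gm).raw
    n = len(gm.accession_ids)
    for i, j, k in itertools.permutations(range(n), 3):
        assert d[i, k] <= d[i, j] + d[j, k] + 1e-12


# --------------------------------------------------------------------------- #
# windowed π
# --------------------------------------------------------------------------- #


def test_site_pi_formula_and_window_scaling():
    # one segregating site, c0 = c1 = 5 chromosomes (5 diploids):
    # site π = 25 / C(10,2) = 25/45
    calls = np.array([[0], [0], [1], [2], [2]], dtype=np.int8)
    gm = GenotypeMatrix(list("abcde"), ["chr1"], [500], calls)
    assert site_pi(gm)[0] == pytest.approx(25 / 45)
    stats = windowed_pi(gm, window_bp=10_000, step_bp=10_000)
    assert stats[0].value == pytest.approx(25 / 45 / 10_000)
    assert stats[0].n_sites == 1


def test_monomorphic_windows_have_zero_pi():
    calls = np.zeros((3, 5), dtype=np.int8)
    gm = GenotypeMatrix(["a", "b", "c"], ["chr1"] * 5, [10, 20, 30, 40, 50], calls)
    assert all(w.value == 0.0 for w in windowed_pi(gm, window_bp=100, step_bp=50))


def test_pi_invariant_to_allele_swap_and_accession_order(sim_ds):
    gm = sim_ds.genotypes
    swapped = GenotypeMatrix(
        gm.accession_ids,
        gm.chrom.copy(), gm.pos.copy(),
        np.where(gm.calls == MISSING, MISSING, 2 - gm.calls),
    )
    a = [w.value for w in windowed_pi(gm, window_bp=50_000, step_bp=50_000)]
    b = [w.value for w in windowed_pi(swapped, window_bp=50_000, step_bp=50_000)]
    assert a == pytest.approx(b, abs=1e-15)
    order = list(reversed(gm.accession_ids))
    c = [w.value for w in windowed_pi(gm.subset(order), window_bp=50_000, step_bp=50_000)]
    assert a == pytest.approx(c, abs=1e-15)


def brute_force_windowed_pi(gm, window_bp, step_bp):
    """Independent oracle: recount every window from scratch."""
    pi = site_pi(gm)
    out = []
    for chrom in dict.fromkeys(gm.chrom.astype(str)):
        on = gm.chrom.astype(str) == chrom
        pos, vals = gm.pos[on], pi[on]
        start = 1
        while start <= pos.max():
            end = start + window_bp - 1
            inside = (pos >= start) & (pos <= end)
            out.append(float(vals[inside].sum() / window_bp))
            start += step_bp
    return out


def test_windowed_pi_matches_brute_force_recount(sim_ds):
    gm = sim_ds.genotypes
    stats = windowed_pi(gm, window_bp=100_000, step_bp=10_000)
    oracle = brute_force_windowed_pi(gm, 100_000, 10_000)
    assert len(stats) == len(oracle)
    for w, expect in zip(stats, oracle):
        assert abs(w.value - expect) < 1e-12


def test_window_bp_must_be_positive(tiny_gm):
    with pytest.raises(ValidationError):
        windowed_pi(tiny_gm, window_bp=0)


# --------------------------------------------------------------------------- #
# ROD
# --------------------------------------------------------------------------- #


def test_rod_worked_example_rounds_to_46_percent():
    rod = rod_from_pi(7.13e-6, 1.32e-5)
    assert rod == pytest.approx(0.45984848, rel=1e-6)
    assert rod_percent(rod) == 46


def test_rod_ratio_cases():
    assert rod_from_pi(5e-6, 1e-5) == pytest.approx(0.5)
    assert rod_from_pi(1e-5, 1e-5) == 0.0
    with pytest.raises(ValidationError):
        rod_from_pi(1e-5, 0.0)


def test_group_diversity_rod_zero_for_control(sim_ds):
    divs = group_diversity(sim_ds.genotypes, sim_ds.meta,
                           control_group="wild_oleracea",
                           window_bp=100_000, step_bp=100_000)
    by_group = {d.group: d for d in divs}
    assert by_group["wild_oleracea"].rod_vs_control == 0.0
    assert all(d.mean_pi >= 0 for d in divs)


# --------------------------------------------------------------------------- #
# Weir-Cockerham F_ST
# --------------------------------------------------------------------------- #


def wc84_single_site(genos_a, genos_b):
    """Formula-transcription oracle: WC84 two-population components a, b, c
    for one biallelic site, written scalar-by-scalar (independent of the
    vectorized path)."""
    r = 2
    stats = []
    for genos in (genos_a, genos_b):
        obs = [g for g in genos if g != MISSING]
        n_i = len(obs)
        p_i = sum(obs) / (2 * n_i)
        h_i = sum(1 for g in obs if g == 1) / n_i
        stats.append((n_i, p_i, h_i))
    (n1, p1, h1), (n2, p2, h2) = stats
    n_bar = (n1 + n2) / r
    n_c = (r * n_bar - (n1 ** 2 + n2 ** 2) / (r * n_bar)) / (r - 1)
    p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
    s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1) * n_bar)
    h_bar = (n1 * h1 + n2 * h2) / (r * n_bar)
    a = (n_bar / n_c) * (
        s2 - (p_bar * (1 - p_bar) - s2 * (r - 1) / r - h_bar / 4) / (n_bar - 1)
    )
    b = (n_bar / (n_bar - 1)) * (
        p_bar * (1 - p_bar) - s2 * (r - 1) / r - h_bar * (2 * n_bar - 1) / (4 * n_bar)
    )
    c = h_bar / 2
    return a, b, c


def test_wc_components_match_scalar_transcription():
    # n = 4 + 4 diploids with fixed genotype configurations
    ga = np.array([[0], [1], [1], [2]], dtype=np.int8)
    gb = np.array([[2], [2], [1], [2]], dtype=np.int8)
    a, b, c, usable = _wc_components(ga, gb)
    ea, eb, ec = wc84_single_site([0, 1, 1, 2], [2, 2, 1, 2])
    assert usable[0]
    assert a[0] == pytest.approx(ea, rel=1e-12)
    assert b[0] == pytest.approx(eb, rel=1e-12)
    assert c[0] == pytest.approx(ec, rel=1e-12)


def test_wc_components_with_missing_calls_match_oracle():
    ga = np.array([[0], [MISSING], [1], [2]], dtype=np.int8)
    gb = np.array([[2], [2], [MISSING], [0]], dtype=np.int8)
    a, b, c, _ = _wc_components(ga, gb)
    ea, eb, ec = wc84_single_site([0, 1, 2], [2, 2, 0])
    assert (a[0], b[0], c[0]) == pytest.approx((ea, eb, ec), rel=1e-12)


def test_fst_is_one_for_fixed_opposite_alleles():
    calls = np.array([[0] * 10] * 4 + [[2] * 10] * 4, dtype=np.int8)
    gm = GenotypeMatrix([f"s{i}" for i in range(8)], ["chr1"] * 10,
                        list(range(10, 110, 10)), calls)
    meta = meta_for(gm, ["A"] * 4 + ["B"] * 4)
    _, gw = windowed_fst(gm, meta, "A", "B")
    assert gw == pytest.approx(1.0)


def test_fst_near_zero_under_the_null():
    rng = np.random.default_rng(42)
    vals = []
    for _ in range(3):
        p = rng.uniform(0.05, 0.95, 2000)
        calls = rng.binomial(2, p, size=(20, 2000)).astype(np.int8)
        gm = GenotypeMatrix([f"s{i}" for i in range(20)],
                            ["chr1"] * 2000, np.arange(1, 2001) * 10, calls)
        meta = meta_for(gm, ["A"] * 10 + ["B"] * 10)
        _, gw = windowed_fst(gm, meta, "A", "B")
        vals.append(gw)
    assert all(abs(v) < 0.02 for v in vals)


def test_fst_parameter_recovery_under_balding_nichols():
    """Genome-wide WC F_ST recovers F = 1 − exp(−t) within 20% (spot check)."""
    t = 0.2
    expect = 1 - np.exp(-t)
    est = []
    for seed in range(3):
        rng = np.random.default_rng(100 + seed)
        F = expect
        lam = (1 - F) / F
        p0 = rng.uniform(0.05, 0.95, 2000)
        pa = rng.beta(lam * p0, lam * (1 - p0))
        pb = rng.beta(lam * p0, lam * (1 - p0))
        calls = np.concatenate([
            rng.binomial(2, pa, size=(20, 2000)),
            rng.binomial(2, pb, size=(20, 2000)),
        ]).astype(np.int8)
        gm = GenotypeMatrix([f"s{i}" for i in range(40)],
                            ["chr1"] * 2000, np.arange(1, 2001) * 10, calls)
        meta = meta_for(gm, ["A"] * 20 + ["B"] * 20)
        _, gw = windowed_fst(gm, meta, "A", "B")
        est.append(gw)
    assert np.mean(est) == pytest.approx(expect, rel=0.2)


def test_fst_requires_two_members_per_group(tiny_gm):
    meta = meta_for(tiny_gm, ["A", "A", "B"])
    with pytest.raises(ValidationError, match="fewer than 2"):
        windowed_fst(tiny_gm, meta, "A", "B")


# --------------------------------------------------------------------------- #
# band classifier
# --------------------------------------------------------------------------- #


@pytest.mark.parametrize("value,band", [
    (0.04, FstBand.little),       # summer/autumn vs winter broccoli
    (0.21, FstBand.strong),       # cauliflower vs heading cabbage
    (0.34, FstBand.very_strong),  # cauliflower vs wild C9
    (0.15, FstBand.strong),       # boundary: 0.15 belongs to "strong"
    (0.05, FstBand.moderate),
    (0.25, FstBand.very_strong),
    (-0.01, FstBand.little),      # negative estimates treated as little
])
def test_fst_band_thresholds(value, band):
    assert classify_fst(value) is band


@settings(deadline=None, derandomize=True, max_examples=200)
@given(st_h.floats(min_value=0.0, max_value=1.0, allow_nan=False))
def test_fst_bands_partition_unit_interval(value):
    band = classify_fst(value)
    assert band in FstBand
    # exhaustive, non-overlapping thresholds
    expected = (FstBand.little if value < 0.05 else FstBand.moderate
                if value < 0.15 else FstBand.strong if value < 0.25
                else FstBand.very_strong)
    assert band is expected


def test_classify_rejects_nan():
    with pytest.raises(ValidationError):
        classify_fst(float("nan"))
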