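"""End-to-end pipeline: simulate/load → distances → diversity → F_ST → PCA
→ SVD-quartets species tree → character tracing → dating.

One YAML/JSON config drives every stage; a JSON manifest records outputs,
parameters, the seed and per-stage wall time.  All stage randomness derives
from a single global seed through a fixed fan-out, so a rerun with the same
config is bit-identical on every TSV/Newick output.
"""

from __future__ import annotations

import itertools
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import chronology, geno_io, popgen_stats, species_tree, structure_support, synthetic_data, trait_evolution
from .errors import ColepopError, ValidationError

logger = logging.getLogger(__name__)

STAGES = ["simulate", "distances", "diversity", "fst", "pca", "svdq", "trace", "date"]


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage child seed from the global seed (< 2**31)."""
    return int(np.random.SeedSequence([seed, STAGES.index(stage)]).generate_state(1)[0] % (2**31))


def demo_config(outdir: str = "colepop_demo", seed: int = 1) -> dict:
    """The default desk-scale demo: 8 simulated groups × 12 accessions × 2000 loci."""
    return {
        "seed": seed,
        "outdir": outdir,
        "window_bp": 100_000,
        "step_bp": 10_000,
        "simulate": {},  # all synthetic_data defaults
        "stages": {s: True for s in STAGES},
        "diversity": {"control_group": "wild_oleracea"},
        "fst": {"pairs": "all"},
        "svdq": {"bootstrap": 100, "outgroup": "wild_C9", "collapse": 50},
        "trace": {"states": ["winter", "summer_autumn", "tropical"], "rate": 1.0},
        "date": {"calibrations": [{"clade": ["cauliflower", "broccoli"], "age": 2500}],
                 "present_year": chronology.DEFAULT_PRESENT_YEAR},
    }


def load_config(path: str | Path) -> dict:
    try:
        text = Path(path).read_text()
    except OSError as exc:
        raise ColepopError(f"cannot read config {path}: {exc}") from exc
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ValidationError(f"config {path} is not a mapping")
    return cfg


def validate_config(cfg: dict | str | Path) -> list[str]:
    """Human-readable list of config violations; empty list = valid."""
    if not isinstance(cfg, dict):
        cfg = load_config(cfg)
    errors: list[str] = []
    if not isinstance(cfg.get("seed", 0), int):
        errors.append("seed must be an integer")
    stages = cfg.get("stages", {})
    unknown = set(stages) - set(STAGES)
    if unknown:
        errors.append(f"unknown stages: {sorted(unknown)}")
    enabled = {s for s in STAGES if stages.get(s, False)}
    for key in ("window_bp", "step_bp"):
        v = cfg.get(key, 1)
        if not isinstance(v, int) or v <= 0:
            errors.append(f"{key} must be a positive integer")
    has_genotypes = "simulate" in cfg or "inputs" in cfg
    if enabled - {"trace", "date"} and not has_genotypes:
        errors.append("genotype stages enabled but neither 'simulate' nor 'inputs' given")
    if "inputs" in cfg:
        for key in ("genotypes", "metadata"):
            p = cfg["inputs"].get(key)
            if not p:
                errors.append(f"inputs.{key} is required")
            elif not Path(p).exists():
                errors.append(f"inputs.{key} file {p!r} does not exist")
    if "simulate" in cfg:
        try:
            _sim_config(cfg)
        except (ColepopError, KeyError, TypeError, ValueError) as exc:
            errors.append(f"simulate block invalid: {exc}")
    if "date" in enabled:
        if "simulate" not in cfg and not cfg.get("date", {}).get("tree"):
            errors.append("date stage needs date.tree when not simulating (no truth tree)")
        if not cfg.get("date", {}).get("calibrations"):
            errors.append("date stage needs at least one calibration")
    if "trace" in enabled and "simulate" not in cfg and not cfg.get("trace", {}).get("tree"):
        errors.append("trace stage needs trace.tree when not simulating")
    if "svdq" in enabled:
        lm = cfg.get("svdq", {}).get("lineage_map")
        if lm and not Path(lm).exists():
            errors.append(f"svdq.lineage_map file {lm!r} does not exist")
    return errors


def _sim_config(cfg: dict) -> synthetic_data.SimulationConfig:
    block = dict(cfg.get("simulate") or {})
    block.setdefault("seed", stage_seed(cfg.get("seed", 0), "simulate"))
    if "chromosome_layout" in block:
        block["chromosome_layout"] = [tuple(x) for x in block["chromosome_layout"]]
    sim = synthetic_data.SimulationConfig(**block)
    sim.validate()
    return sim


def run_pipeline(cfg: dict | str | Path, outdir: str | Path | None = None) -> dict:
    """Run every enabled stage; returns (and writes) the output manifest."""
    if not isinstance(cfg, dict):
        cfg = load_config(cfg)
    problems = validate_config(cfg)
    if problems:
        raise ValidationError("invalid pipeline config: " + "; ".join(problems))
    out = Path(outdir if outdir is not None else cfg.get("outdir", "colepop_out"))
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    window_bp = int(cfg.get("window_bp", popgen_stats.DEFAULT_WINDOW_BP))
    step_bp = int(cfg.get("step_bp", popgen_stats.DEFAULT_STEP_BP))
    stages = {s: bool(cfg.get("stages", {}).get(s, False)) for s in STAGES}
    manifest: dict = {"seed": seed, "outdir": str(out), "stages": {}}

    gm = meta = truth_tree = None

    def record(stage: str, t0: float, files: dict, **params) -> None:
        manifest["stages"][stage] = {
            "outputs": {k: str(v) for k, v in files.items()},
            "params": params,
            "seed": stage_seed(seed, stage),
            "wall_time_s": round(time.perf_counter() - t0, 3),
        }

    # ---- acquire genotypes -------------------------------------------------
    if stages["simulate"] or ("simulate" in cfg and any(stages.values())):
        t0 = time.perf_counter()
        sim = _sim_config(cfg)
        ds = synthetic_data.simulate_dataset(sim)
        gm, meta, truth_tree = ds.genotypes, ds.meta, ds.truth_tree
        files = {
            "genotypes_tsv": out / "genotypes.tsv",
            "genotypes_vcf": out / "genotypes.vcf",
            "metadata": out / "metadata.tsv",
            "truth_tree": out / "truth_tree.nwk",
            "truth_freqs": out / "truth_freqs.tsv",
        }
        geno_io.write_genotype_tsv(gm, files["genotypes_tsv"])
        geno_io.write_vcf(gm, files["genotypes_vcf"])
        geno_io.write_metadata(meta, files["metadata"])
        geno_io.write_newick(truth_tree, files["truth_tree"])
        ds.truth_group_freqs.to_csv(files["truth_freqs"], sep="\t", float_format="%.10g")
        record("simulate", t0, files, n_loci=gm.n_loci, n_accessions=gm.n_accessions)
    elif "inputs" in cfg:
        gpath = cfg["inputs"]["genotypes"]
        gm = (geno_io.read_vcf(gpath) if str(gpath).endswith(".vcf")
              else geno_io.read_genotype_tsv(gpath))
        meta = geno_io.read_metadata(cfg["inputs"]["metadata"])
        geno_io.check_paired(gm, meta)

    # ---- distances ---------------------------------------------------------
    if stages["distances"]:
        t0 = time.perf_counter()
        dm = popgen_stats.pairwise_distance(gm)
        files = {"normalized": out / "distances_normalized.tsv",
                 "raw": out / "distances_raw.tsv"}
        dm.to_frame(normalized=True).to_csv(files["normalized"], sep="\t",
                                            float_format="%.10g")
        dm.to_frame(normalized=False).to_csv(files["raw"], sep="\t", float_format="%.10g")
        record("distances", t0, files, n_accessions=gm.n_accessions)

    # ---- diversity / ROD ---------------------------------------------------
    if stages["diversity"]:
        t0 = time.perf_counter()
        div_cfg = cfg.get("diversity", {})
        groups = list(dict.fromkeys(meta["morphotype"]))
        control = div_cfg.get("control_group") or groups[0]
        divs = popgen_stats.group_diversity(gm, meta, "morphotype", control,
                                            window_bp, step_bp)
        files = {"summary": out / "diversity.json"}
        payload = [
            {"group": d.group, "mean_pi": d.mean_pi, "n_windows": d.n_windows,
             "rod_vs_control": d.rod_vs_control,
             "rod_percent": (popgen_stats.rod_percent(d.rod_vs_control)
                             if d.rod_vs_control is not None else None)}
            for d in divs
        ]
        files["summary"].write_text(json.dumps(
            {"control_group": control, "groups": payload}, indent=2))
        record("diversity", t0, files, control_group=control,
               window_bp=window_bp, step_bp=step_bp)

    # ---- F_ST --------------------------------------------------------------
    if stages["fst"]:
        t0 = time.perf_counter()
        fst_cfg = cfg.get("fst", {})
        groups = list(dict.fromkeys(meta["morphotype"]))
        pairs = fst_cfg.get("pairs", "all")
        if pairs == "all":
            pairs = list(itertools.combinations(groups, 2))
        fst_dir = out / "fst"
        fst_dir.mkdir(exist_ok=True)
        summary = []
        files = {"summary": out / "fst.json"}
        for a, b in pairs:
            wins, gw = popgen_stats.windowed_fst(gm, meta, a, b, "morphotype",
                                                 window_bp, step_bp)
            path = fst_dir / f"fst_{a}_vs_{b}.tsv"
            geno_io.write_window_stats(wins, path)
            summary.append({"A": a, "B": b, "fst": gw,
                            "band": popgen_stats.classify_fst(gw).value})
            files[f"{a}_vs_{b}"] = path
        files["summary"].write_text(json.dumps({"fst_pairs": summary}, indent=2))
        record("fst", t0, files, n_pairs=len(pairs))

    # ---- PCA ---------------------------------------------------------------
    if stages["pca"]:
        t0 = time.perf_counter()
        res = structure_support.pca(gm, n_components=int(cfg.get("pca", {}).get("n_components", 10)))
        files = {"scores": out / "pca_scores.tsv", "eigs": out / "pca_eigenvalues.tsv"}
        res.to_frame().to_csv(files["scores"], sep="\t", float_format="%.10g")
        pd.DataFrame({"eigenvalue": res.eigenvalues,
                      "variance_explained": res.variance_explained}
                     ).to_csv(files["eigs"], sep="\t", index=False, float_format="%.10g")
        record("pca", t0, files, n_components=res.scores.shape[1])

    # ---- SVD-quartets species tree ----------------------------------------
    svdq_tree_path = None
    if stages["svdq"]:
        t0 = time.perf_counter()
        svdq_cfg = cfg.get("svdq", {})
        if svdq_cfg.get("lineage_map"):
            lm = pd.read_csv(svdq_cfg["lineage_map"], sep="\t")
            assignment = species_tree.LineageAssignment(
                dict(zip(lm.iloc[:, 0], lm.iloc[:, 1])))
        else:
            assignment = species_tree.LineageAssignment.from_metadata(meta)
        outgroup = svdq_cfg.get("outgroup")
        if outgroup is not None and outgroup not in assignment.lineages:
            outgroup = None
        tree = species_tree.bootstrap_species_tree(
            gm, assignment,
            n_reps=int(svdq_cfg.get("bootstrap", 100)),
            seed=stage_seed(seed, "svdq"),
            outgroup=outgroup,
        )
        collapsed = species_tree.collapse_low_support(
            tree, float(svdq_cfg.get("collapse", 50)))
        scores = species_tree.score_all_quartets(gm, assignment)
        files = {"tree": out / "species_tree.nwk",
                 "collapsed": out / "species_tree_collapsed.nwk",
                 "quartets": out / "quartet_scores.tsv"}
        geno_io.write_newick(tree, files["tree"])
        geno_io.write_newick(collapsed, files["collapsed"])
        pd.DataFrame(
            [{"quartet": ",".join(q), "chosen": qs.chosen_string, "margin": qs.margin,
              **qs.scores} for q, qs in sorted(scores.items())]
        ).to_csv(files["quartets"], sep="\t", index=False, float_format="%.10g")
        svdq_tree_path = files["tree"]
        record("svdq", t0, files, bootstrap=int(svdq_cfg.get("bootstrap", 100)),
               outgroup=outgroup)

    # ---- character tracing -------------------------------------------------
    if stages["trace"]:
        t0 = time.perf_counter()
        trace_cfg = cfg.get("trace", {})
        if trace_cfg.get("tree"):
            tr = geno_io.read_newick(trace_cfg["tree"])
        else:
            tr = truth_tree
        if trace_cfg.get("characters"):
            cdf = pd.read_csv(trace_cfg["characters"], sep="\t")
            states = dict(zip(cdf.iloc[:, 0], cdf.iloc[:, 1]))
            alphabet = trace_cfg.get("states") or sorted(
                {s for s in states.values() if s != geno_io.UNKNOWN})
        else:
            alphabet = list(trace_cfg.get("states", ["a", "b"]))
            sim_char = synthetic_data.simulate_character(
                tr, alphabet, float(trace_cfg.get("rate", 1.0)),
                stage_seed(seed, "trace"))
            states = sim_char.tip_states
        chars = trait_evolution.CharacterData(states, list(alphabet))
        rec, transitions = trait_evolution.trace_history(tr, chars)
        files = {"nodes": out / "trace_nodes.tsv", "transitions": out / "trace_transitions.tsv"}
        rows = []
        for i, node in enumerate(rec.tree.preorder_node_iter()):
            name = node.taxon.label if node.is_leaf() and node.taxon else f"node{i}"
            rows.append({"node": name, "mpr_set": "|".join(sorted(rec.node_sets[node])),
                         "assigned": rec.assignment[node]})
        pd.DataFrame(rows).to_csv(files["nodes"], sep="\t", index=False)
        pd.DataFrame([t.__dict__ for t in transitions]).to_csv(
            files["transitions"], sep="\t", index=False)
        record("trace", t0, files, n_changes=rec.min_changes,
               n_transitions=len(transitions))

    # ---- dating ------------------------------------------------------------
    if stages["date"]:
        t0 = time.perf_counter()
        date_cfg = cfg.get("date", {})
        tr = geno_io.read_newick(date_cfg["tree"]) if date_cfg.get("tree") else truth_tree
        chron = chronology.ultrametricize(tr)
        chron.present_year = int(date_cfg.get("present_year",
                                              chronology.DEFAULT_PRESENT_YEAR))
        cal = chronology.Calibration(
            [(frozenset(c["clade"]), float(c["age"])) for c in date_cfg["calibrations"]])
        rate = chronology.calibrate_rate(chron, cal)
        ages = chronology.node_ages(chron, rate)
        files = {"ages": out / "node_ages.tsv", "chronogram": out / "chronogram.nwk"}
        rows = []
        for i, node in enumerate(chron.tree.preorder_node_iter()):
            name = node.taxon.label if node.is_leaf() and node.taxon else f"node{i}"
            age = ages[node]
            cal_year = chronology.to_calendar(age, chron.present_year)
            rows.append({"node": name, "height": chron.heights[node],
                         "age_yr": round(age), "calendar": chronology.format_calendar(cal_year)})
        pd.DataFrame(rows).to_csv(files["ages"], sep="\t", index=False,
                                  float_format="%.10g")
        geno_io.write_newick(chron.tree, files["chronogram"])
        record("date", t0, files, rate=rate, present_year=chron.present_year)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
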