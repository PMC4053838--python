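"""End-to-end pipeline driver: simulate → dimorphism → discover → scaffold →
gametologue.

Each stage is an ordinary function over files so it can be run standalone;
:func:`run_pipeline` chains them and writes a manifest (inputs, derived
seeds, parameters, output checksums) into the run directory.  A single
global seed is decorrelated per stage by hashing the stage name, so a stage
re-run in isolation reproduces its in-pipeline output.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as wio
from .core import W_CLASSES
from .dimorphism import (
    classify_tallies,
    compute_fpkm,
    estimate_dispersions,
    normalize_library_sizes,
    test_ratio_difference,
    test_sex_within_tissue,
    test_tissue_average,
    z_dosage_ratio,
)
from .discovery import (
    female_specific_screen,
    load_default_panel,
    pseudogene_filter,
    retroviral_filter,
)
from .gametologue import combined_expression_compare, compare_pair
from .scaffold import assemble_w_transcript
from .synthetic import (
    SimConfig,
    build_candidate_pool,
    fragmentize,
    random_cds,
    simulate_counts,
    simulate_gametologue_pair,
)

log = logging.getLogger("wseq")

STAGES = ("simulate", "dimorphism", "discover", "scaffold", "gametologue")

DEFAULT_CONFIG: dict = {
    "simulate": True,
    "seed": 42,
    "fdr": 0.05,
    "sim": {},
    "sequences": {
        "n_pairs": 6,
        "n_codons": 400,
        "omega": 0.2,
        "subs_per_codon": 0.3,
        "min_fragments": 5,
        "max_fragments": 9,
        "orphan_prob": 0.0,
        "n_decoys": 8,
    },
    "inputs": {},  # counts/design/annotation paths when simulate is false
}


def stage_seed(seed: int, stage: str) -> int:
    """Per-stage seed derived from the global one (stable, < 2^31)."""
    return (seed * 1000003 + zlib.crc32(stage.encode())) % (2**31)


def load_config(path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    for key, value in user.items():
        if isinstance(value, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(value)
        else:
            cfg[key] = value
    return cfg


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def run_simulate(cfg: dict, out: Path, seed: int) -> dict:
    sim_cfg = SimConfig.from_dict({**cfg.get("sim", {}), "seed": seed})
    experiment, truth = simulate_counts(sim_cfg)
    paths = wio.write_experiment(experiment, out)
    truth_path = out / "truth.tsv"
    truth.genes.to_csv(truth_path, sep="\t")
    paths["truth"] = str(truth_path)

    seq_cfg = cfg["sequences"]
    rng = np.random.default_rng(stage_seed(seed, "sequences"))
    ann = experiment.annotation
    w_ids = list(ann.index[ann["chrom_class"].isin(W_CLASSES)])
    z_ids = list(ann.index[ann["chrom_class"] == "Z"])
    n_pairs = min(seq_cfg["n_pairs"], len(w_ids), len(z_ids))
    pairs, z_recs, w_recs, frag_records = [], [], [], []
    for i in range(n_pairs):
        pid = f"pair_{i:02d}"
        z_cds = random_cds(seq_cfg["n_codons"], rng)
        w_cds, _ = simulate_gametologue_pair(
            z_cds, seq_cfg["omega"], seq_cfg["subs_per_codon"], rng
        )
        n_frag = int(rng.integers(seq_cfg["min_fragments"],
                                  seq_cfg["max_fragments"] + 1))
        frags, _ = fragmentize(
            w_cds, n_frag, orphan_prob=seq_cfg["orphan_prob"], seed=rng,
            id_prefix=pid,
        )
        frag_records.extend(frags)
        z_recs.append((pid + "_Z", z_cds))
        w_recs.append((pid + "_W", w_cds))
        pairs.append({"pair_id": pid, "w_gene": w_ids[i], "z_gene": z_ids[i]})
    wio.write_fasta(out / "z_gametologues.fasta", z_recs)
    wio.write_fasta(out / "w_truth.fasta", w_recs)
    wio.write_fragments(out / "fragments.fasta", frag_records)
    pd.DataFrame(pairs).to_csv(out / "pairs.tsv", sep="\t", index=False)

    panel = load_default_panel()
    candidates, fpkm, cand_truth = build_candidate_pool(
        experiment, truth, panel,
        seed=np.random.default_rng(stage_seed(seed, "candidates")),
        n_decoys=seq_cfg["n_decoys"],
    )
    wio.write_fragments(out / "candidates.fasta", candidates)
    fpkm.to_csv(out / "candidate_fpkm.tsv", sep="\t")
    cand_truth.to_csv(out / "candidate_truth.tsv", sep="\t")
    paths.update(
        {k: str(out / v) for k, v in {
            "z_gametologues": "z_gametologues.fasta",
            "w_truth": "w_truth.fasta",
            "fragments": "fragments.fasta",
            "pairs": "pairs.tsv",
            "candidates": "candidates.fasta",
            "candidate_fpkm": "candidate_fpkm.tsv",
        }.items()}
    )
    return paths


def run_dimorphism(counts, design, annotation, out: Path, fdr: float = 0.05) -> dict:
    experiment = wio.read_experiment(counts, design, annotation)
    eff = normalize_library_sizes(experiment)
    disp = estimate_dispersions(experiment)
    results = {
        "sex_blastoderm": test_sex_within_tissue(experiment, disp, "blastoderm"),
        "sex_gonad": test_sex_within_tissue(experiment, disp, "gonad"),
        "ratio_difference": test_ratio_difference(experiment, disp),
        "tissue_average": test_tissue_average(experiment, disp),
    }
    out.mkdir(parents=True, exist_ok=True)
    wio.write_results(results, out / "results.tsv")
    tally = classify_tallies(results, experiment.annotation, fdr=fdr)
    fpkm = compute_fpkm(experiment.counts, experiment.annotation["length"], eff)
    fpkm.to_csv(out / "fpkm.tsv", sep="\t")
    dosage = z_dosage_ratio(fpkm, experiment.design, experiment.annotation)
    summary = {
        "common_dispersion": disp.common_dispersion,
        "n_significant": {k: int(len(v.significant(fdr))) for k, v in results.items()},
        "sex_counts": {
            f"{t}|{d}": row.to_dict()
            for (t, d), row in tally.sex_counts.iterrows()
        },
        "z_dosage_ratio": dosage.to_dict(),
    }
    (out / "tallies.json").write_text(json.dumps(summary, indent=2))
    return {"results": str(out / "results.tsv"),
            "tallies": str(out / "tallies.json"),
            "fpkm": str(out / "fpkm.tsv")}


def run_discover(candidates, fpkm, design, out: Path, panel=None,
                 gametologue_proteins=None) -> dict:
    cands = wio.read_fragments(candidates)
    fpkm_df = pd.read_csv(fpkm, sep="\t", index_col=0)
    design_df = pd.read_csv(design, sep="\t", index_col="sample")
    panel = panel if panel is not None else load_default_panel()
    screen = female_specific_screen(cands, fpkm_df, design_df)
    flagged = [c for c in cands if bool(screen.loc[c.id, "female_specific"])]
    retained, removed, report = retroviral_filter(flagged, panel)
    out.mkdir(parents=True, exist_ok=True)
    paths = {"screen": str(out / "screen.tsv"),
             "filter": str(out / "retroviral_filter.tsv"),
             "retained": str(out / "retained.fasta")}
    if gametologue_proteins:
        retained, pseudo_removed, pseudo_report = pseudogene_filter(
            retained, gametologue_proteins
        )
        pseudo_report.to_csv(out / "pseudogene_filter.tsv", sep="\t")
        paths["pseudogene_filter"] = str(out / "pseudogene_filter.tsv")
    screen.to_csv(out / "screen.tsv", sep="\t")
    report.to_csv(out / "retroviral_filter.tsv", sep="\t")
    wio.write_fragments(out / "retained.fasta", retained)
    return paths


def run_scaffold(fragments, z_fasta, out: Path) -> dict:
    frags = wio.read_fragments(fragments)
    z_seqs = dict(wio.read_fasta(z_fasta))
    out.mkdir(parents=True, exist_ok=True)
    consensus, layouts, reports = [], [], {}
    for zid, z in z_seqs.items():
        pid = zid.rsplit("_Z", 1)[0]
        mine = [f for f in frags if f.id.startswith(pid)] or frags
        merged, report = assemble_w_transcript(mine, z)
        reports[pid] = report
        if merged.sequence:
            consensus.append((pid + "_consensus", merged.sequence))
    wio.write_fasta(out / "consensus.fasta", consensus)
    (out / "assembly_report.json").write_text(json.dumps(reports, indent=2))
    return {"consensus": str(out / "consensus.fasta"),
            "report": str(out / "assembly_report.json")}


def run_gametologue(w_fasta, z_fasta, out: Path, counts=None, design=None,
                    pairs=None) -> dict:
    w_seqs = dict(wio.read_fasta(w_fasta))
    z_seqs = dict(wio.read_fasta(z_fasta))
    out.mkdir(parents=True, exist_ok=True)
    rows, windows = [], []
    for wid, w in sorted(w_seqs.items()):
        pid = wid.rsplit("_", 1)[0] if wid.endswith(("_W", "_consensus")) else wid
        z = z_seqs.get(pid + "_Z")
        if z is None and len(z_seqs) == 1:
            z = next(iter(z_seqs.values()))
        if z is None:
            continue
        if "N" in w or len(w) % 3:
            log.warning("%s consensus not frame-clean; skipping dN/dS", wid)
            continue
        comp = compare_pair(pid, w, z)
        rows.append({
            "pair_id": pid,
            "dna_identity_pct": round(comp.dna_identity, 1),
            "protein_identity_pct": round(comp.protein_identity, 1),
            "dn": round(comp.dn, 6),
            "ds": round(comp.ds, 6),
            "dnds": "" if comp.omega is None else round(comp.omega, 3),
            "status": comp.omega_status,
        })
        for mid, omega in comp.window_profile:
            windows.append({"pair_id": pid, "midpoint_codon": mid,
                            "omega": "" if omega is None else round(omega, 4)})
    pd.DataFrame(rows).to_csv(out / "divergence.tsv", sep="\t", index=False)
    pd.DataFrame(windows).to_csv(out / "windows.tsv", sep="\t", index=False)
    paths = {"divergence": str(out / "divergence.tsv"),
             "windows": str(out / "windows.tsv")}

    if counts and design and pairs:
        experiment = wio.read_experiment(counts, design)
        pair_map = pd.read_csv(pairs, sep="\t")
        verdicts = []
        for _, row in pair_map.iterrows():
            v = combined_expression_compare(
                row["pair_id"],
                experiment.counts.loc[row["w_gene"]],
                experiment.counts.loc[row["z_gene"]],
                experiment.design,
                normalize_library_sizes(experiment),
            )
            for tissue in v.pvalue:
                verdicts.append({
                    "pair_id": v.pair_id, "tissue": tissue,
                    "female_total_cpm": round(v.female_total[tissue], 3),
                    "male_total_cpm": round(v.male_total[tissue], 3),
                    "w_share": round(v.w_share[tissue], 3),
                    "pvalue": v.pvalue[tissue],
                    "significant": v.significant[tissue],
                })
        pd.DataFrame(verdicts).to_csv(out / "combined_expression.tsv",
                                      sep="\t", index=False)
        paths["combined_expression"] = str(out / "combined_expression.tsv")
    return paths


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------


def run_pipeline(config: dict, out_dir, seed: int | None = None,
                 force: bool = False) -> Path:
    """Run every stage into ``out_dir`` and write a manifest.

    ``config`` follows :data:`DEFAULT_CONFIG`; with ``simulate: false`` the
    ``inputs`` section must name counts/design/annotation (an error names
    the missing key).  Existing non-empty run directories are refused
    without ``force``.
    """
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(
            f"run directory {out} is not empty (use force to overwrite)"
        )
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 42) if seed is None else seed)
    manifest: dict = {"seed": seed, "stages": {}, "config": config}

    def record(stage: str, paths: dict) -> None:
        manifest["stages"][stage] = {
            "seed": stage_seed(seed, stage),
            "outputs": {k: _checksum(Path(v)) for k, v in paths.items()},
            "paths": paths,
        }
        log.info("stage %s done (%d outputs)", stage, len(paths))

    if config.get("simulate", True):
        sim_paths = run_simulate(config, out / "simulate",
                                 stage_seed(seed, "simulate"))
        record("simulate", sim_paths)
        inputs = sim_paths
    else:
        inputs = dict(config.get("inputs", {}))
        for key in ("counts", "design", "annotation"):
            if key not in inputs:
                raise KeyError(
                    f"config key inputs.{key} is required when simulate is false"
                )
        manifest["stages"]["simulate"] = {"skipped": True, "inputs": inputs}

    record("dimorphism", run_dimorphism(
        inputs["counts"], inputs["design"], inputs["annotation"],
        out / "dimorphism", fdr=config.get("fdr", 0.05)))

    if "candidates" in inputs:
        from .codons import translate_cds

        gam_proteins = [
            (zid, translate_cds(seq).rstrip("*"))
            for zid, seq in wio.read_fasta(inputs["z_gametologues"])
        ]
        record("discover", run_discover(
            inputs["candidates"], inputs["candidate_fpkm"], inputs["design"],
            out / "discover", gametologue_proteins=gam_proteins))
        record("scaffold", run_scaffold(
            inputs["fragments"], inputs["z_gametologues"], out / "scaffold"))
        record("gametologue", run_gametologue(
            out / "scaffold" / "consensus.fasta", inputs["z_gametologues"],
            out / "gametologue", counts=inputs["counts"],
            design=inputs["design"], pairs=inputs["pairs"]))
    manifest["n_stages"] = len(manifest["stages"])
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out
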