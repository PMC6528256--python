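"""Pipeline orchestration: simulate -> quantify -> covariates -> qtl ->
characterize -> rcs -> coloc, with plain-file handoff between stages.

Every stage reads its inputs from the output directory and writes its
artifacts back there, so any stage can be re-run from prior outputs.
Identical config and seed give byte-identical artifacts.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import characterize as chrz
from . import covariates as cov
from . import gwas as gwasmod
from . import io as cio
from . import qtl as qtlmod
from . import quantify as qnt
from . import rcs as rcsmod
from .simulate import SimulationConfig, simulate_dataset

logger = logging.getLogger(__name__)

STAGES = ["simulate", "quantify", "covariates", "qtl", "characterize", "rcs", "coloc"]

FILES = {
    "counts_c": "counts_circular.tsv",
    "counts_l": "counts_linear.tsv",
    "dosages": "dosages.tsv",
    "snps": "snps.tsv",
    "covariates": "covariates.tsv",
    "circ_bed": "circs.bed",
    "genes": "genes.tsv",
    "exons": "exons.tsv",
    "introns": "introns.fa",
    "gwas": "gwas.tsv",
    "truth_effects": "truth_effects.tsv",
    "truth_rcs": "truth_rcs.tsv",
    "truth_gwas": "truth_gwas_links.tsv",
    "snp_annot": "snp_annotations.tsv",
    "kept": "kept_features.txt",
    "ratio": "ratio.tsv",
    "cpm": "circcpm.tsv",
    "circ_annot": "circ_annotated.tsv",
    "adjusted": "adjusted_expression.tsv",
    "weights": "voom_weights.tsv",
    "qtl_cpm": "qtl_cpm.tsv",
    "qtl_ratio": "qtl_ratio.tsv",
    "qtl_final": "qtl_final.tsv",
    "qtl_summary_cpm": "qtl_summary_cpm.tsv",
    "qtl_summary_ratio": "qtl_summary_ratio.tsv",
    "max_circqtl": "max_circqtl.tsv",
    "controls": "control_snps.txt",
    "enrichment": "element_enrichment.tsv",
    "distance": "backsplice_distance.tsv",
    "splice_report": "splice_site_report.tsv",
    "rcs_flags": "rcs_flags.tsv",
    "rcs_hits": "rcs_hits.tsv",
    "coloc_pairs": "colocalization.tsv",
    "coloc_enrichment": "gwas_enrichment.tsv",
    "report": "run_report.json",
}

DEFAULTS = {
    "cis_window": 100_000,
    "ratio_floor": 0.05,
    "n_perm": 1000,
    "q_cutoff": 0.05,
    "bits_threshold": 100.0,
    "r2_coloc": 0.8,
    "r2_linked": 0.6,
    "ratio_offset": 0.01,
}


@dataclass
class PipelineConfig:
    seed: int
    simulation: SimulationConfig
    cis_window: int = DEFAULTS["cis_window"]
    ratio_floor: float = DEFAULTS["ratio_floor"]
    n_perm: int = DEFAULTS["n_perm"]
    q_cutoff: float = DEFAULTS["q_cutoff"]
    bits_threshold: float = DEFAULTS["bits_threshold"]
    r2_coloc: float = DEFAULTS["r2_coloc"]
    r2_linked: float = DEFAULTS["r2_linked"]
    ratio_offset: float = DEFAULTS["ratio_offset"]
    stages: tuple[str, ...] = tuple(STAGES)


def validate_config(raw: dict) -> PipelineConfig:
    """Normalize a raw (parsed YAML) config: fill defaults, reject
    contradictions, require an explicit seed."""
    if "seed" not in raw:
        raise ValueError("missing required field: seed")
    sim_raw = dict(raw.get("simulation", {}))
    sim_raw.setdefault("seed", int(raw["seed"]))
    sim = SimulationConfig(**sim_raw)
    cfg = PipelineConfig(seed=int(raw["seed"]), simulation=sim)
    for key, default in DEFAULTS.items():
        val = raw.get(key, default)
        setattr(cfg, key, type(default)(val))
    if cfg.cis_window <= 0:
        raise ValueError("cis_window must be positive")
    if cfg.n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if not (0 < cfg.q_cutoff < 1):
        raise ValueError("q_cutoff must be in (0, 1)")
    if "stages" in raw:
        unknown = set(raw["stages"]) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        cfg.stages = tuple(s for s in STAGES if s in raw["stages"])
    return cfg


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        return validate_config(yaml.safe_load(fh) or {})


def _require(outdir: Path, keys: list[str], stage: str, needed_by: str) -> None:
    for k in keys:
        if not (outdir / FILES[k]).exists():
            raise FileNotFoundError(
                f"stage {needed_by!r} needs {FILES[k]} produced by stage {stage!r}; "
                f"run that stage first"
            )


def stage_simulate(cfg: PipelineConfig, outdir: Path) -> dict:
    ds = simulate_dataset(cfg.simulation)
    cio.write_counts(ds.counts, outdir / FILES["counts_c"], outdir / FILES["counts_l"])
    cio.write_genotypes_tsv(ds.genotypes, outdir / FILES["dosages"], outdir / FILES["snps"])
    ds.covariates.to_csv(outdir / FILES["covariates"], sep="\t", float_format="%.10g")
    cio.write_circ_bed(ds.circs, outdir / FILES["circ_bed"])
    cio.write_annotation(ds.annotation, outdir / FILES["genes"], outdir / FILES["exons"])
    cio.write_intron_fasta(ds.introns, outdir / FILES["introns"])
    ds.gwas.to_csv(outdir / FILES["gwas"], sep="\t", index=False, float_format="%.10g")
    ds.truth.effects.to_csv(outdir / FILES["truth_effects"], sep="\t", index=False)
    ds.truth.rcs.to_csv(outdir / FILES["truth_rcs"], sep="\t", index=False)
    ds.truth.gwas_links.to_csv(outdir / FILES["truth_gwas"], sep="\t", index=False, float_format="%.10g")
    ds.snp_annotations.to_csv(outdir / FILES["snp_annot"], sep="\t")
    return {
        "n_samples": int(cfg.simulation.n_samples),
        "n_snps": int(len(ds.genotypes.snp_ids)),
        "n_circ": int(cfg.simulation.n_circ),
        "n_planted_effects": int(len(ds.truth.effects)),
    }


def stage_quantify(cfg: PipelineConfig, outdir: Path) -> dict:
    _require(outdir, ["counts_c", "counts_l", "circ_bed", "genes", "exons"], "simulate", "quantify")
    counts = cio.read_counts(outdir / FILES["counts_c"], outdir / FILES["counts_l"])
    circs = cio.read_circ_bed(outdir / FILES["circ_bed"])
    annotation = cio.read_annotation(outdir / FILES["genes"], outdir / FILES["exons"])
    kept = qnt.filter_expressed(counts, ratio_floor=cfg.ratio_floor)
    sub = counts.subset(kept)
    ratios = qnt.ratio_matrix(sub)
    cpm = qnt.circcpm(sub)
    annotated = qnt.annotate_circs(circs.loc[kept], annotation)
    (outdir / FILES["kept"]).write_text("\n".join(kept) + "\n")
    cio.write_matrix(ratios, outdir / FILES["ratio"])
    cio.write_matrix(cpm, outdir / FILES["cpm"])
    annotated.to_csv(outdir / FILES["circ_annot"], sep="\t")
    return {
        "n_input": int(len(counts.feature_ids)),
        "n_kept": int(len(kept)),
        "n_dropped_expression_filter": int(len(counts.feature_ids) - len(kept)),
    }


def stage_covariates(cfg: PipelineConfig, outdir: Path) -> dict:
    _require(outdir, ["cpm", "covariates"], "quantify", "covariates")
    cpm = cio.read_matrix(outdir / FILES["cpm"])
    covariates = pd.read_csv(outdir / FILES["covariates"], sep="\t", index_col=0)
    design = cov.build_design(covariates)
    weights = cov.voom_weights(cpm, design)
    adjusted = cov.adjust_covariates(cpm, weights, design)
    cio.write_matrix(weights, outdir / FILES["weights"])
    cio.write_matrix(adjusted, outdir / FILES["adjusted"])
    return {"n_features": int(cpm.shape[0]), "n_design_columns": int(design.shape[1])}


def _logit_ratio(ratios: pd.DataFrame, offset: float) -> pd.DataFrame:
    r = (ratios.values + offset) / (1.0 + 2 * offset)
    return pd.DataFrame(np.log(r / (1 - r)), index=ratios.index, columns=ratios.columns)


def stage_qtl(cfg: PipelineConfig, outdir: Path) -> dict:
    _require(outdir, ["adjusted", "ratio", "dosages", "snps", "circ_annot", "covariates"], "covariates", "qtl")
    adjusted = cio.read_matrix(outdir / FILES["adjusted"])
    ratios = cio.read_matrix(outdir / FILES["ratio"])
    genotypes = cio.read_genotypes_tsv(outdir / FILES["dosages"], outdir / FILES["snps"]).filter_quality()
    circs = pd.read_csv(outdir / FILES["circ_annot"], sep="\t", index_col=0)
    covariates = pd.read_csv(outdir / FILES["covariates"], sep="\t", index_col=0)
    design = cov.build_design(covariates)
    pairs = qtlmod.cis_pairs(circs, genotypes, window=cfg.cis_window)
    scan_cpm = qtlmod.call_circqtls(
        adjusted, genotypes, pairs, n_perm=cfg.n_perm, seed=cfg.seed + 101,
        q_cutoff=cfg.q_cutoff, quantification="circCPM",
    )
    hosted = circs.index[circs["circ_class"].isin(["exonic", "intronic"])]
    pairs_ratio = pairs[pairs["circ_id"].isin(hosted)]
    scan_ratio = qtlmod.call_circqtls(
        _logit_ratio(ratios.loc[hosted], cfg.ratio_offset), genotypes, pairs_ratio,
        n_perm=cfg.n_perm, seed=cfg.seed + 101, design=design,
        q_cutoff=cfg.q_cutoff, quantification="ratio",
    )
    final = qtlmod.concordance_filter(scan_cpm.qtls, scan_ratio.qtls, circs["circ_class"])
    final = final.assign(snp_pos=final["snp_id"].map(genotypes.snps["pos"]))
    scan_cpm.pairs.to_csv(outdir / FILES["qtl_cpm"], sep="\t", index=False, float_format="%.10g")
    scan_ratio.pairs.to_csv(outdir / FILES["qtl_ratio"], sep="\t", index=False, float_format="%.10g")
    final.to_csv(outdir / FILES["qtl_final"], sep="\t", index=False, float_format="%.10g")
    scan_cpm.summary.to_csv(outdir / FILES["qtl_summary_cpm"], sep="\t", float_format="%.10g")
    scan_ratio.summary.to_csv(outdir / FILES["qtl_summary_ratio"], sep="\t", float_format="%.10g")
    return {
        "n_cis_pairs": int(len(pairs)),
        "n_qtl_circ_cpm": int(scan_cpm.summary["is_qtl_circ"].sum()),
        "n_qtl_pairs_cpm": int(len(scan_cpm.qtls)),
        "n_qtl_pairs_ratio": int(len(scan_ratio.qtls)),
        "n_final_qtl_pairs": int(len(final)),
        "pi0_cpm": float(scan_cpm.pi0),
    }


def stage_characterize(cfg: PipelineConfig, outdir: Path) -> dict:
    _require(outdir, ["qtl_final", "qtl_cpm", "dosages", "snps", "snp_annot", "circ_annot", "adjusted"], "qtl", "characterize")
    final = pd.read_csv(outdir / FILES["qtl_final"], sep="\t")
    genotypes = cio.read_genotypes_tsv(outdir / FILES["dosages"], outdir / FILES["snps"])
    circs = pd.read_csv(outdir / FILES["circ_annot"], sep="\t", index_col=0)
    annotations = pd.read_csv(outdir / FILES["snp_annot"], sep="\t", index_col=0)
    adjusted = cio.read_matrix(outdir / FILES["adjusted"])
    nominal = pd.read_csv(outdir / FILES["qtl_cpm"], sep="\t")
    if len(final) == 0:
        for k in ("max_circqtl", "enrichment", "distance", "splice_report"):
            pd.DataFrame().to_csv(outdir / FILES[k], sep="\t")
        (outdir / FILES["controls"]).write_text("")
        return {"n_max_circqtl": 0, "n_pruned": 0, "n_controls": 0}
    max_q = chrz.select_max_circqtl(final, circs)
    pruned = chrz.prune_ld(
        sorted(set(max_q["snp_id"]), key=lambda s: genotypes.snps.loc[s, "pos"]), genotypes
    )
    # control pool: SNPs never below nominal P 0.05 for any circ, LD-pruned
    min_p = nominal.groupby("snp_id")["p"].min()
    null_snps = [s for s in min_p.index[min_p > 0.05] if s not in set(max_q["snp_id"])]
    null_snps = sorted(null_snps, key=lambda s: genotypes.snps.loc[s, "pos"])
    null_pruned = chrz.prune_ld(null_snps, genotypes)
    pos = genotypes.snps["pos"]
    maf = genotypes.snps["maf"]

    def _dist(snp, cid):
        c = circs.loc[cid]
        d = chrz.backsplice_distance(int(pos.loc[snp]), int(c["start"]), int(c["end"]), window=10**9)
        return 0.0 if d["kind"] == "internal" else abs(d["value"])

    max_tbl = pd.DataFrame(
        {"snp_id": max_q["snp_id"], "maf": max_q["snp_id"].map(maf),
         "dist": [_dist(s, c) for s, c in zip(max_q["snp_id"], max_q["circ_id"])]}
    )
    max_tbl = max_tbl[max_tbl["snp_id"].isin(pruned)]
    snp_to_circ = dict(zip(nominal["snp_id"], nominal["circ_id"]))
    cand = pd.DataFrame(
        {"snp_id": null_pruned, "maf": [maf.loc[s] for s in null_pruned],
         "dist": [_dist(s, snp_to_circ[s]) for s in null_pruned]}
    )
    try:
        controls = chrz.matched_controls(cand, max_tbl, seed=cfg.seed + 202)
    except ValueError as exc:
        logger.warning("control matching failed (%s); using all candidates", exc)
        controls = list(cand["snp_id"])
    enrich = chrz.element_enrichment(list(max_tbl["snp_id"]), controls, annotations)
    dist_rows = []
    for row in max_q.itertuples():
        c = circs.loc[row.circ_id]
        d = chrz.backsplice_distance(int(pos.loc[row.snp_id]), int(c["start"]), int(c["end"]), window=10**9)
        dist_rows.append({"circ_id": row.circ_id, "snp_id": row.snp_id, **d})
    splice = chrz.splice_site_report(final, annotations, adjusted, genotypes)
    max_q.to_csv(outdir / FILES["max_circqtl"], sep="\t", index=False, float_format="%.10g")
    (outdir / FILES["controls"]).write_text("\n".join(controls) + ("\n" if controls else ""))
    enrich.to_csv(outdir / FILES["enrichment"], sep="\t", index=False, float_format="%.10g")
    pd.DataFrame(dist_rows).to_csv(outdir / FILES["distance"], sep="\t", index=False, float_format="%.10g")
    splice.to_csv(outdir / FILES["splice_report"], sep="\t", index=False)
    return {
        "n_max_circqtl": int(len(max_q)),
        "n_pruned": int(len(max_tbl)),
        "n_controls": int(len(controls)),
    }


def stage_rcs(cfg: PipelineConfig, outdir: Path) -> dict:
    _require(outdir, ["introns", "circ_annot"], "simulate", "rcs")
    introns = cio.read_intron_fasta(outdir / FILES["introns"])
    circs = pd.read_csv(outdir / FILES["circ_annot"], sep="\t", index_col=0)
    exonic = set(circs.index[circs["circ_class"] == "exonic"])
    subset = {k: v for k, v in introns.items() if k in exonic}
    flags, hits = rcsmod.scan_introns(subset, threshold=cfg.bits_threshold)
    flags.to_csv(outdir / FILES["rcs_flags"], sep="\t")
    hits.to_csv(outdir / FILES["rcs_hits"], sep="\t", index=False, float_format="%.10g")
    return {"n_intron_pairs": int(len(subset)), "n_rcs_positive": int(flags["has_rcs"].sum())}


def stage_coloc(cfg: PipelineConfig, outdir: Path) -> dict:
    _require(outdir, ["gwas", "qtl_final", "max_circqtl", "controls", "dosages", "snps", "circ_annot"], "characterize", "coloc")
    gwas = pd.read_csv(outdir / FILES["gwas"], sep="\t")
    final = pd.read_csv(outdir / FILES["qtl_final"], sep="\t")
    genotypes = cio.read_genotypes_tsv(outdir / FILES["dosages"], outdir / FILES["snps"])
    circs = pd.read_csv(outdir / FILES["circ_annot"], sep="\t", index_col=0)
    try:
        max_q = pd.read_csv(outdir / FILES["max_circqtl"], sep="\t")
    except pd.errors.EmptyDataError:
        max_q = pd.DataFrame()
    controls = [s for s in (outdir / FILES["controls"]).read_text().splitlines() if s]
    sig = gwasmod.filter_gwas(gwas)
    result = {"n_index_snps": int(len(sig))}
    if len(max_q) and "snp_id" in max_q.columns and len(controls):
        linked_sets = gwasmod.expand_ld(list(sig["SNPS"]), genotypes, r2_min=cfg.r2_linked)
        linked = set().union(*linked_sets.values()) if linked_sets else set()
        odds, p, table = gwasmod.gwas_enrichment(list(max_q["snp_id"]), controls, linked)
        pd.DataFrame([
            {"odds_ratio": odds, "p": p, "a": table[0], "b": table[1], "c": table[2], "d": table[3]}
        ]).to_csv(outdir / FILES["coloc_enrichment"], sep="\t", index=False, float_format="%.10g")
        result.update({"enrichment_or": float(odds), "enrichment_p": float(p)})
    coloc = gwasmod.colocalize(final, sig, genotypes, circs, r2_min=cfg.r2_coloc)
    coloc.to_csv(outdir / FILES["coloc_pairs"], sep="\t", index=False, float_format="%.10g")
    result["n_coloc_pairs"] = int(len(coloc))
    return result


STAGE_FUNCS = {
    "simulate": stage_simulate,
    "quantify": stage_quantify,
    "covariates": stage_covariates,
    "qtl": stage_qtl,
    "characterize": stage_characterize,
    "rcs": stage_rcs,
    "coloc": stage_coloc,
}


def run_pipeline(cfg: PipelineConfig, outdir) -> dict:
    """Run the configured stages in dependency order; returns the run report
    (also written as JSON to the output directory)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = {
        "parameters": {
            **{k: getattr(cfg, k) for k in DEFAULTS},
            "seed": cfg.seed,
            "simulation": {
                k: v for k, v in dataclasses.asdict(cfg.simulation).items()
                if not isinstance(v, (tuple, list, dict)) or k in ("maf_range", "depth_range")
            },
        },
        "stages": {},
    }
    for stage in STAGES:
        if stage not in cfg.stages:
            continue
        t0 = time.perf_counter()
        logger.info("running stage %s", stage)
        stats = STAGE_FUNCS[stage](cfg, outdir)
        stats["wall_seconds"] = round(time.perf_counter() - t0, 3)
        report["stages"][stage] = stats
    with open(outdir / FILES["report"], "w") as fh:
        json.dump(report, fh, indent=2, default=str, sort_keys=True)
    return report
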