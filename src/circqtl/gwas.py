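"""GWAS filtering, LD expansion, circQTL enrichment and colocalization.

Disease-associated index SNPs (P <= 5e-8) from a GWAS-catalog-style table
are expanded to the SNPs linked at r^2 > 0.6 in the genotype panel; the
enrichment of pruned max-circQTL SNPs in that linked set over matched
non-circQTL controls is a one-tailed Fisher test; and circQTL SNPs in high
LD (r^2 > 0.8) with index SNPs are reported as colocalized circRNA-disease
pairs.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .characterize import backsplice_distance, fisher_2x2, ld_r2
from .core import GenotypeMatrix

logger = logging.getLogger(__name__)

GWAS_P_MAX = 5e-8
LD_RADIUS = 1_000_000  # search radius around an index SNP


def filter_gwas(
    table: pd.DataFrame, p_max: float = GWAS_P_MAX, traits: list[str] | None = None
) -> pd.DataFrame:
    """Genome-wide-significant rows (P <= p_max) for the requested traits
    (literal label match; empty/None keeps all traits)."""
    p = pd.to_numeric(table["P-VALUE"], errors="coerce")
    bad = np.flatnonzero(~np.isfinite(p.values) | (p.values <= 0) | (p.values > 1))
    if len(bad):
        raise ValueError(f"malformed P value at row {bad[0]}")
    keep = p <= p_max
    if traits:
        keep &= table["DISEASE/TRAIT"].isin(traits)
    return table[keep].reset_index(drop=True)


def expand_ld(
    index_snps: list[str],
    genotypes: GenotypeMatrix,
    r2_min: float = 0.6,
    radius: int = LD_RADIUS,
) -> dict[str, list[str]]:
    """Per index SNP, all panel SNPs within ``radius`` bp with r^2 strictly
    above ``r2_min`` (an index SNP is always in its own set). Index SNPs
    absent from the panel are logged and skipped."""
    out: dict[str, list[str]] = {}
    snps = genotypes.snps
    D = genotypes.dosages.values.astype(float)
    Dc = D - D.mean(axis=1, keepdims=True)
    sd = Dc.std(axis=1)
    Dn = Dc / np.where(sd[:, None] > 0, sd[:, None], 1.0) / np.sqrt(D.shape[1])
    loc = {s: i for i, s in enumerate(genotypes.snp_ids)}
    for idx in index_snps:
        if idx not in loc:
            logger.warning("index SNP %s not in the genotype panel; skipped", idx)
            continue
        i = loc[idx]
        near = (snps["chrom"] == snps["chrom"].iloc[i]) & (
            (snps["pos"] - snps["pos"].iloc[i]).abs() <= radius
        )
        cand = np.flatnonzero(near.values)
        r = Dn[cand] @ Dn[i]
        linked = [genotypes.snp_ids[j] for j, rv in zip(cand, r) if rv * rv > r2_min or j == i]
        out[idx] = linked
    return out


def gwas_enrichment(
    max_circqtls: list[str],
    controls: list[str],
    linked: set[str],
) -> tuple[float, float, tuple[int, int, int, int]]:
    """One-tailed Fisher enrichment of circQTL SNPs in the GWAS-linked set
    against matched controls. Returns (OR, P, 2x2 table); OR is NaN when the
    linked set is empty."""
    if not max_circqtls:
        raise ValueError("empty circQTL set")
    if not linked:
        return float("nan"), float("nan"), (0, len(max_circqtls), 0, len(controls))
    a = sum(1 for s in max_circqtls if s in linked)
    c = sum(1 for s in controls if s in linked)
    b, d = len(max_circqtls) - a, len(controls) - c
    odds, p = fisher_2x2(a, b, c, d, alternative="greater")
    return odds, p, (a, b, c, d)


def per_disease_enrichment(
    max_circqtls: list[str],
    controls: list[str],
    gwas: pd.DataFrame,
    genotypes: GenotypeMatrix,
    r2_min: float = 0.6,
    min_risk_loci: int = 90,
) -> pd.DataFrame:
    """Repeat the enrichment per trait (BH across traits), testing only
    traits with strictly more than ``min_risk_loci`` significant loci."""
    sig = filter_gwas(gwas)
    rows = []
    for trait, grp in sig.groupby("DISEASE/TRAIT"):
        if len(grp) <= min_risk_loci:
            continue
        linked_sets = expand_ld(list(grp["SNPS"]), genotypes, r2_min)
        linked = set().union(*linked_sets.values()) if linked_sets else set()
        odds, p, table = gwas_enrichment(max_circqtls, controls, linked)
        rows.append({"trait": trait, "odds_ratio": odds, "p": p, "n_loci": len(grp)})
    out = pd.DataFrame(rows, columns=["trait", "odds_ratio", "p", "n_loci"])
    if len(out):
        from statsmodels.stats.multitest import multipletests

        out["fdr"] = multipletests(out["p"].fillna(1.0).values, method="fdr_bh")[1]
    return out


def colocalize(
    circqtl_snps: pd.DataFrame,
    index_snps: pd.DataFrame,
    genotypes: GenotypeMatrix,
    circs: pd.DataFrame,
    r2_min: float = 0.8,
    radius: int = LD_RADIUS,
) -> pd.DataFrame:
    """circQTL-GWAS colocalization pairs at r^2 strictly above ``r2_min``.

    ``circqtl_snps`` needs columns circ_id, snp_id; ``index_snps`` needs
    SNPS and DISEASE/TRAIT (already filtered to genome-wide significance).
    Each reported row carries the circQTL SNP's region class relative to its
    circRNA (flanking intron / circRNA region / other).
    """
    rows = []
    panel = set(genotypes.snp_ids)
    pos = genotypes.snps["pos"]
    for idx_label, idx_data in index_snps.iterrows():
        idx = idx_data["SNPS"]
        trait = idx_data["DISEASE/TRAIT"]
        if idx not in panel:
            logger.warning("index SNP %s not in the genotype panel; skipped", idx)
            continue
        for q_row in circqtl_snps.itertuples():
            snp = q_row.snp_id
            if snp not in panel:
                continue
            if abs(int(pos.loc[snp]) - int(pos.loc[idx])) > radius:
                continue
            r2 = ld_r2(genotypes, snp, idx)
            if not np.isnan(r2) and r2 > r2_min:
                circ = circs.loc[q_row.circ_id]
                desc = backsplice_distance(int(pos.loc[snp]), int(circ["start"]), int(circ["end"]))
                rows.append(
                    {"circ_id": q_row.circ_id, "snp_id": snp, "index_snp": idx,
                     "trait": trait, "r2": r2, "region": desc["region"]}
                )
    return pd.DataFrame(rows, columns=["circ_id", "snp_id", "index_snp", "trait", "r2", "region"])
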