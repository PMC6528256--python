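"""Characterization of circQTL SNPs.

Selects the most significant SNP per circQTL-containing circRNA
(max-circQTL), prunes linked SNPs with a sliding-window r^2 rule, draws
MAF- and distance-matched non-circQTL controls, measures distances to the
back-splice sites, and tests enrichment of sequence-defined element
categories (two-tailed Fisher's exact test with BH correction), including a
separate reverse-complement-sequence test restricted to intronic SNPs.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import GenotypeMatrix

logger = logging.getLogger(__name__)

ELEMENT_CATEGORIES = [
    "canonical splice site",
    "missense",
    "splice region",
    "synonymous",
    "5' UTR",
    "3' UTR",
    "noncoding transcript exon",
    "intron",
    "upstream gene",
    "downstream gene",
    "intergenic",
]


def _distance_to_backsplice(pos: int, start: int, end: int) -> float:
    """Signed distance to the nearest back-splice site; 0 for internal SNPs."""
    if pos < start:
        return pos - start
    if pos > end:
        return pos - end
    return 0.0


def select_max_circqtl(final_qtls: pd.DataFrame, circs: pd.DataFrame) -> pd.DataFrame:
    """One SNP per circQTL-containing circRNA: smallest nominal P, ties
    broken by distance to the nearest back-splice site then snp_id."""
    if len(final_qtls) == 0:
        raise ValueError("empty circQTL set")
    df = final_qtls.copy()
    starts = df["circ_id"].map(circs["start"])
    ends = df["circ_id"].map(circs["end"])
    snp_pos = df["snp_pos"] if "snp_pos" in df.columns else None
    if snp_pos is None:
        raise ValueError("final_qtls must carry a snp_pos column")
    df["_dist"] = [
        abs(_distance_to_backsplice(p, s, e)) for p, s, e in zip(snp_pos, starts, ends)
    ]
    df = df.sort_values(["circ_id", "p", "_dist", "snp_id"], kind="mergesort")
    out = df.groupby("circ_id", sort=True).head(1).drop(columns=["_dist"])
    return out.reset_index(drop=True)


def ld_r2(genotypes: GenotypeMatrix, snp_a: str, snp_b: str) -> float:
    """Squared Pearson correlation of dosage vectors (PLINK's dosage r^2).

    NaN for monomorphic SNPs (undefined).
    """
    a = genotypes.dosages.loc[snp_a].values.astype(float)
    b = genotypes.dosages.loc[snp_b].values.astype(float)
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def prune_ld(
    snps: list[str],
    genotypes: GenotypeMatrix,
    window: int = 50,
    step: int = 5,
    r2_max: float = 0.5,
) -> list[str]:
    """Sliding-window LD pruning (the --indep-pairwise 50 5 0.5 procedure).

    Within each window of ``window`` SNPs, advanced by ``step``, any pair
    with r^2 > ``r2_max`` loses one member (the smaller-MAF SNP; ties drop
    the later position) until no such pair remains. Input must be
    position-sorted; the kept subset preserves input order.
    """
    pos = genotypes.snps["pos"]
    order = sorted(snps, key=lambda s: (genotypes.snps.loc[s, "chrom"], pos.loc[s]))
    if order != list(snps):
        raise ValueError("snps must be position-sorted")
    maf = genotypes.snps["maf"]
    D = genotypes.dosages.loc[order].values.astype(float)
    D = D - D.mean(axis=1, keepdims=True)
    sd = D.std(axis=1)
    Dn = D / np.where(sd[:, None] > 0, sd[:, None], 1.0) / np.sqrt(D.shape[1])
    loc = {s: i for i, s in enumerate(order)}

    def _r2(a: str, b: str) -> float:
        ia, ib = loc[a], loc[b]
        if sd[ia] == 0 or sd[ib] == 0:
            return float("nan")
        r = float(Dn[ia] @ Dn[ib])
        return r * r

    kept = set(snps)
    n = len(order)
    start = 0
    while True:
        win = [s for s in order[start : start + window] if s in kept]
        changed = True
        while changed:
            changed = False
            for i in range(len(win)):
                for j in range(i + 1, len(win)):
                    a, b = win[i], win[j]
                    r2 = _r2(a, b)
                    if np.isnan(r2) or r2 <= r2_max:
                        continue
                    if maf.loc[a] < maf.loc[b]:
                        drop = a
                    elif maf.loc[b] < maf.loc[a]:
                        drop = b
                    else:
                        drop = b  # tie: drop the later position
                    kept.discard(drop)
                    win = [s for s in win if s in kept]
                    changed = True
                    break
                if changed:
                    break
        if start + window >= n:
            break
        start += step
    return [s for s in order if s in kept]


def backsplice_distance(snp_pos: int, start: int, end: int, window: int = 100_000) -> dict:
    """Distance descriptor of a cis SNP relative to a circRNA.

    External SNPs report a signed bp distance to the nearest back-splice
    site (negative upstream of the 5' site); internal SNPs report their
    relative position (pos - start)/(end - start) in [0, 1]. The region
    class is ``circRNA region`` for internal SNPs, ``flanking intron`` for
    external SNPs within the flanking-intron reach of the back-splice sites
    (2 kb here), and ``other`` beyond.
    """
    if snp_pos < start - window or snp_pos > end + window:
        raise ValueError("SNP outside the cis window")
    if start <= snp_pos <= end:
        rel = (snp_pos - start) / (end - start) if end > start else 0.0
        return {"kind": "internal", "value": rel, "region": "circRNA region"}
    dist = _distance_to_backsplice(snp_pos, start, end)
    region = "flanking intron" if abs(dist) <= 2000 else "other"
    return {"kind": "external", "value": float(dist), "region": region}


def matched_controls(
    candidate_snps: pd.DataFrame,
    max_circqtls: pd.DataFrame,
    seed: int,
    maf_bin_width: float = 0.05,
) -> list[str]:
    """Non-circQTL controls matched to the max-circQTL set's joint MAF x
    distance distribution.

    Both inputs need columns snp_id, maf, dist (abs bp to the nearest
    back-splice site, 0 = internal). MAF bins are 0.05 wide; distance bins
    are {internal, 0-1 kb, 1-10 kb, 10-100 kb}. One control is drawn per
    target SNP without replacement; empty bins borrow from the nearest
    available bin with a logged warning.
    """
    if len(candidate_snps) < len(max_circqtls):
        raise ValueError("candidate pool smaller than the target set")
    rng = np.random.default_rng(seed)

    def binkey(maf, dist):
        mb = int(min(maf, 0.4999) / maf_bin_width)
        if dist == 0:
            db = 0
        elif dist <= 1000:
            db = 1
        elif dist <= 10_000:
            db = 2
        else:
            db = 3
        return (mb, db)

    pool: dict[tuple, list[str]] = {}
    for row in candidate_snps.itertuples():
        pool.setdefault(binkey(row.maf, row.dist), []).append(row.snp_id)
    for v in pool.values():
        rng.shuffle(v)
    chosen = []
    for row in max_circqtls.itertuples():
        key = binkey(row.maf, row.dist)
        if pool.get(key):
            chosen.append(pool[key].pop())
            continue
        # borrow from the nearest non-empty bin (Manhattan distance in bin space)
        avail = [k for k, v in pool.items() if v]
        if not avail:
            raise ValueError("candidate pool exhausted before matching completed")
        near = min(avail, key=lambda k: abs(k[0] - key[0]) + abs(k[1] - key[1]))
        logger.warning("control bin %s empty; borrowing from %s", key, near)
        chosen.append(pool[near].pop())
    return chosen


def fisher_2x2(a: int, b: int, c: int, d: int, alternative: str = "two-sided"):
    """Fisher's exact test on [[a, b], [c, d]] with Haldane-corrected OR.

    Two-tailed P is the hypergeometric sum of all tables with probability
    not exceeding the observed one; one-tailed ('greater') is the
    enrichment tail.
    """
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative=alternative)
    aa, bb, cc, dd = a, b, c, d
    if 0 in (a, b, c, d):
        aa, bb, cc, dd = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    odds = (aa * dd) / (bb * cc)
    return float(odds), float(p)


@dataclass
class EnrichmentRow:
    category: str
    table: tuple[int, int, int, int]  # in_qtl, out_qtl, in_ctrl, out_ctrl
    odds_ratio: float
    p: float
    fdr: float = float("nan")


def element_enrichment(
    max_set: list[str],
    control_set: list[str],
    annotations: pd.DataFrame,
) -> pd.DataFrame:
    """Per-category two-tailed Fisher tests of max-circQTLs vs controls.

    ``annotations`` is indexed by snp_id with columns category, in_RCS.
    Categories absent from both sets are skipped with a warning. The
    separate RCS test is restricted to SNPs in the intron category. Returns
    a DataFrame with category, a, b, c, d, odds_ratio, p, fdr (BH across
    the element categories; the RCS row keeps its raw P).
    """
    if not max_set or not control_set:
        raise ValueError("both SNP sets must be non-empty")
    missing = (set(max_set) | set(control_set)) - set(annotations.index)
    if missing:
        raise ValueError(f"unannotated SNPs: {sorted(missing)[:5]}")
    cat_q = annotations.loc[max_set, "category"]
    cat_c = annotations.loc[control_set, "category"]
    nq, nc = len(max_set), len(control_set)
    rows = []
    for cat in ELEMENT_CATEGORIES:
        a = int((cat_q == cat).sum())
        c = int((cat_c == cat).sum())
        if a == 0 and c == 0:
            logger.warning("category %r absent from both sets; skipped", cat)
            continue
        odds, p = fisher_2x2(a, nq - a, c, nc - c, alternative="two-sided")
        rows.append({"category": cat, "a": a, "b": nq - a, "c": c, "d": nc - c,
                     "odds_ratio": odds, "p": p})
    out = pd.DataFrame(rows)
    if len(out):
        from statsmodels.stats.multitest import multipletests

        out["fdr"] = multipletests(out["p"].values, method="fdr_bh")[1]
    # RCS enrichment among intronic SNPs only
    iq = [s for s in max_set if annotations.loc[s, "category"] == "intron"]
    ic = [s for s in control_set if annotations.loc[s, "category"] == "intron"]
    if iq and ic and "in_RCS" in annotations.columns:
        a = int(annotations.loc[iq, "in_RCS"].sum())
        c = int(annotations.loc[ic, "in_RCS"].sum())
        odds, p = fisher_2x2(a, len(iq) - a, c, len(ic) - c, alternative="two-sided")
        rcs_row = pd.DataFrame(
            [{"category": "RCS (intronic)", "a": a, "b": len(iq) - a, "c": c,
              "d": len(ic) - c, "odds_ratio": odds, "p": p, "fdr": np.nan}]
        )
        out = pd.concat([out, rcs_row], ignore_index=True)
    return out


def splice_site_report(
    qtls: pd.DataFrame,
    annotations: pd.DataFrame,
    expr: pd.DataFrame,
    genotypes: GenotypeMatrix,
) -> pd.DataFrame:
    """Genotype-stratified expression at canonical-splice-site circQTL SNPs.

    For every called pair whose SNP is flagged as a canonical splice site,
    reports the mean adjusted expression per rounded genotype class and
    whether the canonical (reference, dosage 0) genotype expresses higher.
    """
    flagged = annotations[annotations["category"] == "canonical splice site"].index
    rows = []
    for row in qtls[qtls["snp_id"].isin(flagged)].itertuples():
        if row.circ_id not in expr.index:
            continue
        dos = np.round(genotypes.dosages.loc[row.snp_id].values).astype(int)
        y = expr.loc[row.circ_id].values
        means = {g: float(y[dos == g].mean()) for g in (0, 1, 2) if (dos == g).any()}
        if len(means) < 2:
            direction = "none"
        else:
            gs = sorted(means)
            lo, hi = means[gs[0]], means[gs[-1]]
            if math.isclose(lo, hi, abs_tol=1e-9):
                direction = "none"
            else:
                direction = "canonical-higher" if lo > hi else "canonical-lower"
        site_class = (
            "back-splice"
            if bool(annotations.loc[row.snp_id].get("at_backsplice_site", False))
            else "internal splice"
        )
        rows.append(
            {"circ_id": row.circ_id, "snp_id": row.snp_id,
             "mean_by_genotype": means, "direction": direction, "site_class": site_class}
        )
    return pd.DataFrame(rows, columns=["circ_id", "snp_id", "mean_by_genotype", "direction", "site_class"])
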