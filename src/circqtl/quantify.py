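"""Quantification of circRNA expression from junction counts.

The circular ratio C/(C+L) measures the fraction of junction-spanning reads
supporting the circular isoform; circCPM (circular junction counts per
million circular junction reads) measures absolute circRNA abundance on a
depth-normalized log2 scale. Expression filters, locus classification and
inferred circle lengths follow the conventions of back-splice callers.
"""
from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .core import Annotation, CircRNA, JunctionCounts, merge_intervals

logger = logging.getLogger(__name__)

RATIO_FLOOR = 0.05  # minimum mean circular ratio for an expressed circRNA


def circular_ratio(C, L):
    """Circular ratio C/(C+L); defined as 0 where C+L=0 (unexpressed locus).

    Accepts scalars or aligned arrays; returns the same shape.
    """
    C = np.asarray(C, dtype=float)
    L = np.asarray(L, dtype=float)
    if (C < 0).any() or (L < 0).any():
        raise ValueError("junction counts must be non-negative")
    total = C + L
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(total > 0, C / np.where(total > 0, total, 1.0), 0.0)
    if ratio.ndim == 0:
        return float(ratio)
    return ratio


def ratio_matrix(counts: JunctionCounts) -> pd.DataFrame:
    """Per-feature, per-sample circular ratios in [0, 1]."""
    vals = circular_ratio(counts.C.values, counts.L.values)
    return pd.DataFrame(vals, index=counts.feature_ids, columns=counts.sample_ids)


def filter_expressed(counts: JunctionCounts, ratio_floor: float = RATIO_FLOOR) -> pd.Index:
    """Expressed circRNAs: C >= 1 in strictly more than half of the samples
    and mean circular ratio >= ``ratio_floor``, both over the same samples.
    """
    n = counts.C.shape[1]
    if n < 1 or counts.C.shape[0] < 1:
        raise ValueError("empty count matrix")
    detected = (counts.C.values >= 1).sum(axis=1)
    ratios = ratio_matrix(counts)
    keep = (detected > n / 2) & (ratios.mean(axis=1).values >= ratio_floor)
    return counts.feature_ids[keep]


def classify_circrna(circ: CircRNA, annotation: Annotation) -> str:
    """Classify a back-splice locus as exonic, intronic or intergenic.

    A locus with either end outside all genes is intergenic; with either end
    inside a gene but not in any exon it is intronic; only loci with both
    ends in annotated exons are exonic. Precedence: intergenic > intronic >
    exonic.
    """
    if circ.chrom not in annotation.chromosomes():
        raise ValueError(f"unknown chromosome {circ.chrom!r} for {circ.id}")
    classes = []
    for pos in (circ.start, circ.end):
        if len(annotation.genes_at(circ.chrom, pos)) == 0:
            classes.append("intergenic")
        elif len(annotation.exons_at(circ.chrom, pos)) == 0:
            classes.append("intronic")
        else:
            classes.append("exonic")
    if "intergenic" in classes:
        return "intergenic"
    if "intronic" in classes:
        return "intronic"
    return "exonic"


def circ_length(circ: CircRNA, annotation: Annotation) -> int:
    """Inferred circle length in bp.

    Exonic circles: sum of (merged) annotated exons fully enclosed by the
    back-splice sites. An enclosed gap between exons is counted as a
    retained intron only when the annotation offers no splice junction to
    remove it, i.e. the gap is not an annotated intron of a single host
    transcript (no enclosed exon boundary pair flanks it). Intronic and
    intergenic circles use the genomic span end - start + 1.
    """
    if circ.circ_class is None:
        circ.circ_class = classify_circrna(circ, annotation)
    span = circ.end - circ.start + 1
    if circ.circ_class in ("intronic", "intergenic"):
        return span
    enclosed = annotation.exons_within(circ.chrom, circ.start, circ.end)
    if len(enclosed) == 0:
        warnings.warn(
            f"exonic circRNA {circ.id} encloses no annotated exon; "
            "falling back to genomic span"
        )
        return span
    merged = merge_intervals(list(zip(enclosed["start"], enclosed["end"])))
    length = sum(e - s + 1 for s, e in merged)
    # Retained-intron clause: add an enclosed inter-exon gap only if no
    # annotated exon boundary (donor/acceptor pair of the host gene) flanks
    # it, i.e. the gap is not an annotated intron that linear splicing would
    # remove. With complete host-gene annotation every gap between enclosed
    # exons is such an intron, so nothing is added.
    host_bounds = set()
    for g in enclosed["gene_id"].unique():
        ex = annotation.exons[annotation.exons["gene_id"] == g]
        for s, e in zip(ex["start"], ex["end"]):
            host_bounds.add(("e", e))
            host_bounds.add(("s", s))
    for (s1, e1), (s2, e2) in zip(merged, merged[1:]):
        is_annotated_intron = ("e", e1) in host_bounds and ("s", s2) in host_bounds
        if not is_annotated_intron:
            length += s2 - e1 - 1
    return length


def circcpm(counts: JunctionCounts) -> pd.DataFrame:
    """log2 circCPM: log2((C + 0.5) / (T + 1) * 1e6) with T the per-sample
    total circular junction count over the (already filtered) feature set.

    The 0.5/1 offsets are the voom-lineage convention and keep zero counts
    finite.
    """
    C = counts.C.values.astype(float)
    totals = C.sum(axis=0)
    zero = totals == 0
    if zero.any():
        bad = list(counts.sample_ids[zero])
        raise ValueError(f"zero total circular junction counts for samples: {bad}")
    vals = np.log2((C + 0.5) / (totals + 1.0) * 1e6)
    return pd.DataFrame(vals, index=counts.feature_ids, columns=counts.sample_ids)


def gcpm_filter(gene_counts: pd.DataFrame, min_cpm: float = 1.0, min_frac: float = 0.5) -> pd.Index:
    """Host-gene expression filter: genes with >= ``min_cpm`` gene-CPM in at
    least ``min_frac`` of samples (inclusive thresholds)."""
    totals = gene_counts.sum(axis=0).values
    cpm = gene_counts.values / totals * 1e6
    frac = (cpm >= min_cpm).mean(axis=1)
    return gene_counts.index[frac >= min_frac]


def annotate_circs(circ_df: pd.DataFrame, annotation: Annotation) -> pd.DataFrame:
    """Classify and measure every circRNA in a table (id, chrom, start, end).

    Returns a copy with ``circ_class``, ``length`` and ``host_gene`` columns.
    """
    out = circ_df.copy()
    classes, lengths, hosts = [], [], []
    for row in out.itertuples():
        circ = CircRNA(chrom=row.chrom, start=row.start, end=row.end)
        circ.circ_class = classify_circrna(circ, annotation)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            lengths.append(circ_length(circ, annotation))
        classes.append(circ.circ_class)
        host = None
        if circ.circ_class != "intergenic":
            g5 = annotation.genes_at(circ.chrom, circ.start)
            g3 = annotation.genes_at(circ.chrom, circ.end)
            common = set(g5["gene_id"]) & set(g3["gene_id"])
            if common:
                host = sorted(common)[0]
            elif len(g5):
                host = g5["gene_id"].iloc[0]
        hosts.append(host)
    out["circ_class"] = classes
    out["length"] = lengths
    out["host_gene"] = hosts
    return out
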