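"""Core data containers shared across the pipeline.

Coordinates are 1-based inclusive internally (the convention of back-splice
callers such as CIRI); BED-style I/O converts at the boundary.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

CIRC_ID_RE = re.compile(r"^(?P<chrom>[^:]+):(?P<start>\d+)\|(?P<end>\d+)$")


def parse_circ_id(circ_id: str) -> tuple[str, int, int]:
    """Parse a back-splice locus id of the form ``chrom:start|end``."""
    m = CIRC_ID_RE.match(circ_id)
    if m is None:
        raise ValueError(f"malformed circRNA id: {circ_id!r}")
    return m.group("chrom"), int(m.group("start")), int(m.group("end"))


def format_circ_id(chrom: str, start: int, end: int) -> str:
    return f"{chrom}:{start}|{end}"


@dataclass
class CircRNA:
    """A back-splice junction locus.

    ``start``/``end`` are the 1-based inclusive coordinates of the two
    back-spliced sites (5' acceptor-side and 3' donor-side on the genome).
    """

    chrom: str
    start: int
    end: int
    strand: str = "+"
    circ_class: Optional[str] = None  # exonic | intronic | intergenic
    length: Optional[int] = None
    host_gene: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"start > end for {self.id}")

    @property
    def id(self) -> str:
        return format_circ_id(self.chrom, self.start, self.end)

    @classmethod
    def from_id(cls, circ_id: str, strand: str = "+") -> "CircRNA":
        chrom, start, end = parse_circ_id(circ_id)
        return cls(chrom=chrom, start=start, end=end, strand=strand)


@dataclass
class JunctionCounts:
    """Paired circular (C) and linear (L) junction count matrices.

    Both are features x samples DataFrames sharing index and columns.
    C counts reads spanning the back-splice junction; L is the mean count of
    reads crossing the two back-splice sites on the linear transcript.
    """

    C: pd.DataFrame
    L: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.C.index.equals(self.L.index) or not self.C.columns.equals(
            self.L.columns
        ):
            raise ValueError("C and L must share feature and sample labels")
        if (self.C.values < 0).any() or (self.L.values < 0).any():
            raise ValueError("junction counts must be non-negative")

    @property
    def feature_ids(self) -> pd.Index:
        return self.C.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.C.columns

    def subset(self, features) -> "JunctionCounts":
        return JunctionCounts(self.C.loc[features], self.L.loc[features])


@dataclass
class GenotypeMatrix:
    """SNP x sample additive dosages in [0, 2] with positional metadata.

    ``snps`` carries one row per SNP (index = snp id) with columns
    ``chrom``, ``pos`` (1-based), ``maf`` and ``qual`` (imputation quality).
    ``haplotypes`` optionally keeps the underlying (2, n_snps, n_samples)
    0/1 haplotype array from the simulator.
    """

    dosages: pd.DataFrame
    snps: pd.DataFrame
    haplotypes: Optional[np.ndarray] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not self.dosages.index.equals(self.snps.index):
            raise ValueError("dosage rows and SNP metadata must align")
        vals = self.dosages.values
        if np.nanmin(vals) < 0 or np.nanmax(vals) > 2:
            raise ValueError("dosages must lie in [0, 2]")

    @property
    def sample_ids(self) -> pd.Index:
        return self.dosages.columns

    @property
    def snp_ids(self) -> pd.Index:
        return self.dosages.index

    def filter_quality(self, min_qual: float = 0.8, min_maf: float = 0.05) -> "GenotypeMatrix":
        """Keep high-quality common SNPs (imputation quality and MAF filters)."""
        keep = (self.snps["qual"] >= min_qual) & (self.snps["maf"] >= min_maf)
        hap = None
        if self.haplotypes is not None:
            hap = self.haplotypes[:, keep.values, :]
        return GenotypeMatrix(self.dosages.loc[keep.values], self.snps.loc[keep.values], hap)


@dataclass
class Annotation:
    """Gene/exon annotation as interval tables, 1-based inclusive.

    ``genes``: columns gene_id, chrom, start, end, strand.
    ``exons``: columns gene_id, chrom, start, end.
    """

    genes: pd.DataFrame
    exons: pd.DataFrame

    def __post_init__(self) -> None:
        self._gene_by_chrom = {c: g for c, g in self.genes.groupby("chrom")}
        self._exon_by_chrom = {c: g for c, g in self.exons.groupby("chrom")}

    def chromosomes(self) -> set[str]:
        return set(self.genes["chrom"]) | set(self.exons["chrom"])

    def genes_at(self, chrom: str, pos: int) -> pd.DataFrame:
        g = self._gene_by_chrom.get(chrom)
        if g is None:
            return self.genes.iloc[0:0]
        return g[(g["start"] <= pos) & (g["end"] >= pos)]

    def exons_at(self, chrom: str, pos: int) -> pd.DataFrame:
        e = self._exon_by_chrom.get(chrom)
        if e is None:
            return self.exons.iloc[0:0]
        return e[(e["start"] <= pos) & (e["end"] >= pos)]

    def exons_within(self, chrom: str, start: int, end: int) -> pd.DataFrame:
        """Exons fully enclosed by [start, end]."""
        e = self._exon_by_chrom.get(chrom)
        if e is None:
            return self.exons.iloc[0:0]
        return e[(e["start"] >= start) & (e["end"] <= end)]


def merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping or book-ended 1-based inclusive intervals."""
    if not intervals:
        return []
    ivs = sorted(intervals)
    merged = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]
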