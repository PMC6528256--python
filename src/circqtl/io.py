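"""Plain-file readers and writers for pipeline handoff.

Everything travels as TSV/FASTA/VCF text so any stage can be inspected or
re-entered. Circ/exon intervals are written 0-based half-open per the BED
convention and converted back to the package's 1-based inclusive
coordinates on read.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .core import Annotation, GenotypeMatrix, JunctionCounts, format_circ_id


def write_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", float_format="%.10g")


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_counts(counts: JunctionCounts, circ_path, linear_path) -> None:
    write_matrix(counts.C, circ_path)
    write_matrix(counts.L, linear_path)


def read_counts(circ_path, linear_path) -> JunctionCounts:
    return JunctionCounts(C=read_matrix(circ_path), L=read_matrix(linear_path))


def write_circ_bed(circs: pd.DataFrame, path) -> None:
    """BED6 of back-splice loci (0-based half-open)."""
    with open(path, "w") as fh:
        for row in circs.itertuples():
            fh.write(
                f"{row.chrom}\t{row.start - 1}\t{row.end}\t{row.Index}\t0\t{getattr(row, 'strand', '+')}\n"
            )


def read_circ_bed(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            chrom, start0, end = f[0], int(f[1]), int(f[2])
            start = start0 + 1
            cid = f[3] if len(f) > 3 else format_circ_id(chrom, start, end)
            rows.append(
                {"circ_id": cid, "chrom": chrom, "start": start, "end": end,
                 "strand": f[5] if len(f) > 5 else "+"}
            )
    return pd.DataFrame(rows).set_index("circ_id")


def write_annotation(annotation: Annotation, gene_path, exon_path) -> None:
    g = annotation.genes.copy()
    g["start"] -= 1  # BED-style on disk
    g.to_csv(gene_path, sep="\t", index=False)
    e = annotation.exons.copy()
    e["start"] -= 1
    e.to_csv(exon_path, sep="\t", index=False)


def read_annotation(gene_path, exon_path) -> Annotation:
    g = pd.read_csv(gene_path, sep="\t")
    g["start"] += 1
    e = pd.read_csv(exon_path, sep="\t")
    e["start"] += 1
    return Annotation(genes=g, exons=e)


def write_genotypes_tsv(genotypes: GenotypeMatrix, dosage_path, snp_path) -> None:
    write_matrix(genotypes.dosages, dosage_path)
    genotypes.snps.to_csv(snp_path, sep="\t", float_format="%.10g")


def read_genotypes_tsv(dosage_path, snp_path) -> GenotypeMatrix:
    dos = read_matrix(dosage_path)
    snps = pd.read_csv(snp_path, sep="\t", index_col=0)
    return GenotypeMatrix(dosages=dos, snps=snps)


def write_genotypes_vcf(genotypes: GenotypeMatrix, path) -> None:
    """Minimal VCF with a DS (dosage) FORMAT field plus MAF/IQ INFO tags."""
    samples = list(genotypes.sample_ids)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=MAF,Number=1,Type=Float,Description="Minor allele frequency">\n')
        fh.write('##INFO=<ID=IQ,Number=1,Type=Float,Description="Imputation quality">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Genotype dosage">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for snp_id, meta in genotypes.snps.iterrows():
            ds = genotypes.dosages.loc[snp_id]
            fields = [
                str(meta["chrom"]), str(int(meta["pos"])), str(snp_id), "A", "G", ".", "PASS",
                f"MAF={meta['maf']:.6g};IQ={meta['qual']:.6g}", "DS",
            ] + [f"{v:.6g}" for v in ds]
            fh.write("\t".join(fields) + "\n")


def read_genotypes_vcf(path) -> GenotypeMatrix:
    """Read dosages from the DS FORMAT field of a (plain-text) VCF."""
    samples, rows, meta = None, [], []
    with open(path) as fh:
        for line in fh:
            if line.startswith("##"):
                continue
            f = line.rstrip("\n").split("\t")
            if line.startswith("#CHROM"):
                samples = f[9:]
                continue
            info = dict(kv.split("=", 1) for kv in f[7].split(";") if "=" in kv)
            fmt = f[8].split(":")
            ds_idx = fmt.index("DS")
            ds = [float(v.split(":")[ds_idx]) for v in f[9:]]
            rows.append(ds)
            meta.append(
                {"snp_id": f[2], "chrom": f[0], "pos": int(f[1]),
                 "maf": float(info.get("MAF", "nan")), "qual": float(info.get("IQ", "nan"))}
            )
    snps = pd.DataFrame(meta).set_index("snp_id")
    dosages = pd.DataFrame(np.asarray(rows), index=snps.index, columns=samples)
    return GenotypeMatrix(dosages=dosages, snps=snps)


def write_fasta(seqs: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_intron_fasta(introns: dict[str, tuple[str, str]], path) -> None:
    """Flanking-intron pairs keyed ``<circ_id>|up`` and ``<circ_id>|down``."""
    flat = {}
    for cid, (a, b) in introns.items():
        flat[f"{cid}|up"] = a
        flat[f"{cid}|down"] = b
    write_fasta(flat, path)


def read_intron_fasta(path) -> dict[str, tuple[str, str]]:
    flat = read_fasta(path)
    out: dict[str, list] = {}
    for name, seq in flat.items():
        cid, side = name.rsplit("|", 1)
        out.setdefault(cid, [None, None])[0 if side == "up" else 1] = seq
    return {k: (a, b) for k, (a, b) in out.items() if a is not None and b is not None}
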