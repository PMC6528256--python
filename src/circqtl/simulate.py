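"""Synthetic data generator for the circQTL pipeline.

Emulates the statistical structure the analysis assumes: genotype dosages in
Hardy-Weinberg equilibrium with haplotype-copying LD blocks and common
alleles (MAF >= 0.05), negative-binomial circular/linear junction counts with
planted additive genotype effects on circular ratio or abundance, covariate
and batch effects on the log-mean scale, canonical-splice-disruption SNPs,
reverse-complement repeats planted in flanking introns, and GWAS index SNPs
in high LD with planted circQTL SNPs. A truth table records every planted
effect and is the ground truth for recovery tests.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .core import Annotation, GenotypeMatrix, JunctionCounts, format_circ_id

DNA = np.array(list("ACGT"))
_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class PlantedEffect:
    """One planted genotype effect on one circRNA.

    ``ratio_shift`` shifts the logit circular fraction by ``beta`` per
    dosage unit (a splicing-level effect); ``abundance_shift`` multiplies
    both circular and linear junction means by 2**(beta*dosage) (a host-gene
    expression effect); ``splice_disruption`` multiplies only the circular
    mean by 2**(beta*dosage), beta < 0, mimicking a SNP breaking a canonical
    back-splice site.
    """

    circ_id: str
    snp_id: str
    mode: str  # ratio_shift | abundance_shift | splice_disruption
    beta: float

    def __post_init__(self) -> None:
        if self.mode not in ("ratio_shift", "abundance_shift", "splice_disruption"):
            raise ValueError(f"unknown effect mode {self.mode!r}")


@dataclass(frozen=True)
class CovariateSpec:
    """Batch/age/sex/diagnosis effects on log2 junction abundance.

    Each circRNA is affected by a covariate with probability
    ``affected_frac``; affected circRNAs draw a coefficient of the given
    scale (sd for the batch levels, fixed slope magnitude otherwise).
    """

    n_batches: int = 3
    batch_sd: float = 0.5
    age_beta: float = 0.01  # log2 units per year
    sex_beta: float = 0.3
    diagnosis_beta: float = 0.0
    affected_frac: float = 0.3


@dataclass(frozen=True)
class SimulationConfig:
    n_samples: int = 100
    n_snps: int = 1000
    n_circ: int = 100
    ld_block_size: int = 10
    ld_rho: float = 0.9
    maf_range: tuple[float, float] = (0.05, 0.5)
    nb_dispersion: float = 0.15
    depth_range: tuple[int, int] = (100_000, 200_000)
    planted_effects: Optional[tuple[PlantedEffect, ...]] = None
    # auto-planting counts used when planted_effects is None
    n_ratio_qtl: int = 5
    n_abundance_qtl: int = 5
    n_splice_qtl: int = 2
    ratio_beta: float = 1.5
    abundance_beta: float = 1.0
    splice_beta: float = -2.0
    covariate_spec: CovariateSpec = field(default_factory=CovariateSpec)
    # flanking-intron / RCS parameters
    intron_len: int = 800
    rcs_len: int = 100
    rcs_frac: float = 0.3
    # GWAS table parameters
    n_gwas_linked: int = 5
    n_gwas_background: int = 5
    n_gwas_decoys: int = 3
    gwas_flip_prob: float = 0.01
    snp_spacing: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_samples", "n_snps", "n_circ", "ld_block_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        lo, hi = self.maf_range
        if not (0.05 <= lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within [0.05, 0.5]")
        if not (0 <= self.ld_rho < 1):
            raise ValueError("ld_rho must be in [0, 1)")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if self.depth_range[0] <= 0 or self.depth_range[1] < self.depth_range[0]:
            raise ValueError("invalid depth_range")


@dataclass
class TruthTable:
    """Ledger of everything the simulator planted."""

    effects: pd.DataFrame  # circ_id, snp_id, mode, beta
    rcs: pd.DataFrame  # circ_id, a_start, a_end, b_start, b_end, length
    gwas_links: pd.DataFrame  # index_snp, qtl_snp, trait, realized_r2

    def __post_init__(self) -> None:
        if len(self.effects):
            dup = self.effects.duplicated(["circ_id", "snp_id", "mode"])
            if dup.any():
                raise ValueError("duplicate planted effect for a (circ, snp, mode)")


def simulate_genotypes(config: SimulationConfig, rng: Optional[np.random.Generator] = None) -> GenotypeMatrix:
    """Dosages as the sum of two haplotypes built per LD block.

    Within a block, each haplotype copies the previous SNP's allele with
    probability ``ld_rho`` and otherwise draws fresh at the SNP's allele
    frequency; blocks are independent. Monomorphic or near-monomorphic SNPs
    (realized MAF < 0.01) are redrawn. Positions are strictly increasing on
    one synthetic chromosome.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n, m = config.n_samples, config.n_snps
    lo, hi = config.maf_range
    freqs = rng.uniform(lo, hi, size=m)
    hap = np.zeros((2, m, n), dtype=np.int8)
    for j in range(m):
        fresh = rng.random((2, n)) < freqs[j]
        if j % config.ld_block_size == 0:
            hap[:, j, :] = fresh
        else:
            copy = rng.random((2, n)) < config.ld_rho
            hap[:, j, :] = np.where(copy, hap[:, j - 1, :], fresh)
    # redraw SNPs whose realized MAF fell below 1%
    for j in range(m):
        for _ in range(100):
            f_hat = hap[:, j, :].mean()
            if 0.01 <= f_hat <= 0.99:
                break
            hap[:, j, :] = rng.random((2, n)) < freqs[j]
        else:  # pragma: no cover - requires pathological maf_range
            raise RuntimeError("could not realize a polymorphic SNP")
    dosage = hap.sum(axis=0).astype(float)
    f_hat = dosage.mean(axis=1) / 2
    maf = np.minimum(f_hat, 1 - f_hat)
    snp_ids = pd.Index([f"snp{j:05d}" for j in range(m)], name="snp_id")
    pos = config.snp_spacing * (np.arange(m) + 1)
    snps = pd.DataFrame(
        {"chrom": "chr1", "pos": pos, "maf": maf, "qual": 1.0}, index=snp_ids
    )
    samples = pd.Index([f"S{i:04d}" for i in range(n)], name="sample_id")
    dosages = pd.DataFrame(dosage, index=snp_ids, columns=samples)
    return GenotypeMatrix(dosages=dosages, snps=snps, haplotypes=hap)


def simulate_annotation(config: SimulationConfig, rng: np.random.Generator):
    """Place circRNAs and a minimal host-gene annotation along the chromosome.

    Roughly 80% of circRNAs are exonic (back-splice sites at exon
    boundaries), 10% intronic and 10% intergenic, echoing the class mix seen
    in brain data. Spacing guarantees every circRNA has at least 20 cis SNPs
    within the +/-100 kb window.
    """
    genome_len = config.snp_spacing * (config.n_snps + 1)
    spacing = genome_len // (config.n_circ + 1)
    circ_rows, gene_rows, exon_rows = [], [], []
    classes = []
    for i in range(config.n_circ):
        u = i / max(config.n_circ - 1, 1)
        classes.append("exonic" if u < 0.8 else ("intronic" if u < 0.9 else "intergenic"))
    rng.shuffle(classes)
    for i, cls in enumerate(classes):
        anchor = spacing * (i + 1)
        span_hi = min(3000, spacing - 3200)
        if span_hi <= 600:  # tight layouts (few SNPs per circ) use short spans
            span_hi = max(201, spacing // 4)
        span = int(rng.integers(min(600, span_hi - 1), span_hi))
        start, end = anchor, anchor + span
        cid = format_circ_id("chr1", start, end)
        circ_rows.append({"circ_id": cid, "chrom": "chr1", "start": start, "end": end, "strand": "+"})
        gid = f"gene{i:04d}"
        if cls == "exonic":
            gene_rows.append({"gene_id": gid, "chrom": "chr1", "start": start - 1500, "end": end + 1500, "strand": "+"})
            exon_len = min(200, span // 3)
            exon_rows += [
                {"gene_id": gid, "chrom": "chr1", "start": start - 1500, "end": start - 1301},
                {"gene_id": gid, "chrom": "chr1", "start": start, "end": start + exon_len - 1},
                {"gene_id": gid, "chrom": "chr1", "start": end - exon_len + 1, "end": end},
                {"gene_id": gid, "chrom": "chr1", "start": end + 1301, "end": end + 1500},
            ]
        elif cls == "intronic":
            gene_rows.append({"gene_id": gid, "chrom": "chr1", "start": start - 1500, "end": end + 1500, "strand": "+"})
            exon_rows += [
                {"gene_id": gid, "chrom": "chr1", "start": start - 1500, "end": start - 1301},
                {"gene_id": gid, "chrom": "chr1", "start": end + 1301, "end": end + 1500},
            ]
        # intergenic: no gene
        circ_rows[-1]["sim_class"] = cls
    circs = pd.DataFrame(circ_rows).set_index("circ_id")
    genes = pd.DataFrame(gene_rows, columns=["gene_id", "chrom", "start", "end", "strand"])
    exons = pd.DataFrame(exon_rows, columns=["gene_id", "chrom", "start", "end"])
    annotation = Annotation(genes=genes, exons=exons)
    return circs, annotation


def _cis_snps(circs: pd.DataFrame, genotypes: GenotypeMatrix, window: int = 100_000) -> dict[str, pd.Index]:
    pos = genotypes.snps["pos"].values
    out = {}
    for row in circs.itertuples():
        mask = (pos >= row.start - window) & (pos <= row.end + window)
        out[row.Index] = genotypes.snp_ids[mask]
    return out


def plan_effects(config: SimulationConfig, circs: pd.DataFrame, genotypes: GenotypeMatrix,
                 rng: np.random.Generator) -> tuple[PlantedEffect, ...]:
    """Choose (circ, cis SNP) pairs for planting when none were supplied.

    Ratio and splice effects go to exonic circRNAs (the ratio rescan covers
    exonic and intronic loci); each circRNA carries at most one effect. The
    SNP is a common cis SNP (MAF >= 0.2) near the locus for power.
    """
    cis = _cis_snps(circs, genotypes)
    maf = genotypes.snps["maf"]
    rng_order = list(circs.index)
    rng.shuffle(rng_order)
    classes = circs["sim_class"] if "sim_class" in circs.columns else pd.Series("exonic", index=circs.index)
    wanted = (
        [("ratio_shift", config.ratio_beta)] * config.n_ratio_qtl
        + [("abundance_shift", config.abundance_beta)] * config.n_abundance_qtl
        + [("splice_disruption", config.splice_beta)] * config.n_splice_qtl
    )
    effects = []
    used = set()
    for mode, beta in wanted:
        for cid in rng_order:
            if cid in used:
                continue
            if mode in ("ratio_shift", "splice_disruption") and classes[cid] == "intergenic":
                continue  # the ratio rescan covers exonic and intronic loci only
            snp_pool = [s for s in cis[cid] if maf[s] >= 0.2]
            if not snp_pool:
                continue
            # prefer the SNP closest to the locus midpoint
            mid = (circs.loc[cid, "start"] + circs.loc[cid, "end"]) / 2
            snp = min(snp_pool, key=lambda s: abs(genotypes.snps.loc[s, "pos"] - mid))
            effects.append(PlantedEffect(circ_id=cid, snp_id=snp, mode=mode, beta=beta))
            used.add(cid)
            break
        else:
            raise ValueError(f"could not place a {mode} effect: no eligible circRNA/SNP left")
    return tuple(effects)


def simulate_junction_counts(
    genotypes: GenotypeMatrix,
    config: SimulationConfig,
    circs: pd.DataFrame,
    rng: np.random.Generator,
    effects: Optional[tuple[PlantedEffect, ...]] = None,
) -> tuple[JunctionCounts, pd.DataFrame, pd.DataFrame]:
    """Negative-binomial C/L junction counts with planted effects.

    For each circRNA and sample the expected circular fraction is
    p = inv_logit(logit(p0) + beta*dosage) under a ratio_shift effect; the
    total junction mean is the sample depth times the circRNA's abundance
    share. abundance_shift scales both C and L means by 2**(beta*dosage);
    splice_disruption scales only C's mean. Covariate effects act on the
    log2 total-mean scale. Returns (counts, covariate table, effects table).
    """
    if effects is None:
        effects = config.planted_effects or ()
    n = config.n_samples
    samples = genotypes.sample_ids
    if len(samples) != n:
        raise ValueError("genotypes not aligned with configured sample count")
    spec = config.covariate_spec
    batch = rng.integers(0, spec.n_batches, size=n)
    age = rng.uniform(20, 90, size=n)
    sex = rng.integers(0, 2, size=n)
    dx = rng.integers(0, 2, size=n)
    covariates = pd.DataFrame(
        {"LIB": [f"batch{b}" for b in batch], "AOD": age, "gender": sex, "diagnosis": dx},
        index=samples,
    )

    n_circ = len(circs)
    p0 = rng.uniform(0.08, 0.5, size=n_circ)
    share = rng.lognormal(mean=0.0, sigma=1.0, size=n_circ)
    share /= share.sum()
    depth = rng.integers(config.depth_range[0], config.depth_range[1] + 1, size=n)

    # baseline total-junction mean per circ x sample
    M = np.outer(share, depth.astype(float))

    # covariate effects on log2 total mean
    log2_shift = np.zeros((n_circ, n))
    affected = rng.random((n_circ, 4)) < spec.affected_frac
    batch_coef = rng.normal(0, spec.batch_sd, size=(n_circ, spec.n_batches))
    age_c = age - age.mean()
    for i in range(n_circ):
        if affected[i, 0]:
            log2_shift[i] += batch_coef[i, batch]
        if affected[i, 1]:
            log2_shift[i] += rng.choice([-1, 1]) * spec.age_beta * age_c
        if affected[i, 2] and spec.sex_beta:
            log2_shift[i] += rng.choice([-1, 1]) * spec.sex_beta * (sex - 0.5)
        if affected[i, 3] and spec.diagnosis_beta:
            log2_shift[i] += rng.choice([-1, 1]) * spec.diagnosis_beta * (dx - 0.5)
    M = M * 2.0 ** log2_shift

    logit_p = np.log(p0 / (1 - p0))[:, None] * np.ones((1, n))
    c_scale = np.ones((n_circ, n))
    circ_index = {c: i for i, c in enumerate(circs.index)}
    eff_rows = []
    for e in effects:
        if e.circ_id not in circ_index:
            raise ValueError(f"planted effect references unknown circRNA {e.circ_id!r}")
        if e.snp_id not in genotypes.snp_ids:
            raise ValueError(f"planted effect references unknown SNP {e.snp_id!r}")
        i = circ_index[e.circ_id]
        dos = genotypes.dosages.loc[e.snp_id].values
        if e.mode == "ratio_shift":
            logit_p[i] = logit_p[i] + e.beta * dos
        elif e.mode == "abundance_shift":
            M[i] = M[i] * 2.0 ** (e.beta * dos)
        else:  # splice_disruption
            c_scale[i] = c_scale[i] * 2.0 ** (e.beta * dos)
        eff_rows.append({"circ_id": e.circ_id, "snp_id": e.snp_id, "mode": e.mode, "beta": e.beta})
    p = 1.0 / (1.0 + np.exp(-logit_p))

    mu_c = M * p * c_scale
    mu_l = M * (1 - p)
    C = _nb_draw(mu_c, config.nb_dispersion, rng)
    L = _nb_draw(mu_l, config.nb_dispersion, rng)
    counts = JunctionCounts(
        C=pd.DataFrame(C, index=circs.index, columns=samples),
        L=pd.DataFrame(L, index=circs.index, columns=samples),
    )
    effects_df = pd.DataFrame(eff_rows, columns=["circ_id", "snp_id", "mode", "beta"])
    return counts, covariates, effects_df


def _nb_draw(mu: np.ndarray, dispersion: float, rng: np.random.Generator) -> np.ndarray:
    """Negative binomial with mean mu and variance mu + dispersion*mu**2
    via the gamma-Poisson mixture; Poisson when dispersion is 0."""
    mu = np.maximum(mu, 1e-12)
    if dispersion <= 0:
        return rng.poisson(mu)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mu * dispersion)
    return rng.poisson(lam)


def plant_rcs(intron_len: int, rcs_len: int, rng: np.random.Generator):
    """Two random intron sequences where a segment of intron B is the exact
    reverse complement of a segment of intron A; rcs_len=0 plants nothing.

    Returns (seq_a, seq_b, truth) with truth = None or a dict of 0-based
    half-open intervals on both introns.
    """
    if rcs_len >= intron_len:
        raise ValueError("rcs_len must be smaller than intron_len")
    seq_a = "".join(rng.choice(DNA, size=intron_len))
    seq_b = "".join(rng.choice(DNA, size=intron_len))
    if rcs_len == 0:
        return seq_a, seq_b, None
    a_start = int(rng.integers(0, intron_len - rcs_len + 1))
    b_start = int(rng.integers(0, intron_len - rcs_len + 1))
    segment = seq_a[a_start : a_start + rcs_len]
    seq_b = seq_b[:b_start] + revcomp(segment) + seq_b[b_start + rcs_len :]
    truth = {
        "a_start": a_start,
        "a_end": a_start + rcs_len,
        "b_start": b_start,
        "b_end": b_start + rcs_len,
        "length": rcs_len,
    }
    return seq_a, seq_b, truth


def simulate_flanking_introns(
    config: SimulationConfig, circs: pd.DataFrame, rng: np.random.Generator
) -> tuple[dict[str, tuple[str, str]], pd.DataFrame]:
    """Flanking-intron FASTA pairs per circRNA; a fraction carries a planted
    reverse-complement repeat. Returns ({circ_id: (upstream, downstream)},
    rcs truth table)."""
    introns: dict[str, tuple[str, str]] = {}
    rows = []
    for cid in circs.index:
        planted = rng.random() < config.rcs_frac and config.rcs_len > 0
        rcs_len = config.rcs_len if planted else 0
        a, b, truth = plant_rcs(config.intron_len, rcs_len, rng)
        introns[cid] = (a, b)
        if truth is not None:
            rows.append({"circ_id": cid, **truth})
    truth_df = pd.DataFrame(rows, columns=["circ_id", "a_start", "a_end", "b_start", "b_end", "length"])
    return introns, truth_df


def simulate_gwas_table(
    genotypes: GenotypeMatrix,
    effects_df: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, GenotypeMatrix, pd.DataFrame]:
    """GWAS-catalog-style table with planted index SNPs.

    Linked index SNPs are synthesized as near-copies of planted circQTL SNP
    haplotypes (per-allele flip probability ``gwas_flip_prob``, giving
    r^2 around 0.95) and appended to the genotype panel; background index
    SNPs are drawn from non-effect panel SNPs; decoy rows sit above the
    genome-wide threshold (P = 1e-6) and must be filtered out downstream.
    Returns (gwas table, augmented genotypes, link truth table).
    """
    hap = genotypes.haplotypes
    effect_snps = list(dict.fromkeys(effects_df["snp_id"])) if len(effects_df) else []
    linked = effect_snps[: config.n_gwas_linked]
    if hap is None and linked:
        raise ValueError("haplotypes required to synthesize linked index SNPs")
    snp_pos = genotypes.snps["pos"]
    new_haps, new_rows, gwas_rows, link_rows = [], [], [], []
    for k, qtl_snp in enumerate(linked):
        j = genotypes.snp_ids.get_loc(qtl_snp)
        h = hap[:, j, :].copy()
        flip = rng.random(h.shape) < config.gwas_flip_prob
        h = np.where(flip, 1 - h, h)
        dos = h.sum(axis=0).astype(float)
        if dos.std() == 0:  # pragma: no cover - vanishing probability
            dos[0] = max(0.0, dos[0] - 1)
        gid = f"gwsnp{k:04d}"
        pos = int(snp_pos.loc[qtl_snp]) + 17 + k
        r = np.corrcoef(dos, genotypes.dosages.loc[qtl_snp].values)[0, 1]
        new_haps.append(h)
        f_hat = dos.mean() / 2
        new_rows.append({"snp_id": gid, "chrom": "chr1", "pos": pos, "maf": min(f_hat, 1 - f_hat), "qual": 1.0})
        gwas_rows.append({"SNPS": gid, "CHR_ID": "chr1", "CHR_POS": pos, "DISEASE/TRAIT": "schizophrenia", "P-VALUE": 1e-12})
        link_rows.append({"index_snp": gid, "qtl_snp": qtl_snp, "trait": "schizophrenia", "realized_r2": r * r, "dosage": dos})
    # background index SNPs: panel SNPs carrying no planted effect
    pool = [s for s in genotypes.snp_ids if s not in set(effect_snps)]
    background = list(rng.choice(pool, size=min(config.n_gwas_background, len(pool)), replace=False))
    for s in background:
        gwas_rows.append(
            {"SNPS": s, "CHR_ID": "chr1", "CHR_POS": int(snp_pos.loc[s]), "DISEASE/TRAIT": "coronary artery disease", "P-VALUE": 1e-10}
        )
    decoy_pool = [s for s in pool if s not in set(background)]
    for s in rng.choice(decoy_pool, size=min(config.n_gwas_decoys, len(decoy_pool)), replace=False):
        gwas_rows.append(
            {"SNPS": s, "CHR_ID": "chr1", "CHR_POS": int(snp_pos.loc[s]), "DISEASE/TRAIT": "schizophrenia", "P-VALUE": 1e-6}
        )
    gwas = pd.DataFrame(gwas_rows, columns=["SNPS", "CHR_ID", "CHR_POS", "DISEASE/TRAIT", "P-VALUE"])
    links = pd.DataFrame(link_rows, columns=["index_snp", "qtl_snp", "trait", "realized_r2", "dosage"])
    if not new_rows:
        return gwas, genotypes, links.drop(columns=["dosage"], errors="ignore")
    add_snps = pd.DataFrame(new_rows).set_index("snp_id")
    add_dos = pd.DataFrame(
        np.stack([r["dosage"] for r in link_rows]), index=add_snps.index, columns=genotypes.sample_ids
    )
    snps = pd.concat([genotypes.snps, add_snps])
    dosages = pd.concat([genotypes.dosages, add_dos])
    order = snps["pos"].argsort(kind="stable").values
    hap_all = np.concatenate([hap, np.stack(new_haps, axis=1)], axis=1)[:, order, :]
    augmented = GenotypeMatrix(dosages=dosages.iloc[order], snps=snps.iloc[order], haplotypes=hap_all)
    return gwas, augmented, links.drop(columns=["dosage"])


def annotate_snps(
    genotypes: GenotypeMatrix,
    annotation: Annotation,
    circs: pd.DataFrame,
    effects_df: pd.DataFrame,
    rcs_truth: pd.DataFrame,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """VEP-style element category per SNP plus RCS and back-splice flags.

    Position-driven: SNPs outside genes are intergenic (with some up/downstream
    near gene edges), inside exons they draw a coding-ish category, otherwise
    intron. splice_disruption SNPs are relabelled canonical splice site with
    the back-splice flag set. Intronic SNPs within the flanking-intron span of
    an RCS-carrying circRNA get the in_RCS flag.
    """
    cats, in_rcs, at_bs = [], [], []
    exonic_cats = np.array(["missense", "synonymous", "5' UTR", "3' UTR", "noncoding transcript exon", "splice region"])
    exonic_p = np.array([0.3, 0.3, 0.1, 0.1, 0.15, 0.05])
    rcs_circs = set(rcs_truth["circ_id"]) if len(rcs_truth) else set()
    rcs_spans = [
        (circs.loc[c, "start"] - 1500, circs.loc[c, "end"] + 1500)
        for c in rcs_circs
        if c in circs.index
    ]
    for snp_id, row in genotypes.snps.iterrows():
        pos = row["pos"]
        genes = annotation.genes_at(row["chrom"], pos)
        if len(genes) == 0:
            near = annotation.genes[
                (annotation.genes["chrom"] == row["chrom"])
                & (annotation.genes["start"] - 5000 <= pos)
                & (annotation.genes["end"] + 5000 >= pos)
            ]
            if len(near) == 0:
                cats.append("intergenic")
            else:
                cats.append("upstream gene" if pos < near["start"].iloc[0] else "downstream gene")
        elif len(annotation.exons_at(row["chrom"], pos)) > 0:
            cats.append(str(rng.choice(exonic_cats, p=exonic_p)))
        else:
            cats.append("intron")
        in_rcs.append(any(s <= pos <= e for s, e in rcs_spans) and cats[-1] == "intron")
        at_bs.append(False)
    out = pd.DataFrame(
        {"category": cats, "in_RCS": in_rcs, "at_backsplice_site": at_bs},
        index=genotypes.snp_ids,
    )
    splice = effects_df[effects_df["mode"] == "splice_disruption"]["snp_id"]
    for s in splice:
        if s in out.index:
            out.loc[s, "category"] = "canonical splice site"
            out.loc[s, "at_backsplice_site"] = True
    return out


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    genotypes: GenotypeMatrix
    counts: JunctionCounts
    covariates: pd.DataFrame
    circs: pd.DataFrame
    annotation: Annotation
    snp_annotations: pd.DataFrame
    introns: dict[str, tuple[str, str]]
    gwas: pd.DataFrame
    truth: TruthTable


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Run the full generator: genotypes, loci, counts, introns, GWAS, truth."""
    rng = np.random.default_rng(config.seed)
    genotypes = simulate_genotypes(config, rng)
    circs, annotation = simulate_annotation(config, rng)
    effects = config.planted_effects
    if effects is None:
        effects = plan_effects(config, circs, genotypes, rng)
    counts, covariates, effects_df = simulate_junction_counts(
        genotypes, config, circs, rng, effects
    )
    introns, rcs_truth = simulate_flanking_introns(config, circs, rng)
    gwas, genotypes, gwas_links = simulate_gwas_table(genotypes, effects_df, config, rng)
    snp_annotations = annotate_snps(genotypes, annotation, circs, effects_df, rcs_truth, rng)
    truth = TruthTable(effects=effects_df, rcs=rcs_truth, gwas_links=gwas_links)
    return SimulatedDataset(
        config=config,
        genotypes=genotypes,
        counts=counts,
        covariates=covariates,
        circs=circs,
        annotation=annotation,
        snp_annotations=snp_annotations,
        introns=introns,
        gwas=gwas,
        truth=truth,
    )
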