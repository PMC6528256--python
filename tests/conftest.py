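import numpy as np
import pandas as pd
import pytest

from circqtl.core import Annotation, GenotypeMatrix, JunctionCounts
from circqtl.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def toy_annotation() -> Annotation:
    """One gene on chr1 (1000-5000) with exons at 1000-1199, 2000-2299
    and 3000-3199, plus a second gene on chr2."""
    genes = pd.DataFrame(
        [
            {"gene_id": "g1", "chrom": "chr1", "start": 1000, "end": 5000, "strand": "+"},
            {"gene_id": "g2", "chrom": "chr2", "start": 100, "end": 900, "strand": "-"},
        ]
    )
    exons = pd.DataFrame(
        [
            {"gene_id": "g1", "chrom": "chr1", "start": 1000, "end": 1199},
            {"gene_id": "g1", "chrom": "chr1", "start": 2000, "end": 2299},
            {"gene_id": "g1", "chrom": "chr1", "start": 3000, "end": 3199},
            {"gene_id": "g2", "chrom": "chr2", "start": 100, "end": 300},
        ]
    )
    return Annotation(genes=genes, exons=exons)


def make_counts(C_rows, L_rows, feature_ids=None) -> JunctionCounts:
    C = np.atleast_2d(np.asarray(C_rows))
    L = np.atleast_2d(np.asarray(L_rows))
    features = feature_ids or [f"f{i}" for i in range(C.shape[0])]
    samples = [f"s{j}" for j in range(C.shape[1])]
    return JunctionCounts(
        C=pd.DataFrame(C, index=features, columns=samples),
        L=pd.DataFrame(L, index=features, columns=samples),
    )


def make_genotypes(dosage_rows, pos=None, maf=None, chrom="chr1") -> GenotypeMatrix:
    D = np.atleast_2d(np.asarray(dosage_rows, dtype=float))
    m, n = D.shape
    snp_ids = pd.Index([f"snp{j}" for j in range(m)], name="snp_id")
    if pos is None:
        pos = 100 * (np.arange(m) + 1)
    if maf is None:
        f = D.mean(axis=1) / 2
        maf = np.minimum(f, 1 - f)
    snps = pd.DataFrame({"chrom": chrom, "pos": pos, "maf": maf, "qual": 1.0}, index=snp_ids)
    dosages = pd.DataFrame(D, index=snp_ids, columns=[f"s{j}" for j in range(n)])
    return GenotypeMatrix(dosages=dosages, snps=snps)


@pytest.fixture(scope="session")
def small_dataset():
    """A small simulated dataset with planted effects, shared across tests."""
    cfg = SimulationConfig(
        n_samples=120,
        n_snps=400,
        n_circ=40,
        n_ratio_qtl=3,
        n_abundance_qtl=3,
        n_splice_qtl=1,
        n_gwas_linked=3,
        n_gwas_background=3,
        seed=11,
    )
    return simulate_dataset(cfg)
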