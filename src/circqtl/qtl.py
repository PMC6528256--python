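"""cis-circQTL mapping with a permutation empirical-P / q-value procedure.

SNPs within 100 kb of either back-splice site are tested against
covariate-adjusted expression under an additive dosage model. Per-circRNA
multiple testing over correlated cis SNPs is corrected by permuting sample
labels of the expression matrix: the minimum P over a circRNA's cis SNPs is
collected per permutation, the observed minimum P is ranked within that
null (add-one smoothing), and Storey q-values over the per-circRNA
empirical P values control the FDR. A per-circRNA nominal-P threshold
(the empirical quantile of its own permutation minima at the q = 0.05
empirical-P cutoff) calls all significant cis SNPs, and a dual-quantification
concordance filter (circCPM scan vs circular-ratio scan) removes pairs
whose association reflects host-gene expression rather than circularization.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import GenotypeMatrix

CIS_WINDOW = 100_000
AUTOSOMES = {f"chr{i}" for i in range(1, 23)} | {str(i) for i in range(1, 23)}


def cis_pairs(
    circs: pd.DataFrame, genotypes: GenotypeMatrix, window: int = CIS_WINDOW
) -> pd.DataFrame:
    """All (circRNA, SNP) pairs with the SNP inside the closed interval
    [start - window, end + window] on the circRNA's chromosome.

    Only autosomal SNPs are paired. Returns a DataFrame with columns
    circ_id, snp_id.
    """
    snp_chrom = genotypes.snps["chrom"].values
    snp_pos = genotypes.snps["pos"].values
    auto = np.isin(snp_chrom, list(AUTOSOMES))
    rows = []
    for row in circs.itertuples():
        mask = (
            auto
            & (snp_chrom == row.chrom)
            & (snp_pos >= row.start - window)
            & (snp_pos <= row.end + window)
        )
        for s in genotypes.snp_ids[mask]:
            rows.append((row.Index, s))
    return pd.DataFrame(rows, columns=["circ_id", "snp_id"])


def _residualize(Y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Project rows of Y off the column space of X (OLS residuals)."""
    beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
    return Y - (X @ beta).T


@dataclass
class _ScanArrays:
    """Standardized arrays prepared once for the observed scan and all
    permutations."""

    circ_ids: list
    snp_ids: list
    E: np.ndarray  # circ x sample, row-standardized
    G: np.ndarray  # snp x sample, row-standardized
    mask: np.ndarray  # circ x snp cis-pair indicator
    e_sd: np.ndarray
    g_sd: np.ndarray
    df: int


def _prepare(
    expr: pd.DataFrame,
    genotypes: GenotypeMatrix,
    pairs: pd.DataFrame,
    design: pd.DataFrame | None,
) -> _ScanArrays:
    if not expr.columns.equals(genotypes.sample_ids):
        if set(expr.columns) != set(genotypes.sample_ids):
            raise ValueError("expression and genotype samples do not match")
        genotypes = GenotypeMatrix(
            genotypes.dosages[expr.columns], genotypes.snps, genotypes.haplotypes
        )
    n = expr.shape[1]
    circ_ids = [c for c in expr.index if c in set(pairs["circ_id"])]
    snp_ids = [s for s in genotypes.snp_ids if s in set(pairs["snp_id"])]
    E = expr.loc[circ_ids].values.astype(float)
    G = genotypes.dosages.loc[snp_ids].values.astype(float)
    p_design = 0
    if design is not None:
        X = design.loc[expr.columns].values.astype(float)
        E = _residualize(E, X)
        G = _residualize(G, X)
        p_design = X.shape[1]
    E = E - E.mean(axis=1, keepdims=True)
    G = G - G.mean(axis=1, keepdims=True)
    e_sd = E.std(axis=1)
    g_sd = G.std(axis=1)
    poly = g_sd > 1e-12
    snp_ids = [s for s, ok in zip(snp_ids, poly) if ok]
    G, g_sd = G[poly], g_sd[poly]
    En = E / np.where(e_sd[:, None] > 1e-12, e_sd[:, None], 1.0) / math.sqrt(n)
    Gn = G / g_sd[:, None] / math.sqrt(n)
    ci = {c: i for i, c in enumerate(circ_ids)}
    si = {s: j for j, s in enumerate(snp_ids)}
    mask = np.zeros((len(circ_ids), len(snp_ids)), dtype=bool)
    for c, s in zip(pairs["circ_id"], pairs["snp_id"]):
        if c in ci and s in si:
            mask[ci[c], si[s]] = True
    df = n - 2 - (p_design - 1 if p_design else 0)
    return _ScanArrays(circ_ids, snp_ids, En, Gn, mask, e_sd, g_sd, df)


def _r_to_p(r: np.ndarray, df: int) -> np.ndarray:
    r = np.clip(r, -1 + 1e-15, 1 - 1e-15)
    t = r * np.sqrt(df / (1 - r ** 2))
    return 2 * stats.t.sf(np.abs(t), df)


def marginal_scan(
    expr: pd.DataFrame,
    genotypes: GenotypeMatrix,
    pairs: pd.DataFrame,
    design: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Additive-dosage linear scan over cis pairs.

    With ``design`` (the circular-ratio route) covariates are included as
    co-regressors via Frisch-Waugh projection of both expression and dosage;
    without it the expression is taken as already covariate-adjusted.
    Monomorphic SNPs are dropped. Returns columns circ_id, snp_id, slope,
    t, p.
    """
    arr = _prepare(expr, genotypes, pairs, design)
    ci = {c: i for i, c in enumerate(arr.circ_ids)}
    si = {s: j for j, s in enumerate(arr.snp_ids)}
    rows = []
    R = arr.E @ arr.G.T  # correlations, circ x snp
    for c, s in zip(pairs["circ_id"], pairs["snp_id"]):
        if c not in ci or s not in si:
            continue
        i, j = ci[c], si[s]
        r = R[i, j]
        r = min(max(r, -1 + 1e-15), 1 - 1e-15)
        t = r * math.sqrt(arr.df / (1 - r * r))
        p = 2 * stats.t.sf(abs(t), arr.df)
        slope = r * arr.e_sd[i] / arr.g_sd[j]
        rows.append((c, s, slope, t, p))
    return pd.DataFrame(rows, columns=["circ_id", "snp_id", "slope", "t", "p"])


@dataclass
class PermutationResult:
    """Per-circRNA permutation minima: minP_n for n = 1..N."""

    minp: dict[str, np.ndarray]
    n_perm: int

    def __post_init__(self) -> None:
        for c, v in self.minp.items():
            if len(v) != self.n_perm:
                raise ValueError(f"minP vector for {c} has wrong length")


def permute_minp(
    expr: pd.DataFrame,
    genotypes: GenotypeMatrix,
    pairs: pd.DataFrame,
    n_perm: int,
    seed: int,
    design: pd.DataFrame | None = None,
    exhaustive: bool = False,
) -> PermutationResult:
    """Permutation null of per-circRNA minimum P.

    Each round applies one shared sample-label permutation to the expression
    matrix (genotypes fixed, preserving cross-feature correlation) and
    records, per circRNA, the minimum P over its cis SNPs. With
    ``exhaustive`` every distinct permutation of the sample labels is
    enumerated instead (small n only) and ``n_perm`` is ignored.
    """
    arr = _prepare(expr, genotypes, pairs, design)
    n = arr.E.shape[1]
    if exhaustive:
        from itertools import permutations as _perms

        perm_iter = [np.array(p) for p in _perms(range(n))]
        n_perm = len(perm_iter)
    else:
        if n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        rng = np.random.default_rng(seed)
        perm_iter = [rng.permutation(n) for _ in range(n_perm)]
    Gt = arr.G.T
    nonempty = arr.mask.any(axis=1)
    rmax = np.zeros((len(arr.circ_ids), n_perm))
    for k, idx in enumerate(perm_iter):
        R = arr.E[:, idx] @ Gt
        rmax[:, k] = np.where(arr.mask, np.abs(R), -1.0).max(axis=1, initial=-1.0)
    minp = {}
    for i, c in enumerate(arr.circ_ids):
        if nonempty[i]:
            minp[c] = _r_to_p(rmax[i], arr.df)
    return PermutationResult(minp=minp, n_perm=n_perm)


def empirical_p(p_obs: float, minp_n: np.ndarray) -> float:
    """Rank-based empirical P with add-one smoothing:
    (1 + #{n : minP_n < P_obs}) / (N + 1), strict inequality."""
    minp_n = np.asarray(minp_n, float)
    if minp_n.size == 0:
        raise ValueError("empty permutation distribution")
    return (1 + int((minp_n < p_obs).sum())) / (minp_n.size + 1)


@dataclass
class QValueResult:
    qvalues: pd.Series
    pi0: float


def storey_qvalues(pvalues: pd.Series | np.ndarray) -> QValueResult:
    """Storey q-values with the smoother estimate of pi0.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) over lambda in
    0.05..0.95 (step 0.05) is smoothed by a cubic fit and read off at the
    largest lambda, clamped to (0, 1]. With fewer than 10 features pi0 = 1
    (the BH limit). q_(i) = min_{j>=i} pi0 * m * p_(j) / j.
    """
    if isinstance(pvalues, pd.Series):
        index = pvalues.index
        p = pvalues.values.astype(float)
    else:
        p = np.asarray(pvalues, float)
        index = pd.RangeIndex(len(p))
    if p.size == 0:
        raise ValueError("no P values supplied")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("P values must lie in (0, 1]")
    m = p.size
    if m < 10:
        pi0 = 1.0
    else:
        lam = np.arange(0.05, 0.96, 0.05)
        pi0_lam = np.array([(p > l).sum() / (m * (1 - l)) for l in lam])
        coef = np.polyfit(lam, pi0_lam, 3)
        pi0 = float(np.polyval(coef, lam[-1]))
        pi0 = min(max(pi0, 1.0 / m), 1.0)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        prev = min(prev, pi0 * m * p[i] / rank)
        q[i] = prev
    return QValueResult(qvalues=pd.Series(q, index=index), pi0=pi0)


def per_feature_threshold(minp_n: np.ndarray, empp_star: float) -> float:
    """Nominal-P cutoff for one circRNA: the empP_star empirical quantile
    (inverse-CDF convention) of its own permutation minima."""
    minp_n = np.sort(np.asarray(minp_n, float))
    n = minp_n.size
    k = max(1, math.ceil(empp_star * n))
    return float(minp_n[min(k, n) - 1])


@dataclass
class ScanResult:
    """One quantification's full scan: nominal pairs, per-circ summary and
    the called circQTL pairs."""

    pairs: pd.DataFrame  # circ_id, snp_id, slope, t, p
    summary: pd.DataFrame  # index circ_id: min_p, emp_p, q, threshold, is_qtl_circ
    qtls: pd.DataFrame  # called pairs: circ_id, snp_id, slope, t, p
    quantification: str
    pi0: float


def call_circqtls(
    expr: pd.DataFrame,
    genotypes: GenotypeMatrix,
    pairs: pd.DataFrame,
    n_perm: int,
    seed: int,
    design: pd.DataFrame | None = None,
    q_cutoff: float = 0.05,
    quantification: str = "circCPM",
) -> ScanResult:
    """Run the full permutation procedure for one quantification.

    circRNAs with q < ``q_cutoff`` on their empirical P are
    circQTL-containing; the largest empirical P among them maps back, per
    circRNA, to a nominal-P threshold via the empirical quantile of its own
    permutation minima, and every cis SNP below that threshold is called.
    """
    nominal = marginal_scan(expr, genotypes, pairs, design=design)
    perm = permute_minp(expr, genotypes, pairs, n_perm, seed, design=design)
    circ_ids = [c for c in expr.index if c in perm.minp]
    obs_minp = nominal.groupby("circ_id")["p"].min()
    rows = []
    for c in circ_ids:
        p_obs = float(obs_minp.get(c, 1.0))
        rows.append((c, p_obs, empirical_p(p_obs, perm.minp[c])))
    summary = pd.DataFrame(rows, columns=["circ_id", "min_p", "emp_p"]).set_index("circ_id")
    qres = storey_qvalues(summary["emp_p"])
    summary["q"] = qres.qvalues
    summary["is_qtl_circ"] = summary["q"] < q_cutoff
    sig = summary[summary["is_qtl_circ"]]
    if len(sig):
        empp_star = float(sig["emp_p"].max())
    else:
        empp_star = np.nan
    thresholds = {}
    for c in summary.index:
        if summary.loc[c, "is_qtl_circ"]:
            thresholds[c] = per_feature_threshold(perm.minp[c], empp_star)
        else:
            thresholds[c] = np.nan
    summary["threshold"] = pd.Series(thresholds)
    thr = nominal["circ_id"].map(summary["threshold"])
    called = nominal[nominal["p"] < thr.fillna(-1.0)]
    return ScanResult(
        pairs=nominal,
        summary=summary,
        qtls=called.reset_index(drop=True),
        quantification=quantification,
        pi0=qres.pi0,
    )


def concordance_filter(
    qtls_cpm: pd.DataFrame,
    qtls_ratio: pd.DataFrame,
    circ_classes: pd.Series,
) -> pd.DataFrame:
    """Final circQTL set: pairs significant under both quantifications with
    the same slope sign, plus circCPM-significant pairs of intergenic
    circRNAs (which have no host gene and hence no informative ratio).
    """
    missing = set(qtls_cpm["circ_id"]) - set(circ_classes.index)
    if missing:
        raise ValueError(f"no class for circRNAs: {sorted(missing)[:5]}")
    key = ["circ_id", "snp_id"]
    merged = qtls_cpm.merge(qtls_ratio[key + ["slope"]], on=key, suffixes=("", "_ratio"))
    concordant = merged[np.sign(merged["slope"]) == np.sign(merged["slope_ratio"])]
    intergenic = qtls_cpm[qtls_cpm["circ_id"].map(circ_classes) == "intergenic"]
    final = pd.concat(
        [concordant.drop(columns=["slope_ratio"]), intergenic], ignore_index=True
    ).drop_duplicates(key)
    return final.reset_index(drop=True)
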