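"""cis pairing, marginal scan, permutation empirical P, Storey q-values,
per-feature thresholds and the concordance filter."""
from itertools import permutations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from circqtl.qtl import (
    call_circqtls,
    cis_pairs,
    concordance_filter,
    empirical_p,
    marginal_scan,
    per_feature_threshold,
    permute_minp,
    storey_qvalues,
)

from conftest import make_genotypes


def _expr(rows, circ_ids, n):
    return pd.DataFrame(
        np.atleast_2d(rows), index=circ_ids, columns=[f"s{j}" for j in range(n)]
    )


class TestCisPairs:
    def _circs(self, start, end):
        return pd.DataFrame(
            {"chrom": ["chr1"], "start": [start], "end": [end]},
            index=pd.Index(["c1"], name="circ_id"),
        )

    def test_window_boundary_is_closed(self):
        geno = make_genotypes(np.ones((3, 4)), pos=[100_000, 99_999, 300_000])
        circs = self._circs(200_000, 210_000)
        got = set(cis_pairs(circs, geno)["snp_id"])
        assert "snp0" in got  # at start - 100000 exactly
        assert "snp1" not in got  # one bp beyond
        assert "snp2" in got

    def test_no_snps_in_window(self):
        geno = make_genotypes(np.ones((1, 4)), pos=[10])
        circs = self._circs(2_000_000, 2_000_100)
        assert len(cis_pairs(circs, geno)) == 0

    def test_non_autosomal_snps_excluded(self):
        geno = make_genotypes(np.ones((1, 4)), pos=[200_000], chrom="chrX")
        circs = pd.DataFrame(
            {"chrom": ["chrX"], "start": [200_000], "end": [200_100]},
            index=pd.Index(["c1"], name="circ_id"),
        )
        assert len(cis_pairs(circs, geno)) == 0


class TestMarginalScan:
    def test_perfect_linear_relation(self):
        rng = np.random.default_rng(0)
        dos = rng.uniform(0, 2, size=10)
        geno = make_genotypes([dos], pos=[100])
        expr = _expr(2 * dos, ["c1"], 10)
        pairs = pd.DataFrame({"circ_id": ["c1"], "snp_id": ["snp0"]})
        res = marginal_scan(expr, geno, pairs)
        assert res["slope"].iloc[0] == pytest.approx(2.0, abs=1e-9)
        assert res["p"].iloc[0] < 1e-12

    def test_matches_closed_form_ols_oracle(self):
        rng = np.random.default_rng(1)
        n = 25
        for _ in range(20):
            dos = rng.uniform(0, 2, n)
            y = rng.normal(size=n)
            geno = make_genotypes([dos], pos=[100])
            expr = _expr(y, ["c1"], n)
            pairs = pd.DataFrame({"circ_id": ["c1"], "snp_id": ["snp0"]})
            res = marginal_scan(expr, geno, pairs)
            lr = stats.linregress(dos, y)
            assert res["slope"].iloc[0] == pytest.approx(lr.slope, abs=1e-10)
            assert res["p"].iloc[0] == pytest.approx(lr.pvalue, rel=1e-9)

    def test_null_p_uniform(self):
        rng = np.random.default_rng(2)
        n, n_circ, n_snp = 50, 100, 100
        geno = make_genotypes(
            rng.binomial(2, 0.3, size=(n_snp, n)).astype(float),
            pos=100 * (np.arange(n_snp) + 1),
        )
        expr = _expr(rng.normal(size=(n_circ, n)), [f"c{i}" for i in range(n_circ)], n)
        pairs = pd.DataFrame(
            [(f"c{i}", f"snp{j}") for i in range(n_circ) for j in range(n_snp)],
            columns=["circ_id", "snp_id"],
        )
        res = marginal_scan(expr, geno, pairs)
        assert len(res) == 10_000
        ks = stats.kstest(res["p"].values, "uniform")
        assert ks.pvalue > 0.01

    def test_monomorphic_snp_dropped(self):
        geno = make_genotypes([[1.0] * 8, [0, 1, 2, 0, 1, 2, 0, 1]], pos=[100, 200])
        expr = _expr(np.arange(8.0), ["c1"], 8)
        pairs = pd.DataFrame({"circ_id": ["c1", "c1"], "snp_id": ["snp0", "snp1"]})
        res = marginal_scan(expr, geno, pairs)
        assert list(res["snp_id"]) == ["snp1"]

    def test_sample_mismatch_errors(self):
        geno = make_genotypes([[0, 1, 2]], pos=[100])
        expr = pd.DataFrame([[1.0, 2.0, 3.0]], index=["c1"], columns=["x", "y", "z"])
        pairs = pd.DataFrame({"circ_id": ["c1"], "snp_id": ["snp0"]})
        with pytest.raises(ValueError, match="samples"):
            marginal_scan(expr, geno, pairs)


class TestPermutationEmpiricalP:
    def test_exhaustive_matches_enumeration_oracle(self):
        # tiny-n ground truth: all 720 sample-label permutations enumerated
        n = 6
        agree = 0
        for inst in range(50):
            rng = np.random.default_rng(1000 + inst)
            nsnp = int(rng.integers(1, 4))
            dos = rng.uniform(0, 2, (nsnp, n))
            geno = make_genotypes(dos, pos=100 * (np.arange(nsnp) + 1))
            y = rng.normal(size=n)
            expr = _expr(y, ["c1"], n)
            pairs = pd.DataFrame({"circ_id": ["c1"] * nsnp, "snp_id": [f"snp{j}" for j in range(nsnp)]})
            perm = permute_minp(expr, geno, pairs, 0, 0, exhaustive=True)
            assert perm.n_perm == 720

            def pval(yv, g):
                r = np.corrcoef(yv, g)[0, 1]
                t = r * np.sqrt((n - 2) / (1 - r * r))
                return 2 * stats.t.sf(abs(t), n - 2)

            oracle = np.array(
                [min(pval(y[list(p)], dos[j]) for j in range(nsnp)) for p in permutations(range(n))]
            )
            assert np.allclose(np.sort(perm.minp["c1"]), np.sort(oracle), atol=1e-12)
            obs_oracle = min(pval(y, dos[j]) for j in range(nsnp))
            obs_impl = marginal_scan(expr, geno, pairs)["p"].min()
            emp = empirical_p(obs_impl, perm.minp["c1"])
            emp_oracle = (1 + (oracle < obs_oracle).sum()) / 721
            agree += emp == emp_oracle
        assert agree == 50

    def test_single_cis_snp_minp_is_pair_p(self):
        # with one cis SNP the per-circ minimum is just that pair's P
        n = 5
        rng = np.random.default_rng(3)
        dos = rng.uniform(0, 2, (1, n))
        geno = make_genotypes(dos, pos=[100])
        y = rng.normal(size=n)
        expr = _expr(y, ["c1"], n)
        pairs = pd.DataFrame({"circ_id": ["c1"], "snp_id": ["snp0"]})
        perm = permute_minp(expr, geno, pairs, 0, 0, exhaustive=True)

        def pval(yv):
            r = np.corrcoef(yv, dos[0])[0, 1]
            t = r * np.sqrt((n - 2) / (1 - r * r))
            return 2 * stats.t.sf(abs(t), n - 2)

        oracle = sorted(pval(y[list(p)]) for p in permutations(range(n)))
        assert np.allclose(sorted(perm.minp["c1"]), oracle, atol=1e-12)

    def test_null_empirical_p_centered(self):
        # under the null the observed minP sits near the middle of its
        # permutation distribution
        rng = np.random.default_rng(4)
        n, n_circ, n_snp = 40, 30, 60
        geno = make_genotypes(
            np.clip(rng.binomial(2, 0.4, (n_snp, n)) + rng.uniform(0, 0.01, (n_snp, n)), 0, 2),
            pos=100 * (np.arange(n_snp) + 1),
        )
        expr = _expr(rng.normal(size=(n_circ, n)), [f"c{i}" for i in range(n_circ)], n)
        pairs = pd.DataFrame(
            [(f"c{i}", f"snp{j}") for i in range(n_circ) for j in range(n_snp)],
            columns=["circ_id", "snp_id"],
        )
        perm = permute_minp(expr, geno, pairs, 400, seed=9)
        obs = marginal_scan(expr, geno, pairs).groupby("circ_id")["p"].min()
        emps = [empirical_p(obs[c], perm.minp[c]) for c in obs.index]
        assert abs(np.mean(emps) - 0.5) < 0.15

    def test_seeded_reproducibility(self):
        rng = np.random.default_rng(5)
        geno = make_genotypes(rng.uniform(0, 2, (3, 12)), pos=[100, 200, 300])
        expr = _expr(rng.normal(size=(2, 12)), ["c1", "c2"], 12)
        pairs = pd.DataFrame(
            {"circ_id": ["c1", "c1", "c2"], "snp_id": ["snp0", "snp1", "snp2"]}
        )
        a = permute_minp(expr, geno, pairs, 50, seed=42)
        b = permute_minp(expr, geno, pairs, 50, seed=42)
        for c in a.minp:
            assert np.array_equal(a.minp[c], b.minp[c])


class TestEmpiricalP:
    def test_direct_count(self):
        assert empirical_p(0.5, np.array([0.2, 0.4, 0.6, 0.8])) == pytest.approx(3 / 5)

    def test_no_smaller_minp(self):
        assert empirical_p(1e-9, np.full(10_000, 0.5)) == pytest.approx(1 / 10_001)

    def test_all_smaller(self):
        assert empirical_p(0.9, np.full(10_000, 0.5)) == pytest.approx(1.0)

    def test_ties_not_counted(self):
        # strict inequality: equal minP values do not count against the observation
        assert empirical_p(0.5, np.array([0.5, 0.5, 0.5, 0.5])) == pytest.approx(1 / 5)


class TestStoreyQ:
    def test_all_ones(self):
        res = storey_qvalues(np.ones(20))
        assert np.allclose(res.qvalues.values, 1.0)

    def test_single_feature_q_equals_p(self):
        res = storey_qvalues(np.array([0.3]))
        assert res.pi0 == 1.0
        assert res.qvalues.iloc[0] == pytest.approx(0.3)

    def test_signal_recovery_with_uniform_nulls(self):
        rng = np.random.default_rng(6)
        p = np.concatenate([rng.uniform(size=1000), np.full(50, 1e-6)])
        res = storey_qvalues(p)
        sig = res.qvalues.values < 0.05
        assert sig[1000:].sum() >= 45
        assert sig[:1000].sum() <= 5

    def test_q_monotone_in_p_rank(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(size=200)
        q = storey_qvalues(p).qvalues.values
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_invalid_p_errors(self):
        with pytest.raises(ValueError):
            storey_qvalues(np.array([0.0, 0.5]))


class TestPerFeatureThreshold:
    def test_inverse_cdf_convention(self):
        assert per_feature_threshold(np.array([0.1, 0.2, 0.3, 0.4]), 0.5) == pytest.approx(0.2)

    def test_smallest_empp_maps_to_min(self):
        minp = np.array([0.3, 0.1, 0.2])
        assert per_feature_threshold(minp, 1 / (len(minp) + 1)) == pytest.approx(0.1)

    def test_monotone_in_empp_star(self):
        rng = np.random.default_rng(8)
        minp = rng.uniform(size=100)
        stars = np.linspace(0.01, 1.0, 25)
        thr = [per_feature_threshold(minp, s) for s in stars]
        assert (np.diff(thr) >= 0).all()


class TestConcordanceFilter:
    def _qtls(self, rows):
        return pd.DataFrame(rows, columns=["circ_id", "snp_id", "slope", "t", "p"])

    def test_concordant_pair_retained(self):
        cpm = self._qtls([("c1", "s1", 0.3, 3.0, 1e-4)])
        ratio = self._qtls([("c1", "s1", 0.1, 2.5, 1e-3)])
        classes = pd.Series({"c1": "exonic"})
        out = concordance_filter(cpm, ratio, classes)
        assert len(out) == 1

    def test_discordant_pair_dropped(self):
        cpm = self._qtls([("c1", "s1", 0.3, 3.0, 1e-4)])
        ratio = self._qtls([("c1", "s1", -0.1, -2.5, 1e-3)])
        classes = pd.Series({"c1": "exonic"})
        assert len(concordance_filter(cpm, ratio, classes)) == 0

    def test_intergenic_kept_from_cpm_only(self):
        cpm = self._qtls([("c1", "s1", 0.3, 3.0, 1e-4), ("c2", "s2", 0.5, 4.0, 1e-5)])
        ratio = self._qtls([])
        classes = pd.Series({"c1": "exonic", "c2": "intergenic"})
        out = concordance_filter(cpm, ratio, classes)
        assert list(out["circ_id"]) == ["c2"]

    def test_missing_class_errors(self):
        cpm = self._qtls([("c1", "s1", 0.3, 3.0, 1e-4)])
        with pytest.raises(ValueError, match="class"):
            concordance_filter(cpm, self._qtls([]), pd.Series(dtype=object))


def test_call_circqtls_null_fdr_single_seed():
    """On a fully null simulation few circRNAs should reach q < 0.05."""
    rng = np.random.default_rng(9)
    n, n_circ, n_snp = 60, 40, 200
    geno = make_genotypes(
        rng.binomial(2, 0.3, (n_snp, n)).astype(float),
        pos=1000 * (np.arange(n_snp) + 1),
    )
    circs = pd.DataFrame(
        {
            "chrom": "chr1",
            "start": np.linspace(5000, 190_000, n_circ).astype(int),
            "end": np.linspace(6000, 191_000, n_circ).astype(int),
        },
        index=pd.Index([f"c{i}" for i in range(n_circ)], name="circ_id"),
    )
    expr = _expr(rng.normal(size=(n_circ, n)), list(circs.index), n)
    pairs = cis_pairs(circs, geno)
    res = call_circqtls(expr, geno, pairs, n_perm=200, seed=1)
    assert res.summary["is_qtl_circ"].mean() <= 0.1
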