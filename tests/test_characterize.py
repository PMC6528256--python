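"""max-circQTL selection, LD r2 and pruning, matched controls, distance
conventions and element enrichment."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from circqtl.characterize import (
    backsplice_distance,
    element_enrichment,
    fisher_2x2,
    ld_r2,
    matched_controls,
    prune_ld,
    select_max_circqtl,
    splice_site_report,
)

from conftest import make_genotypes


def hypergeom_fet(a, b, c, d, alternative):
    """Independent enumeration oracle for Fisher's exact test on
    [[a, b], [c, d]] with fixed margins."""
    r1, c1, n = a + b, a + c, a + b + c + d
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n, r1, c1)
    p_obs = stats.hypergeom.pmf(a, n, r1, c1)
    if alternative == "greater":
        return pmf[support >= a].sum()
    return pmf[pmf <= p_obs * (1 + 1e-9)].sum()


class TestMaxCircqtl:
    def _circs(self):
        return pd.DataFrame(
            {"chrom": ["chr1"], "start": [1000], "end": [2000]},
            index=pd.Index(["c1"], name="circ_id"),
        )

    def test_smallest_p_wins(self):
        qtls = pd.DataFrame(
            {"circ_id": ["c1", "c1"], "snp_id": ["a", "b"], "p": [1e-8, 1e-5],
             "snp_pos": [5000, 1500], "slope": [1, 1], "t": [5, 4]}
        )
        out = select_max_circqtl(qtls, self._circs())
        assert list(out["snp_id"]) == ["a"]

    def test_tie_broken_by_distance(self):
        qtls = pd.DataFrame(
            {"circ_id": ["c1", "c1"], "snp_id": ["far", "near"], "p": [1e-8, 1e-8],
             "snp_pos": [7000, 2050], "slope": [1, 1], "t": [5, 5]}
        )
        out = select_max_circqtl(qtls, self._circs())
        assert list(out["snp_id"]) == ["near"]

    def test_single_snp(self):
        qtls = pd.DataFrame(
            {"circ_id": ["c1"], "snp_id": ["only"], "p": [0.01], "snp_pos": [1500],
             "slope": [1], "t": [2]}
        )
        assert list(select_max_circqtl(qtls, self._circs())["snp_id"]) == ["only"]


class TestLdR2:
    def test_identical_vectors(self):
        g = make_genotypes([[0, 1, 2, 1, 0], [0, 1, 2, 1, 0]])
        assert ld_r2(g, "snp0", "snp1") == pytest.approx(1.0)

    def test_sign_free(self):
        a = np.array([0, 1, 2, 1, 0, 2], dtype=float)
        g = make_genotypes([a, 2 - a])
        assert ld_r2(g, "snp0", "snp1") == pytest.approx(1.0)

    def test_monomorphic_is_nan(self):
        g = make_genotypes([[1, 1, 1, 1], [0, 1, 2, 1]])
        assert np.isnan(ld_r2(g, "snp0", "snp1"))

    def test_independent_snps_low_r2(self):
        low = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            g = make_genotypes(rng.binomial(2, 0.3, (2, 500)).astype(float))
            low += ld_r2(g, "snp0", "snp1") < 0.05
        assert low >= 19


def _block_genotypes(rng, n_blocks=5, block=5, n=300):
    """Haplotype blocks with near-perfect within-block LD."""
    rows = []
    for _ in range(n_blocks):
        base = rng.binomial(1, 0.4, (2, n))
        for _ in range(block):
            flip = rng.random((2, n)) < 0.02
            rows.append(np.where(flip, 1 - base, base).sum(axis=0).astype(float))
    return make_genotypes(rows, pos=100 * (np.arange(n_blocks * block) + 1))


class TestPruneLd:
    def test_perfect_pair_keeps_one(self):
        g = make_genotypes([[0, 1, 2, 1, 0, 2], [0, 1, 2, 1, 0, 2]], maf=[0.3, 0.4])
        kept = prune_ld(["snp0", "snp1"], g)
        assert kept == ["snp1"]  # smaller-MAF member dropped

    def test_unlinked_all_kept(self):
        rng = np.random.default_rng(1)
        g = make_genotypes(rng.binomial(2, 0.4, (10, 400)).astype(float))
        snps = list(g.snp_ids)
        assert prune_ld(snps, g) == snps

    def test_blocks_reduced_to_one_representative(self):
        rng = np.random.default_rng(2)
        g = _block_genotypes(rng)
        kept = prune_ld(list(g.snp_ids), g)
        assert len(kept) == 5
        blocks = {int(s.replace("snp", "")) // 5 for s in kept}
        assert len(blocks) == 5

    def test_no_retained_pair_exceeds_threshold_brute_force(self):
        rng = np.random.default_rng(3)
        rows = list(rng.binomial(2, 0.4, (100, 200)).astype(float))
        base = rng.binomial(1, 0.5, (2, 200))
        for _ in range(100):  # a large tangled LD cluster
            flip = rng.random((2, 200)) < 0.1
            rows.append(np.where(flip, 1 - base, base).sum(axis=0).astype(float))
        g = make_genotypes(rows, pos=100 * (np.arange(200) + 1))
        kept = prune_ld(list(g.snp_ids), g)
        order = {s: i for i, s in enumerate(g.snp_ids)}
        for i, a in enumerate(kept):
            for b in kept[i + 1 :]:
                if abs(order[a] - order[b]) < 50:  # same window reach
                    assert ld_r2(g, a, b) <= 0.5 + 1e-12

    def test_unsorted_input_errors(self):
        g = make_genotypes([[0, 1, 2, 1], [1, 0, 1, 2]], pos=[100, 200])
        with pytest.raises(ValueError, match="sorted"):
            prune_ld(["snp1", "snp0"], g)


class TestMatchedControls:
    def test_single_bin_contract(self):
        target = pd.DataFrame({"snp_id": [f"t{i}" for i in range(5)], "maf": 0.07, "dist": 500.0})
        cand = pd.DataFrame(
            {"snp_id": [f"c{i}" for i in range(40)],
             "maf": [0.07] * 20 + [0.4] * 20,
             "dist": [500.0] * 20 + [50_000.0] * 20}
        )
        controls = matched_controls(cand, target, seed=1)
        assert len(controls) == 5
        assert all(c.startswith("c") and int(c[1:]) < 20 for c in controls)

    def test_seed_determinism(self):
        rng = np.random.default_rng(4)
        target = pd.DataFrame({"snp_id": [f"t{i}" for i in range(10)],
                               "maf": rng.uniform(0.05, 0.5, 10),
                               "dist": rng.uniform(0, 90_000, 10)})
        cand = pd.DataFrame({"snp_id": [f"c{i}" for i in range(200)],
                             "maf": rng.uniform(0.05, 0.5, 200),
                             "dist": rng.uniform(0, 90_000, 200)})
        assert matched_controls(cand, target, seed=7) == matched_controls(cand, target, seed=7)

    def test_maf_histogram_matches_target(self):
        rng = np.random.default_rng(5)
        m = 300
        target = pd.DataFrame({"snp_id": [f"t{i}" for i in range(m)],
                               "maf": rng.uniform(0.05, 0.25, m),
                               "dist": rng.uniform(0, 900, m)})
        cand = pd.DataFrame({"snp_id": [f"c{i}" for i in range(5000)],
                             "maf": rng.uniform(0.05, 0.5, 5000),
                             "dist": rng.uniform(0, 900, 5000)})
        controls = matched_controls(cand, target, seed=8)
        maf = cand.set_index("snp_id").loc[controls, "maf"]
        bins = np.arange(0.05, 0.55, 0.05)
        h_t = np.histogram(target["maf"], bins)[0]
        h_c = np.histogram(maf, bins)[0]
        keep = h_t > 0
        chi2 = stats.chisquare(h_c[keep], h_t[keep])
        assert chi2.pvalue > 0.01

    def test_pool_too_small_errors(self):
        target = pd.DataFrame({"snp_id": ["a", "b"], "maf": 0.1, "dist": 0.0})
        cand = pd.DataFrame({"snp_id": ["x"], "maf": [0.1], "dist": [0.0]})
        with pytest.raises(ValueError, match="pool"):
            matched_controls(cand, target, seed=1)


class TestBackspliceDistance:
    def test_at_start_is_internal_zero(self):
        d = backsplice_distance(1000, 1000, 2000)
        assert d["kind"] == "internal" and d["value"] == 0.0
        assert d["region"] == "circRNA region"

    def test_midpoint(self):
        d = backsplice_distance(1500, 1000, 2000)
        assert d["value"] == pytest.approx(0.5)

    def test_upstream_flanking(self):
        d = backsplice_distance(500, 1000, 2000)
        assert d == {"kind": "external", "value": -500.0, "region": "flanking intron"}

    def test_far_downstream_is_other(self):
        d = backsplice_distance(52_000, 1000, 2000)
        assert d["value"] == 50_000.0 and d["region"] == "other"

    def test_outside_window_errors(self):
        with pytest.raises(ValueError):
            backsplice_distance(10_000_000, 1000, 2000)


class TestElementEnrichment:
    def test_or_and_p_for_known_table(self):
        odds, p = fisher_2x2(10, 10, 5, 20, alternative="two-sided")
        assert odds == pytest.approx(4.0)
        assert p == pytest.approx(hypergeom_fet(10, 10, 5, 20, "two-sided"), rel=1e-9)

    def test_matches_enumeration_oracle_both_tails(self):
        rng = np.random.default_rng(6)
        for _ in range(100):
            a, b, c, d = rng.integers(0, 26, 4)
            if (a + b) == 0 or (c + d) == 0:
                continue
            for alt in ("two-sided", "greater"):
                _, p = fisher_2x2(int(a), int(b), int(c), int(d), alternative=alt)
                assert p == pytest.approx(hypergeom_fet(a, b, c, d, alt), rel=1e-8, abs=1e-12)

    def test_identical_composition_null(self):
        snps = [f"q{i}" for i in range(20)] + [f"c{i}" for i in range(20)]
        cats = (["intron"] * 10 + ["intergenic"] * 10) * 2
        annot = pd.DataFrame({"category": cats, "in_RCS": False}, index=snps)
        out = element_enrichment(snps[:20], snps[20:], annot)
        rows = out[out["category"].isin(["intron", "intergenic"])]
        assert np.allclose(rows["odds_ratio"], 1.0)
        assert np.allclose(rows["p"], 1.0)

    def test_planted_intron_enrichment_detected(self):
        rng = np.random.default_rng(7)
        n = 300
        q_cats = rng.choice(["intron", "intergenic"], n, p=[0.6, 0.4])
        c_cats = rng.choice(["intron", "intergenic"], n, p=[0.2, 0.8])
        snps = [f"q{i}" for i in range(n)] + [f"c{i}" for i in range(n)]
        annot = pd.DataFrame(
            {"category": np.concatenate([q_cats, c_cats]), "in_RCS": False}, index=snps
        )
        out = element_enrichment(snps[:n], snps[n:], annot).set_index("category")
        assert out.loc["intron", "odds_ratio"] > 1
        assert out.loc["intron", "fdr"] < 0.05

    def test_empty_sets_error(self):
        annot = pd.DataFrame({"category": ["intron"], "in_RCS": [False]}, index=["x"])
        with pytest.raises(ValueError):
            element_enrichment([], ["x"], annot)

    def test_rcs_row_restricted_to_introns(self):
        snps = [f"q{i}" for i in range(10)] + [f"c{i}" for i in range(10)]
        annot = pd.DataFrame(
            {"category": ["intron"] * 20,
             "in_RCS": [True] * 8 + [False] * 2 + [False] * 10},
            index=snps,
        )
        out = element_enrichment(snps[:10], snps[10:], annot)
        rcs = out[out["category"] == "RCS (intronic)"]
        assert len(rcs) == 1 and rcs["odds_ratio"].iloc[0] > 1


class TestSpliceSiteReport:
    def test_planted_disruption_reports_canonical_higher(self, small_dataset):
        from circqtl.quantify import circcpm

        eff = small_dataset.truth.effects
        splice = eff[eff["mode"] == "splice_disruption"]
        qtls = splice.rename(columns={"circ_id": "circ_id", "snp_id": "snp_id"})
        expr = circcpm(small_dataset.counts)
        report = splice_site_report(
            qtls, small_dataset.snp_annotations, expr, small_dataset.genotypes
        )
        assert len(report) == len(splice)
        assert (report["direction"] == "canonical-higher").all()
        assert (report["site_class"] == "back-splice").all()

    def test_flat_genotype_means_direction_none(self):
        annot = pd.DataFrame(
            {"category": ["canonical splice site"], "at_backsplice_site": [True]},
            index=["snpA"],
        )
        g = make_genotypes([[0, 0, 1, 1, 2, 2]])
        g.dosages.index = pd.Index(["snpA"], name="snp_id")
        g.snps.index = g.dosages.index
        expr = pd.DataFrame([[1.0] * 6], index=["c1"], columns=g.sample_ids)
        qtls = pd.DataFrame({"circ_id": ["c1"], "snp_id": ["snpA"]})
        report = splice_site_report(qtls, annot, expr, g)
        assert report["direction"].iloc[0] == "none"

    def test_no_flagged_snps_empty(self):
        annot = pd.DataFrame({"category": ["intron"], "at_backsplice_site": [False]}, index=["s"])
        g = make_genotypes([[0, 1, 2]])
        expr = pd.DataFrame([[1.0, 2.0, 3.0]], index=["c1"], columns=g.sample_ids)
        qtls = pd.DataFrame({"circ_id": ["c1"], "snp_id": ["snp0"]})
        assert len(splice_site_report(qtls, annot, expr, g)) == 0
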