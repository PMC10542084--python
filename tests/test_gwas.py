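import math

import numpy as np
import pytest

from magicpanel import tables
from magicpanel.genotype import GenotypeMatrix, VariantSite
from magicpanel.gwas import (KinshipError, KinshipMatrix, MixedLMScan,
                             bonferroni_threshold, build_regions,
                             candidate_genes, genotype_contrast, kinship,
                             mlm_scan, multi_trait_hits)

from conftest import random_matrix


def geno_from_calls(calls, chrom="c1"):
    calls = np.asarray(calls, dtype=np.int8)
    sites = [VariantSite(chrom, i + 1, f"s{i}", "A", "G")
             for i in range(calls.shape[0])]
    return GenotypeMatrix.from_calls(
        sites, [f"x{j}" for j in range(calls.shape[1])], calls)


class TestKinship:
    def test_matches_hand_linear_algebra(self):
        calls = [[0, 1, 2], [2, 2, 0], [0, 0, 2], [1, 1, 1]]
        m = geno_from_calls(calls)
        d = np.array(calls, float)
        p = d.mean(axis=1) / 2
        c = np.sum(2 * p * (1 - p))
        W = (d - d.mean(axis=1, keepdims=True)).T
        K = kinship(m)
        assert np.allclose(K.values, W @ W.T / c)

    def test_duplicate_samples_share_diagonal_value(self):
        rng = np.random.default_rng(60)
        base = rng.integers(0, 3, size=(50, 1))
        calls = np.hstack([base, base, rng.integers(0, 3, size=(50, 3))])
        K = kinship(geno_from_calls(calls)).values
        assert K[0, 1] == pytest.approx(K[0, 0])
        assert K[0, 1] == pytest.approx(max(K[0].max(), K[1].max()))

    def test_centering_zeroes_column_means(self):
        rng = np.random.default_rng(61)
        m = random_matrix(rng, n_sites=40, n_samples=8, missing_rate=0.1)
        d = m.dosage(impute=True)
        W = (d - d.mean(axis=1, keepdims=True)).T
        assert np.allclose(W.mean(axis=0), 0.0, atol=1e-12)

    def test_monomorphic_only_rejected(self):
        with pytest.raises(KinshipError):
            kinship(geno_from_calls([[0, 0, 0], [2, 2, 2]]))


class TestBonferroni:
    def test_known_values(self):
        assert bonferroni_threshold(0.05, 1) == pytest.approx(1.3010, abs=1e-4)
        assert bonferroni_threshold(0.05, 18_816) == pytest.approx(
            -math.log10(0.05 / 18_816))
        assert bonferroni_threshold(0.05, 18_186) == pytest.approx(5.5608,
                                                                   abs=1e-4)

    def test_strictly_increasing_in_n(self):
        vals = [bonferroni_threshold(0.05, n) for n in (1, 10, 100, 10_000)]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_validation(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.0, 10)
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)


class TestMlmScan:
    def test_identity_kinship_matches_ols(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(62)
        n, m = 120, 40
        calls = rng.integers(0, 3, size=(m, n)).astype(np.int8)
        geno = geno_from_calls(calls)
        y = rng.normal(size=n) + 0.5 * calls[0]
        K = KinshipMatrix(list(geno.samples), np.eye(n))
        res = MixedLMScan(y, geno, kin=K).fit()
        for i in range(m):
            ols = sm.OLS(y, sm.add_constant(calls[i].astype(float))).fit()
            assert res.table["p_value"][i] == pytest.approx(ols.pvalues[1],
                                                            abs=1e-6)
            assert res.table["add_effect"][i] == pytest.approx(ols.params[1],
                                                               abs=1e-6)

    def test_large_variance_ratio_converges_to_ols(self):
        # sigma2_g -> 0 (delta -> inf) must recover fixed-effects regression
        import statsmodels.api as sm

        rng = np.random.default_rng(63)
        n, m = 100, 25
        calls = rng.integers(0, 3, size=(m, n)).astype(np.int8)
        geno = geno_from_calls(calls)
        y = rng.normal(size=n)
        K = kinship(geno)
        res = MixedLMScan(y, geno, kin=K).fit(delta=1e12)
        for i in range(0, m, 5):
            ols = sm.OLS(y, sm.add_constant(calls[i].astype(float))).fit()
            assert res.table["p_value"][i] == pytest.approx(ols.pvalues[1],
                                                            abs=1e-6)

    def test_pvalues_invariant_under_affine_phenotype_rescale(self):
        rng = np.random.default_rng(64)
        n, m = 80, 30
        calls = rng.integers(0, 3, size=(m, n)).astype(np.int8)
        geno = geno_from_calls(calls)
        y = rng.normal(size=n)
        K = kinship(geno)
        a = MixedLMScan(y, geno, kin=K).fit()
        b = MixedLMScan(3.7 * y - 11.0, geno, kin=K).fit()
        assert np.allclose(a.neg_log10_p, b.neg_log10_p, atol=1e-8,
                           equal_nan=True)

    def test_collinear_marker_flagged_skipped(self):
        rng = np.random.default_rng(65)
        n = 50
        calls = np.vstack([np.zeros((1, n)),  # constant marker
                           rng.integers(0, 3, size=(4, n))]).astype(np.int8)
        geno = geno_from_calls(calls)
        res = MixedLMScan(rng.normal(size=n), geno).fit()
        assert bool(res.table["skipped"][0])
        assert np.isnan(res.table["p_value"][0])
        assert res.n_markers == 4

    def test_constant_phenotype_rejected(self):
        geno = geno_from_calls([[0, 1, 2, 0]])
        with pytest.raises(ValueError):
            MixedLMScan(np.ones(4), geno)

    def test_summary_mentions_components(self):
        rng = np.random.default_rng(66)
        calls = rng.integers(0, 3, size=(30, 60)).astype(np.int8)
        geno = geno_from_calls(calls)
        res = mlm_scan(geno, rng.normal(size=60), K=kinship(geno),
                       trait="area")
        s = res.summary()
        assert "area" in s and "variance components" in s


class TestMultiTraitAndRegions:
    def make_results(self, nlp_by_trait, geno):
        import pandas as pd

        from magicpanel.gwas import ScanResults

        out = {}
        for trait, nlp in nlp_by_trait.items():
            t = pd.DataFrame({
                "site_id": [s.site_id for s in geno.sites],
                "chrom": [s.chrom for s in geno.sites],
                "pos": [s.pos for s in geno.sites],
                "trait": trait,
                "neg_log10_p": nlp,
                "add_effect": 0.0,
                "p_value": 10.0 ** -np.asarray(nlp),
                "skipped": False,
            })
            out[trait] = ScanResults(None, t, None, 1)
        return out

    def test_min_traits_rule(self):
        geno = geno_from_calls(np.zeros((3, 4), dtype=np.int8) + 1)
        res = self.make_results(
            {"area": [6.0, 6.0, 1.0], "width": [6.0, 1.0, 1.0],
             "length": [6.0, 6.0, 1.0]}, geno)
        hits = multi_trait_hits(res, threshold=5.5, min_traits=2)
        assert [h[0] for h in hits] == ["s0", "s1"] or \
            sorted(h[0] for h in hits) == ["s0", "s1"]
        d = dict(hits)
        assert d["s0"] == {"area", "width", "length"}
        assert d["s1"] == {"area", "length"}

    def test_matches_bruteforce_intersection(self):
        rng = np.random.default_rng(67)
        geno = geno_from_calls(rng.integers(0, 3, size=(50, 4)).astype(np.int8))
        nlp = {t: rng.uniform(0, 8, 50) for t in ("a", "b", "c")}
        res = self.make_results(nlp, geno)
        hits = dict(multi_trait_hits(res, threshold=5.0, min_traits=2))
        for i, s in enumerate(geno.sites):
            traits = {t for t in nlp if nlp[t][i] >= 5.0}
            if len(traits) >= 2:
                assert hits[s.site_id] == traits
            else:
                assert s.site_id not in hits

    def test_published_hit_spans(self):
        hits = [(c, p) for c, p, *_ in tables.GWAS_HITS]
        regions = build_regions(hits, max_gap=1_000_000)
        spans = {r.chrom: r.span_mb for r in regions}
        assert len(regions) == 3
        assert spans["Arahy.07"] == 0.93
        assert spans["Arahy.12"] == 2.61
        assert spans["Arahy.17"] == 0.0

    def test_regions_idempotent_and_order_free(self):
        rng = np.random.default_rng(68)
        hits = [("c1", int(p)) for p in rng.integers(1, 10_000_000, 30)]
        a = build_regions(hits, 500_000)
        b = build_regions(list(reversed(hits)), 500_000)
        assert [(r.chrom, r.start, r.end) for r in a] == \
            [(r.chrom, r.start, r.end) for r in b]
        rehit = [(r.chrom, p) for r in a for (_, p) in r.sites]
        c = build_regions(rehit, 500_000)
        assert [(r.start, r.end) for r in a] == [(r.start, r.end) for r in c]

    def test_gap_splits_regions(self):
        regions = build_regions([("c1", 100), ("c1", 200), ("c1", 5_000_000)],
                                max_gap=1_000_000)
        assert len(regions) == 2


@pytest.fixture(scope="module")
def gene_db(tmp_path_factory):
    from magicpanel.annotate import load_gene_db

    gff = "\n".join([
        "##gff-version 3",
        "c1\tt\tgene\t100\t500\t.\t+\t.\tID=g1",
        "c1\tt\tgene\t1000\t2000\t.\t-\t.\tID=g2",
        "c1\tt\tgene\t9000\t9500\t.\t+\t.\tID=g3",
    ]) + "\n"
    p = tmp_path_factory.mktemp("gff") / "genes.gff3"
    p.write_text(gff)
    return load_gene_db(str(p))


class TestCandidateGenes:
    def test_overlapping_genes_returned(self, gene_db):
        from magicpanel.gwas import Region

        r = Region("c1", 400, 1500, [])
        assert candidate_genes(r, gene_db) == ["g1", "g2"]

    def test_empty_overlap(self, gene_db):
        from magicpanel.gwas import Region

        assert candidate_genes(Region("c1", 3000, 4000, []), gene_db) == []

    def test_matches_bruteforce_interval_scan(self, gene_db):
        from magicpanel.gwas import Region

        genes = [("g1", 100, 500), ("g2", 1000, 2000), ("g3", 9000, 9500)]
        rng = np.random.default_rng(69)
        for _ in range(20):
            a, b = sorted(rng.integers(1, 10_000, 2).tolist())
            expected = sorted(g for g, s, e in genes if s <= b and e >= a)
            assert candidate_genes(Region("c1", a, b, []), gene_db) == expected


class TestGenotypeContrast:
    def test_identical_groups_no_difference(self):
        calls = np.array([[0] * 6 + [2] * 6])
        geno = geno_from_calls(calls)
        y = np.array([1.0, 2, 3, 1, 2, 3, 1, 2, 3, 1, 2, 3])
        r = genotype_contrast(geno, "s0", y)
        assert r.mean_difference == pytest.approx(0.0)
        assert r.p_value == pytest.approx(1.0)

    def test_welch_statistic_matches_hand_computation(self):
        calls = np.array([[0, 0, 0, 0, 2, 2, 2, 2]])
        geno = geno_from_calls(calls)
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([3.0, 5.0, 6.0, 8.0])
        r = genotype_contrast(geno, "s0", np.concatenate([a, b]))
        va, vb = a.var(ddof=1) / 4, b.var(ddof=1) / 4
        t_hand = (a.mean() - b.mean()) / math.sqrt(va + vb)
        assert r.t_stat == pytest.approx(t_hand)
        assert r.mean_difference == pytest.approx(b.mean() - a.mean())

    def test_planted_effect_detected_reliably(self):
        rng = np.random.default_rng(70)
        hits = 0
        reps = 40
        for _ in range(reps):
            a = rng.normal(0, 1, 50)
            b = rng.normal(1, 1, 50)  # d = 1 s.d.
            calls = np.array([[0] * 50 + [2] * 50])
            geno = geno_from_calls(calls)
            r = genotype_contrast(geno, "s0", np.concatenate([a, b]))
            hits += r.p_value < 0.05
        assert hits / reps >= 0.9

    def test_conditioning_and_empty_group_error(self):
        calls = np.array([[0, 0, 2, 2], [0, 0, 0, 2]])
        geno = geno_from_calls(calls)
        y = np.arange(4.0)
        r = genotype_contrast(geno, "s0", y, condition=("s1", 0))
        assert r.groups["hom_ref"][0] == 2 and r.groups["hom_alt"][0] == 1
        with pytest.raises(ValueError, match="empty"):
            genotype_contrast(geno, "s0", y, condition=("s1", 2))
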