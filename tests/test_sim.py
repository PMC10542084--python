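import math

import numpy as np
import pytest

from magicpanel.crosses import parse_cross
from magicpanel.genotype import HET, MISSING, GenotypeMatrix, VariantSite
from magicpanel.sim import (GeneticMap, HaplotypeMosaic, SimIndividual,
                            founder_shares, haldane, make_gamete,
                            mosaic_to_genotypes, self_individual,
                            simulate_cross_population)


class TestHaldane:
    def test_closed_form_values(self):
        assert haldane(0) == 0.0
        assert haldane(50) == pytest.approx(0.5 * (1 - math.exp(-1)))
        assert haldane(1e9) == pytest.approx(0.5)

    def test_monotone_nonnegative(self):
        d = np.linspace(0, 300, 50)
        r = [haldane(x) for x in d]
        assert all(b >= a for a, b in zip(r, r[1:]))
        with pytest.raises(ValueError):
            haldane(-1)


def f1_parent(length_bp=100_000_000):
    lengths = {"c": length_bp}
    return SimIndividual("F1", HaplotypeMosaic.pure(0, lengths),
                         HaplotypeMosaic.pure(1, lengths)), lengths


class TestMakeGamete:
    def test_crossover_count_matches_map_length(self):
        parent, lengths = f1_parent(150_000_000)  # 1.5 Morgans at 1 cM/Mb
        gmap = GeneticMap(lengths, rate_cM_per_Mb=1.0)
        rng = np.random.default_rng(21)
        counts = np.array([
            make_gamete(parent, gmap, rng).labels["c"].size - 1
            for _ in range(10_000)])
        se = counts.std(ddof=1) / math.sqrt(counts.size)
        assert abs(counts.mean() - 1.5) <= 3 * se

    def test_tiling_invariant_preserved(self):
        parent, lengths = f1_parent()
        gmap = GeneticMap(lengths, rate_cM_per_Mb=2.0)
        rng = np.random.default_rng(22)
        for _ in range(200):
            make_gamete(parent, gmap, rng).validate(lengths)

    def test_zero_length_chromosome_rejected(self):
        with pytest.raises(ValueError):
            GeneticMap({"c": 0})

    def test_recombination_fraction_matches_haldane(self):
        # 50 cM apart on a 1 cM/Mb map
        parent, lengths = f1_parent(100_000_000)
        gmap = GeneticMap(lengths, rate_cM_per_Mb=1.0)
        rng = np.random.default_rng(23)
        pos = np.array([25_000_000, 75_000_000])
        rec = sum(
            int(np.diff(make_gamete(parent, gmap, rng).founder_at("c", pos))[0]
                != 0)
            for _ in range(8_000)
        )
        r_hat = rec / 8_000
        se = math.sqrt(r_hat * (1 - r_hat) / 8_000)
        assert abs(r_hat - haldane(50)) <= 3 * se


def small_founders(n_sites=60, length=2_000_000):
    rng = np.random.default_rng(30)
    pos = np.sort(rng.choice(np.arange(2, length), n_sites, replace=False))
    sites = [VariantSite("c", int(p), f"c_{p}", "A", "G") for p in pos]
    calls = np.zeros((n_sites, 8), dtype=np.int8)
    for i in range(n_sites):
        calls[i, rng.integers(0, 8)] = 2  # every site is 1:7
    geno = GenotypeMatrix.from_calls(sites, list("ABCDEFGH"), calls)
    gmap = GeneticMap({"c": length}, rate_cM_per_Mb=1.0)
    return geno, gmap


class TestFunnelSimulation:
    def test_f1_fully_heterozygous_at_diagnostic_sites(self):
        geno, gmap = small_founders()
        rng = np.random.default_rng(31)
        pop = simulate_cross_population(parse_cross("A/B"), geno.samples,
                                        gmap, 5, 0, rng)
        out = mosaic_to_genotypes(pop, geno.sites, geno, rng=rng)
        # F1 of A x B is heterozygous wherever A and B genotypes differ
        carriers_ab = [i for i, s in enumerate(geno.sites)
                       if geno.calls[i, 0] != geno.calls[i, 1]]
        assert np.all(out.calls[carriers_ab] == HET)

    def test_mosaic_labels_within_cross_founders(self):
        geno, gmap = small_founders()
        rng = np.random.default_rng(32)
        cross = parse_cross("A/E//D/G///B/C//F/H")
        pop = simulate_cross_population(cross, geno.samples, gmap, 20, 2, rng)
        for ind in pop:
            labels = set(ind.hap1.labels["c"]) | set(ind.hap2.labels["c"])
            assert labels <= set(range(8))
            assert 1 <= len(labels) <= 8
            ind.hap1.validate({"c": 2_000_000})
            ind.hap2.validate({"c": 2_000_000})

    def test_selfing_reduces_heterozygosity(self):
        geno, gmap = small_founders()
        rng = np.random.default_rng(33)
        cross = parse_cross("A/E//D/G///B/C//F/H")
        s0 = simulate_cross_population(cross, geno.samples, gmap, 400, 0, rng)
        s2 = simulate_cross_population(cross, geno.samples, gmap, 400, 2, rng)
        het0 = (mosaic_to_genotypes(s0, geno.sites, geno, rng=rng).calls == HET).mean()
        het2 = (mosaic_to_genotypes(s2, geno.sites, geno, rng=rng).calls == HET).mean()
        assert het0 == pytest.approx(0.25, abs=0.03)
        assert het2 == pytest.approx(het0 / 4, abs=0.02)

    def test_bit_reproducible_with_seed(self):
        geno, gmap = small_founders()
        cross = parse_cross("A/E//D/G///B/C//F/H")

        def run():
            rng = np.random.default_rng(34)
            pop = simulate_cross_population(cross, geno.samples, gmap, 10, 2, rng)
            return mosaic_to_genotypes(pop, geno.sites, geno,
                                       error_rate=0.01, missing_rate=0.02,
                                       rng=rng)

        assert run().equal(run())


class TestProjection:
    def test_deterministic_when_error_free(self):
        geno, gmap = small_founders()
        rng = np.random.default_rng(35)
        pop = simulate_cross_population(parse_cross("A/B"), geno.samples,
                                        gmap, 3, 1, rng)
        a = mosaic_to_genotypes(pop, geno.sites, geno,
                                rng=np.random.default_rng(1))
        b = mosaic_to_genotypes(pop, geno.sites, geno,
                                rng=np.random.default_rng(2))
        assert a.equal(b)  # no randomness left when rates are 0

    def test_all_missing_at_rate_one(self):
        geno, gmap = small_founders()
        rng = np.random.default_rng(36)
        pop = simulate_cross_population(parse_cross("A/B"), geno.samples,
                                        gmap, 3, 0, rng)
        out = mosaic_to_genotypes(pop, geno.sites, geno, missing_rate=1.0,
                                  rng=rng)
        assert np.all(out.calls == MISSING)

    def test_matches_interval_overlap_oracle(self):
        geno, gmap = small_founders(n_sites=50)
        rng = np.random.default_rng(37)
        cross = parse_cross("A/E//D/G///B/C//F/H")
        pop = simulate_cross_population(cross, geno.samples, gmap, 15, 1, rng)
        out = mosaic_to_genotypes(pop, geno.sites, geno, rng=rng)

        def founder_at_oracle(hap, pos):
            prev = 0
            for e, lab in zip(hap.ends["c"], hap.labels["c"]):
                if prev < pos <= e:
                    return lab
                prev = e
            raise AssertionError("position outside mosaic")

        for k, ind in enumerate(pop):
            for i, s in enumerate(geno.sites):
                f1 = founder_at_oracle(ind.hap1, s.pos)
                f2 = founder_at_oracle(ind.hap2, s.pos)
                expected = (geno.calls[i, f1] // 2) + (geno.calls[i, f2] // 2)
                assert out.calls[i, k] == expected

    def test_site_outside_bounds_rejected(self):
        geno, gmap = small_founders()
        rng = np.random.default_rng(38)
        pop = simulate_cross_population(parse_cross("A/B"), geno.samples,
                                        gmap, 2, 0, rng)
        bad = [VariantSite("c", 5_000_000, "far", "A", "G")]
        with pytest.raises((ValueError, KeyError)):
            mosaic_to_genotypes(pop, bad, geno, rng=rng)


def test_founder_shares_sum_to_one():
    geno, gmap = small_founders()
    rng = np.random.default_rng(39)
    cross = parse_cross("A/E//D/G///B/C//F/H")
    pop = simulate_cross_population(cross, geno.samples, gmap, 50, 2, rng)
    shares = founder_shares(pop, {"c": 2_000_000}, 8)
    assert shares.sum() == pytest.approx(1.0)
    assert np.all(shares > 0)
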