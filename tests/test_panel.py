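from itertools import combinations, product

import numpy as np
import pytest

from magicpanel.genotype import GenotypeMatrix, VariantSite
from magicpanel.panel import (HET_PRESENT, MISSING_PRESENT, MONOMORPHIC, P1_7,
                              P2_6, P3_5, P4_4, SitePattern, allocate_quota,
                              build_panel, classify_founder_pattern,
                              density_report, extract_probe_flanks,
                              pairwise_polymorphic_counts, reverse_complement,
                              select_even_spacing, unique_site_counts)
from magicpanel import tables


def founders_from_rows(rows):
    sites = [VariantSite("c1", 10 * (i + 1), f"s{i}", "A", "G")
             for i in range(len(rows))]
    return GenotypeMatrix.from_calls(sites, list("ABCDEFGH"),
                                     np.array(rows, dtype=np.int8))


class TestClassify:
    def test_one_vs_seven(self):
        pat = classify_founder_pattern([2] + [0] * 7, list("ABCDEFGH"))
        assert pat.label == P1_7 and pat.carrier_founders == {"A"}

    def test_monomorphic_and_special(self):
        assert classify_founder_pattern([0] * 8).label == MONOMORPHIC
        assert classify_founder_pattern([2] * 8).label == MONOMORPHIC
        assert classify_founder_pattern([1] + [0] * 7).label == HET_PRESENT
        assert classify_founder_pattern([-1] + [0] * 7).label == MISSING_PRESENT
        # missing dominates het
        assert classify_founder_pattern([-1, 1] + [0] * 6).label == MISSING_PRESENT

    def test_arity_error(self):
        with pytest.raises(ValueError):
            classify_founder_pattern([0] * 7)

    def test_exhaustive_homozygous_enumeration(self):
        counts = {}
        for vec in product((0, 2), repeat=8):
            lab = classify_founder_pattern(vec).label
            counts[lab] = counts.get(lab, 0) + 1
        assert counts == {MONOMORPHIC: 2, P1_7: 16, P2_6: 56, P3_5: 112,
                          P4_4: 70}

    def test_full_oracle_over_all_vectors(self):
        # independent oracle: classify by direct counting rules
        def oracle(vec):
            if any(v == -1 for v in vec):
                return MISSING_PRESENT
            if any(v == 1 for v in vec):
                return HET_PRESENT
            k = min(vec.count(0), vec.count(2))
            return {0: MONOMORPHIC, 1: P1_7, 2: P2_6, 3: P3_5, 4: P4_4}[k]

        for vec in product((0, 1, 2), repeat=8):
            assert classify_founder_pattern(vec).label == oracle(list(vec))


class TestFounderSummaries:
    def test_unique_counts_constructed(self):
        rows = [[2] + [0] * 7] * 5 + [[0, 2] + [0] * 6] * 3 + [[0] * 8] * 4
        m = founders_from_rows(rows)
        counts = unique_site_counts(m)
        assert counts["A"] == 5 and counts["B"] == 3
        assert sum(counts.values()) == 8  # partitions the 1:7 sites

    def test_pairwise_identity_and_p17(self):
        rows = [[2] + [0] * 7] * 4  # 4 sites, A carries minority
        counts = pairwise_polymorphic_counts(founders_from_rows(rows))
        for pair, n in counts.items():
            assert n == (4 if "A" in pair else 0)

    def test_pairwise_matches_bruteforce(self):
        rng = np.random.default_rng(12)
        calls = rng.choice([0, 1, 2, -1], size=(50, 8),
                           p=[0.4, 0.1, 0.4, 0.1]).astype(np.int8)
        m = founders_from_rows(calls.tolist())
        counts = pairwise_polymorphic_counts(m)
        for i, j in combinations(range(8), 2):
            expected = sum(
                1 for r in range(50)
                if {calls[r, i], calls[r, j]} == {0, 2})
            assert counts[frozenset((m.samples[i], m.samples[j]))] == expected


class TestQuota:
    def test_equal_lengths_split_evenly(self):
        q = allocate_quota({"a": 100, "b": 100}, {"a": 99, "b": 99}, 100)
        assert q == {"a": 50, "b": 50}

    def test_largest_remainder_3_to_1(self):
        q = allocate_quota({"a": 3, "b": 1}, {"a": 100, "b": 100}, 8)
        assert q == {"a": 6, "b": 2}

    def test_capped_surplus_redistributed(self):
        q = allocate_quota({"a": 1, "b": 1}, {"a": 3, "b": 100}, 20)
        assert q["a"] == 3 and q["b"] == 17

    def test_empty_warns(self):
        with pytest.warns(UserWarning):
            assert allocate_quota({"a": 10}, {"a": 0}, 5) == {}


def cands(positions, labels=None):
    labels = labels or [P1_7] * len(positions)
    return [(VariantSite("c1", p, f"s{p}", "A", "G"),
             SitePattern(lab, frozenset("A")))
            for p, lab in zip(positions, labels)]


class TestEvenSpacing:
    def test_takes_all_when_quota_covers(self):
        cs = cands(list(range(10, 110, 10)))
        assert select_even_spacing(cs, 10, 100) == cs

    def test_clustered_candidates_borrow(self):
        cs = cands([5, 10, 15])
        out = select_even_spacing(cs, 2, 1000)
        assert len(out) == 2  # second window empty, borrowed globally

    def test_p17_preferred_within_window(self):
        cs = cands([40, 60], [P2_6, P1_7])
        out = select_even_spacing(cs, 1, 100)
        assert out[0][1].label == P1_7

    def test_deterministic(self):
        rng = np.random.default_rng(13)
        pos = np.sort(rng.choice(np.arange(1, 5000), 60, replace=False))
        cs = cands([int(p) for p in pos])
        a = select_even_spacing(cs, 12, 5000)
        b = select_even_spacing(list(cs), 12, 5000)
        assert a == b
        assert [s.pos for s, _ in a] == sorted({s.pos for s, _ in a})

    def test_gap_bound_vs_bruteforce(self):
        from itertools import combinations as comb

        rng = np.random.default_rng(14)
        pos = sorted(int(p) for p in
                     rng.choice(np.arange(1, 2000), 20, replace=False))
        cs = cands(pos)
        quota, L = 3, 2000

        def max_gap(sel):
            ps = [0] + sorted(sel) + [L]
            return max(b - a for a, b in zip(ps, ps[1:]))

        best = min(max_gap(c) for c in comb(pos, quota))
        got = max_gap([s.pos for s, _ in select_even_spacing(cs, quota, L)])
        assert got <= 2 * best


class TestProbeFlanks:
    REF = {"c1": "ACGTACGTACGT"}

    def test_hand_extraction(self):
        site = VariantSite("c1", 6, "s", "C", "G")
        rec = extract_probe_flanks(self.REF, site, 2)
        assert rec.forward_flank == "TACGT"  # positions 4..8, target centered
        assert rec.forward_flank[2] == site.ref_allele

    def test_zero_flank_single_base(self):
        rec = extract_probe_flanks(self.REF, VariantSite("c1", 3, "s", "G", "T"), 0)
        assert rec.forward_flank == "G"

    def test_reverse_complement_involution(self):
        rec = extract_probe_flanks(self.REF, VariantSite("c1", 6, "s", "C", "A"), 3)
        assert reverse_complement(rec.reverse_flank) == rec.forward_flank

    def test_edge_behavior(self):
        site = VariantSite("c1", 2, "s", "C", "T")
        with pytest.raises(ValueError):
            extract_probe_flanks(self.REF, site, 5)
        with pytest.warns(UserWarning):
            rec = extract_probe_flanks(self.REF, site, 5, on_edge="truncate")
        assert rec.forward_flank == "ACGTACG"


class TestDensityReport:
    def test_reproduces_published_rates(self):
        lengths = {c: L for c, (L, _) in tables.PANEL_CHROMOSOMES.items()}
        counts = {c: n for c, (_, n) in tables.PANEL_CHROMOSOMES.items()}
        df = density_report(counts, lengths)
        rates = dict(zip(df["chromosome"], df["rate"]))
        for chrom, rate in tables.PANEL_RATES.items():
            assert rates[chrom] == rate
        total = df[df.chromosome == "Total"].iloc[0]
        assert total["rate"] == tables.PANEL_TOTAL_RATE
        assert total["variants"] == tables.PANEL_TOTAL_VARIANTS

    def test_degenerate_rows(self):
        df = density_report({"a": 5}, {"a": 5, "b": 7})
        row_a = df[df.chromosome == "a"].iloc[0]
        assert row_a["rate"] == 1
        row_b = df[df.chromosome == "b"].iloc[0]
        assert row_b["rate"] is not None and bool(row_b.isna()["rate"])


def test_build_panel_respects_patterns_and_quotas(tiny_founders):
    sf, spec = tiny_founders
    panel = build_panel(sf.genotypes, spec.chromosomes, 200)
    labels = {pat.label for _, pat in panel.selected_sites}
    assert labels <= {P1_7, P2_6}
    by_chrom = panel.counts_by_chrom()
    for chrom, n in by_chrom.items():
        assert n <= panel.quotas[chrom]
    assert panel.n_selected <= 200
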