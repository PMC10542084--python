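"""Self-validation routines: each function recomputes, from scratch, one of
the quantitative checks the package is designed around — funnel counts,
concordance arithmetic, panel densities, region spans, simulator
calibration against closed forms, and the statistical calibration of the
mixed-model scan.  They are used by the acceptance test suite and the
acceptance script.

Stochastic routines take a seed and report Monte-Carlo standard errors so
the caller can apply a 3-s.e. criterion.  Problem sizes follow the demo
scale (20 chromosomes at 1/50 physical length, 300 lines, 5,000 markers)
chosen so the full battery runs in minutes on one CPU.
"""

from __future__ import annotations

import math

import numpy as np

from . import tables
from .concordance import accuracy
from .crosses import (design_funnel, enumerate_eight_way, enumerate_four_way,
                      enumerate_two_way, parse_cross, partition_classes,
                      select_subset)
from .genotype import GenotypeMatrix, HET, VariantSite, all_site_stats, filter_sites
from .gwas import bonferroni_threshold, build_regions, kinship, mlm_scan
from .panel import P1_7, classify_all, density_report
from .sim import (GeneticMap, HaplotypeMosaic, SimIndividual, haldane,
                  make_gamete, mosaic_to_genotypes, simulate_cross_population)
from .synth import FounderSpec, simulate_founders

#: expected S2 heterozygosity at a 1:7 site under the half-allele funnel:
#: the carrier founder sits in exactly one parental quartet, so the 8-way F1
#: is heterozygous with probability 1/4, halved by each selfing generation.
S2_HET_1TO7 = 1.0 / 16.0


# ---------------------------------------------------------------------------
# Exact checks


def funnel_counts(n_per_cross: int = 200) -> dict:
    """Enumerate the 8-founder funnel and report all stage counts."""
    founders = list("ABCDEFGH")
    tw = enumerate_two_way(founders)
    fw = enumerate_four_way(tw)
    ew = enumerate_eight_way(fw)
    classes = partition_classes(ew)
    subset = select_subset(classes)
    return {
        "two_way": len(tw),
        "four_way": len(fw),
        "eight_way": len(ew),
        "classes": len(classes),
        "class_size": len(next(iter(classes.values()))),
        "subset": len(subset),
        "target_population": len(subset) * n_per_cross,
    }


def concordance_accuracies() -> dict[str, float]:
    """Accuracy recomputed from each founder's published consistent count."""
    return {
        acc: accuracy(vals[4], tables.PANEL_TOTAL_VARIANTS)
        for acc, vals in tables.FOUNDER_CONCORDANCE.items()
    }


def panel_density() -> dict:
    """Marker-density table of the released panel from its printed counts."""
    lengths = {c: L for c, (L, _) in tables.PANEL_CHROMOSOMES.items()}
    counts = {c: n for c, (_, n) in tables.PANEL_CHROMOSOMES.items()}
    df = density_report(counts, lengths)
    rates = dict(zip(df["chromosome"], df["rate"]))
    return {
        "rates": rates,
        "total_variants": int(df[df.chromosome == "Total"]["variants"].iloc[0]),
    }


def gwas_region_spans(max_gap: int = 1_000_000) -> dict[str, float]:
    """Span (Mb) of each region chained from the published association hits."""
    hits = [(chrom, pos) for chrom, pos, *_ in tables.GWAS_HITS]
    regions = build_regions(hits, max_gap=max_gap)
    return {r.chrom: r.span_mb for r in regions}


def pattern_enumeration() -> dict:
    """Exhaustively classify founder-call vectors.

    Returns label counts over all 3^8 non-missing call vectors and over the
    2^8 all-homozygous subset (where 1:7 gives 16 and 2:6 gives 56).
    """
    from itertools import product

    from .panel import classify_founder_pattern

    hom_counts: dict[str, int] = {}
    all_counts: dict[str, int] = {}
    for vec in product((0, 1, 2), repeat=8):
        label = classify_founder_pattern(vec).label
        all_counts[label] = all_counts.get(label, 0) + 1
        if 1 not in vec:
            hom_counts[label] = hom_counts.get(label, 0) + 1
    return {"all_homozygous": hom_counts, "all_vectors": all_counts}


# ---------------------------------------------------------------------------
# Simulator calibration


def _demo_founders(seed: int, n_sites: int) -> tuple:
    spec = FounderSpec(chromosomes=tables.chrom_lengths(1 / 50),
                       n_sites=n_sites, seed=seed)
    sf = simulate_founders(spec)
    return sf, spec


def s2_calibration(seed: int, n_lines: int = 2_000, n_sites: int = 500) -> dict:
    """Simulate S2 lines from the genotyped 8-way funnel cross and measure
    heterozygosity at 1:7 sites and per-founder genome shares.

    Monte-Carlo standard errors are taken across independent lines.
    """
    sf, spec = _demo_founders(seed, n_sites)
    cross = parse_cross(tables.S2_SOURCE_CROSS)
    rng = np.random.default_rng(seed)
    pop = simulate_cross_population(cross, sf.genotypes.samples,
                                    sf.genetic_map, n_lines, 2, rng)
    geno = mosaic_to_genotypes(pop, sf.genotypes.sites, sf.genotypes, rng=rng)
    idx = [i for i, p in enumerate(classify_all(sf.genotypes))
           if p.label == P1_7]
    het_per_line = (geno.calls[idx] == HET).mean(axis=0)
    het = float(het_per_line.mean())
    het_se = float(het_per_line.std(ddof=1) / math.sqrt(n_lines))

    lengths = spec.chromosomes
    shares = np.empty((n_lines, 8))
    for i, ind in enumerate(pop):
        shares[i] = (ind.hap1.shares(lengths, 8) + ind.hap2.shares(lengths, 8)) / 2
    share_mean = shares.mean(axis=0)
    share_se = shares.std(axis=0, ddof=1) / math.sqrt(n_lines)
    return {
        "het": het, "het_se": het_se, "het_expected": S2_HET_1TO7,
        "share_mean": share_mean, "share_se": share_se,
        "share_expected": 1.0 / 8.0,
        "n_lines": n_lines, "n_p17_sites": len(idx),
    }


def haldane_calibration(seed: int, distances_cM=(10.0, 50.0, 100.0),
                        n_gametes: int = 20_000) -> list[dict]:
    """Two-locus recombination fractions from simulated meioses vs closed form."""
    out = []
    rng = np.random.default_rng(seed)
    for d in distances_cM:
        length_bp = int(2 * d * 1e6)  # 1 cM/Mb; loci at quarter points
        gmap = GeneticMap({"c": length_bp}, rate_cM_per_Mb=1.0)
        parent = SimIndividual(
            "F1", HaplotypeMosaic.pure(0, {"c": length_bp}),
            HaplotypeMosaic.pure(1, {"c": length_bp}))
        pos = np.array([length_bp // 4, length_bp // 4 + int(d * 1e6)])
        rec = 0
        for _ in range(n_gametes):
            gam = make_gamete(parent, gmap, rng)
            a, b = gam.founder_at("c", pos)
            rec += a != b
        r_hat = rec / n_gametes
        se = math.sqrt(r_hat * (1 - r_hat) / n_gametes)
        out.append({"d_cM": d, "r_hat": r_hat, "r_expected": haldane(d),
                    "se": max(se, 1e-12)})
    return out


def crossover_rate(seed: int, n_gametes: int = 10_000,
                   morgans: float = 1.5) -> dict:
    """Mean crossover count per meiosis vs the map length in Morgans."""
    length_bp = int(morgans * 100 * 1e6)
    gmap = GeneticMap({"c": length_bp}, rate_cM_per_Mb=1.0)
    parent = SimIndividual(
        "F1", HaplotypeMosaic.pure(0, {"c": length_bp}),
        HaplotypeMosaic.pure(1, {"c": length_bp}))
    rng = np.random.default_rng(seed)
    counts = np.empty(n_gametes)
    for i in range(n_gametes):
        gam = make_gamete(parent, gmap, rng)
        counts[i] = gam.labels["c"].size - 1
    return {"mean": float(counts.mean()),
            "se": float(counts.std(ddof=1) / math.sqrt(n_gametes)),
            "expected": morgans}


# ---------------------------------------------------------------------------
# Mixed-model calibration


def _iid_markers(rng: np.random.Generator, n: int, m: int) -> GenotypeMatrix:
    p = rng.uniform(0.05, 0.5, m)
    G = rng.binomial(2, p[:, None], size=(m, n)).astype(np.int8)
    sites = [VariantSite(f"c{i % 20:02d}", i // 20 + 1, f"s{i}", "A", "C")
             for i in range(m)]
    return GenotypeMatrix.from_calls(
        sites, [f"i{j}" for j in range(n)], G)


def mlm_null_calibration(seed: int, n: int = 300, m: int = 5_000,
                         h2: float = 0.5) -> dict:
    """Type-I error of the P3D scan at nominal 0.05 under a pure polygenic
    trait (no QTL), with unlinked markers so the binomial s.e. applies."""
    rng = np.random.default_rng(seed)
    geno = _iid_markers(rng, n, m)
    d = geno.dosage()
    W = d - d.mean(axis=1, keepdims=True)
    u = W.T @ rng.normal(size=m)
    u = u / u.std() * math.sqrt(h2)
    y = u + rng.normal(scale=math.sqrt(1 - h2), size=n)
    res = mlm_scan(geno, y, K=kinship(geno))
    pv = res.table["p_value"].to_numpy()
    pv = pv[~np.isnan(pv)]
    frac = float(np.mean(pv < 0.05))
    return {"type1": frac, "n_markers": pv.size,
            "se": math.sqrt(0.05 * 0.95 / pv.size)}


def mlm_ols_agreement(seed: int, n: int = 200, m: int = 200) -> float:
    """Max |p_mlm - p_ols| with identity kinship (should be ~ 0)."""
    import statsmodels.api as sm

    from .gwas import KinshipMatrix, MixedLMScan

    rng = np.random.default_rng(seed)
    geno = _iid_markers(rng, n, m)
    y = rng.normal(size=n)
    K = KinshipMatrix(list(geno.samples), np.eye(n))
    res = MixedLMScan(y, geno, kin=K).fit()
    worst = 0.0
    d = geno.dosage()
    for i in range(m):
        ols = sm.OLS(y, sm.add_constant(d[i])).fit()
        worst = max(worst, abs(ols.pvalues[1] - res.table["p_value"][i]))
    return worst


def _one_qtl_replicate(sf, cross, seed: int, n_lines: int, pve: float,
                       window_bp: int) -> tuple[bool, bool]:
    rng = np.random.default_rng(seed)
    pop = simulate_cross_population(cross, sf.genotypes.samples,
                                    sf.genetic_map, n_lines, 2, rng)
    geno = mosaic_to_genotypes(pop, sf.genotypes.sites, sf.genotypes, rng=rng)
    geno = filter_sites(geno, 0.3, 0.05)
    d = geno.dosage()
    _, maf, _ = all_site_stats(geno)
    chrom = geno.sites[0].chrom
    idx = [i for i, s in enumerate(geno.sites)
           if s.chrom == chrom and maf[i] >= 0.2]
    qi = idx[len(idx) // 2]
    x = d[qi]
    x = (x - x.mean()) / x.std()
    W = d - d.mean(axis=1, keepdims=True)
    u = W.T @ rng.normal(size=d.shape[0])
    u = u / u.std()
    resid_var = 1.0 - pve - 0.35
    y = (math.sqrt(pve) * x + math.sqrt(0.35) * u
         + rng.normal(scale=math.sqrt(resid_var), size=geno.n_samples))
    res = mlm_scan(geno, y, K=kinship(geno))
    thr = res.threshold(0.05)
    nlp = res.neg_log10_p
    qpos, qchrom = geno.sites[qi].pos, geno.sites[qi].chrom
    near = np.array([s.chrom == qchrom and abs(s.pos - qpos) <= window_bp
                     for s in geno.sites])
    with np.errstate(invalid="ignore"):
        detected = bool(np.nanmax(np.where(near, nlp, np.nan)) >= thr)
    top = int(np.nanargmax(nlp))
    localized = (geno.sites[top].chrom == qchrom
                 and abs(geno.sites[top].pos - qpos) <= window_bp)
    return detected, localized


def mlm_qtl_power(seed: int, n_reps: int = 50, n_lines: int = 300,
                  n_sites: int = 5_000, pve: float = 0.15,
                  window_bp: int = 2_000_000) -> dict:
    """Detection and localization rates for a planted QTL in simulated S2
    populations (detection = any significant marker within the window;
    localization = genome-wide top hit within the window)."""
    sf, _ = _demo_founders(seed, n_sites)
    cross = parse_cross(tables.S2_SOURCE_CROSS)
    flags = [_one_qtl_replicate(sf, cross, seed + 1000 + r, n_lines, pve,
                                window_bp) for r in range(n_reps)]
    det = float(np.mean([f[0] for f in flags]))
    loc = float(np.mean([f[1] for f in flags]))
    return {"detection": det, "localization": loc, "n_reps": n_reps,
            "detected": [f[0] for f in flags],
            "localized": [f[1] for f in flags]}
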