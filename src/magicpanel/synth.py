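"""Synthetic founders, reference, gene models and pod-size phenotypes.

Everything the pipeline consumes can be generated here so the whole stack
is testable without external data: eight homozygous founder lines with a
controllable mix of 1:7 and 2:6 diagnostic sites, a toy reference FASTA
consistent with the ref alleles, toy GFF3 gene models tiling ~30% of each
chromosome, and pod-size phenotypes (area, perimeter, length, width in
labelled arbitrary units) with planted QTLs and a target heritability.

The default demo scale — 8 founders, the 20 panel chromosomes at 1/50
physical length, 5,000 sites, 300 S2 lines, pattern mix 3:1 (1:7 to 2:6),
six pods measured per plant — mirrors the study design at a size that runs
the full pipeline in minutes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import tables
from .genotype import GenotypeMatrix, HOM_ALT, HOM_REF, VariantSite
from .sim import GeneticMap, SimIndividual

FOUNDER_NAMES = list("ABCDEFGH")
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

TRAITS = ("area", "perimeter", "length", "width")
TRAIT_UNITS = {"area": "mm2", "perimeter": "mm", "length": "mm", "width": "mm"}


@dataclass
class FounderSpec:
    """Parameters of the synthetic founder panel."""

    n_founders: int = 8
    chromosomes: dict[str, int] = field(
        default_factory=lambda: tables.chrom_lengths(scale=1 / 50))
    n_sites: int = 5_000
    frac_p17: float = 0.75  # matches the released panel's ~3:1 mix
    frac_p26: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frac_p17 + self.frac_p26 > 1.0 + 1e-12:
            raise ValueError("pattern fractions sum above 1")
        if any(L <= 0 for L in self.chromosomes.values()):
            raise ValueError("chromosome lengths must be positive")


@dataclass
class QtlSpec:
    """Planted QTLs and trait architecture.

    ``qtls`` maps trait -> list of (site_id, effect in trait s.d.);
    dominance is zero.  ``heritability`` applies per base trait.
    """

    qtls: dict[str, list[tuple[str, float]]]
    heritability: float = 0.5
    pods_per_plant: int = 6
    pod_noise_sd: float = 0.3

    def __post_init__(self) -> None:
        if not 0.0 <= self.heritability <= 1.0:
            raise ValueError("heritability must be in [0, 1]")


@dataclass
class SyntheticFounders:
    genotypes: GenotypeMatrix
    reference: dict[str, str]
    gff3: str
    genetic_map: GeneticMap


def simulate_founders(spec: FounderSpec) -> SyntheticFounders:
    """Homozygous founder genotypes plus a consistent toy reference and GFF3.

    Sites are assigned patterns by the requested mix (remainder becomes
    3:5/4:4-style splits drawn uniformly); carriers are uniform founder
    subsets; the reference sequence carries the ref allele at each site.
    """
    rng = np.random.default_rng(spec.seed)
    nf = spec.n_founders
    chroms = sorted(spec.chromosomes)
    total_len = sum(spec.chromosomes.values())
    # per-chromosome site counts proportional to length
    counts = {c: max(1, int(round(spec.n_sites * spec.chromosomes[c] / total_len)))
              for c in chroms}

    sites: list[VariantSite] = []
    calls_rows: list[np.ndarray] = []
    reference: dict[str, str] = {}
    for c in chroms:
        L = spec.chromosomes[c]
        seq = rng.integers(0, 4, size=L)
        n = min(counts[c], max(1, L // 2))
        pos = np.sort(rng.choice(np.arange(2, L), size=n, replace=False))
        for p in pos:
            ref_b = int(seq[p - 1])
            alt_b = int((ref_b + rng.integers(1, 4)) % 4)
            site = VariantSite(c, int(p), f"{c}_{p}",
                               chr(_BASES[ref_b]), chr(_BASES[alt_b]))
            u = rng.random()
            if u < spec.frac_p17:
                k = 1
            elif u < spec.frac_p17 + spec.frac_p26:
                k = 2
            else:
                k = int(rng.integers(3, nf // 2 + 1))
            carriers = rng.choice(nf, size=k, replace=False)
            row = np.full(nf, HOM_REF, dtype=np.int8)
            row[carriers] = HOM_ALT
            sites.append(site)
            calls_rows.append(row)
        reference[c] = _BASES[seq].tobytes().decode()
    founders = GenotypeMatrix.from_calls(
        sites, FOUNDER_NAMES[:nf], np.vstack(calls_rows))
    gff3 = _toy_gff3(spec.chromosomes, rng)
    gmap = GeneticMap(dict(spec.chromosomes), rate_cM_per_Mb=1.0)
    return SyntheticFounders(founders, reference, gff3, gmap)


def _toy_gff3(chromosomes: dict[str, int], rng: np.random.Generator) -> str:
    """Single-exon genes of ~3 kb tiling ~30% of each chromosome."""
    lines = ["##gff-version 3"]
    gi = 0
    for c in sorted(chromosomes):
        L = chromosomes[c]
        gene_len = min(3_000, max(300, L // 10))
        step = int(gene_len / 0.3)
        start = 1 + int(rng.integers(0, max(1, step // 2)))
        while start + gene_len < L:
            gi += 1
            end = start + gene_len - 1
            strand = "+" if rng.random() < 0.5 else "-"
            gid = f"gene{gi:05d}"
            cds_len = (gene_len // 2) // 3 * 3
            cds_start = start + 60
            cds_end = cds_start + cds_len - 1
            lines += [
                f"{c}\tsynth\tgene\t{start}\t{end}\t.\t{strand}\t.\tID={gid}",
                f"{c}\tsynth\tmRNA\t{start}\t{end}\t.\t{strand}\t.\t"
                f"ID={gid}.t1;Parent={gid}",
                f"{c}\tsynth\texon\t{start}\t{end}\t.\t{strand}\t.\t"
                f"ID={gid}.e1;Parent={gid}.t1",
                f"{c}\tsynth\tCDS\t{cds_start}\t{cds_end}\t.\t{strand}\t0\t"
                f"ID={gid}.c1;Parent={gid}.t1",
            ]
            start += step
    return "\n".join(lines) + "\n"


def write_reference_fasta(reference: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for c in sorted(reference):
            fh.write(f">{c}\n")
            seq = reference[c]
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")


# ---------------------------------------------------------------------------
# Phenotypes


def simulate_phenotypes(
    population: list[SimIndividual] | list[str],
    genotypes: GenotypeMatrix,
    qtls: QtlSpec,
    rng: np.random.Generator,
    return_components: bool = False,
):
    """Pod-size phenotype table for the population.

    Length and width are built as latent traits: planted QTL effects on
    standardized dosage, a polygenic term from genome-wide sites, and a
    residual scaled to the target heritability; the observed value is the
    mean of ``pods_per_plant`` noisy pod measurements.  Area is scaled
    length x width and perimeter ~ 2 (length + width), which induces the
    positive inter-trait correlations of real pod measurements.
    """
    samples = genotypes.samples
    n = len(samples)
    d = genotypes.dosage(impute=True)  # sites x samples

    def standardized(site_id: str) -> np.ndarray:
        i = genotypes.site_index_by_id(site_id)
        x = d[i]
        sd = x.std()
        if sd == 0:
            raise ValueError(f"QTL site {site_id} is monomorphic in population")
        return (x - x.mean()) / sd

    h2 = qtls.heritability
    # shared polygenic base from a thinned site set
    poly_sites = d[:: max(1, d.shape[0] // 500)]
    pw = rng.normal(size=poly_sites.shape[0]) / np.sqrt(poly_sites.shape[0])
    base_poly = poly_sites.T @ pw
    if base_poly.std() > 0:
        base_poly = (base_poly - base_poly.mean()) / base_poly.std()

    latent: dict[str, np.ndarray] = {}
    genetic: dict[str, np.ndarray] = {}
    qtl_scale: dict[str, float] = {}
    for trait in ("length", "width"):
        g = np.zeros(n)
        for site_id, eff in qtls.qtls.get(trait, []):
            g += eff * standardized(site_id)
        g += 0.6 * base_poly + 0.4 * rng.normal(size=n)  # trait-specific polygenics
        gv = g.var()
        scale = 1.0
        if gv > 0:
            scale = math.sqrt(h2 / gv)
            g = g * scale
        e = rng.normal(scale=np.sqrt(max(1e-12, 1 - h2)), size=n)
        genetic[trait] = g
        qtl_scale[trait] = scale
        latent[trait] = g + e

    # map to plausible pod dimensions (mm)
    length_mm = 35.0 + 4.0 * latent["length"]
    width_mm = 15.0 + 1.8 * latent["width"]
    area_mm2 = 0.75 * length_mm * width_mm
    perim_mm = 2.05 * (length_mm + width_mm)
    values = {"length": length_mm, "width": width_mm,
              "area": area_mm2, "perimeter": perim_mm}
    out = {}
    for trait in TRAITS:
        v = values[trait]
        pods = v[:, None] + rng.normal(
            scale=qtls.pod_noise_sd * max(1.0, float(np.abs(v).mean()) / 35.0),
            size=(n, qtls.pods_per_plant))
        out[trait] = pods.mean(axis=1)
    df = pd.DataFrame(out, index=pd.Index(samples, name="sample"))
    if return_components:
        # realized mm-scale coefficient per planted QTL (unit-sd dosage)
        unit = {"length": 4.0, "width": 1.8}
        qtl_beta = {
            trait: {sid: eff * qtl_scale[trait] * unit[trait]
                    for sid, eff in qtls.qtls.get(trait, [])}
            for trait in ("length", "width")
        }
        return df, {"genetic": genetic, "latent": latent, "qtl_beta": qtl_beta}
    return df


# ---------------------------------------------------------------------------
# Demo fixture


def make_demo(out_dir, seed: int = 0, n_sites: int = 5_000,
              n_lines: int = 300, scale: float = 1 / 50,
              panel_size: int | None = None) -> dict:
    """Materialize a complete demo fixture directory.

    Writes founder VCF, reference FASTA, gene-model GFF3, population VCF,
    pedigree TSV and phenotype TSV; returns the paths plus the planted-QTL
    truth.  Deterministic for a given seed.
    """
    from . import crosses as cx
    from . import sim as ms
    from .genotype import write_vcf
    from .panel import build_panel

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    spec = FounderSpec(chromosomes=tables.chrom_lengths(scale=scale),
                       n_sites=n_sites, seed=seed)
    synth = simulate_founders(spec)
    founders = synth.genotypes

    write_vcf(founders, out / "founders.vcf", spec.chromosomes)
    write_reference_fasta(synth.reference, out / "reference.fa")
    (out / "genes.gff3").write_text(synth.gff3)

    if panel_size is None:
        panel_size = min(n_sites, 40_000)
    panel = build_panel(founders, spec.chromosomes, panel_size)
    panel_ids = [s.site_id for s, _ in panel.selected_sites]
    panel_geno = founders.subset_sites(
        [founders.site_index_by_id(i) for i in panel_ids])

    plan = cx.design_funnel(founders.samples, n_per_cross=n_lines)
    source = cx.parse_cross(tables.S2_SOURCE_CROSS)
    pop = ms.simulate_funnel(plan, panel_geno, synth.genetic_map,
                             n_per_cross=n_lines, rng=rng, crosses=[source])
    geno = ms.mosaic_to_genotypes(pop, panel_geno.sites, panel_geno,
                                  error_rate=0.002, missing_rate=0.01, rng=rng)
    write_vcf(geno, out / "population.vcf", spec.chromosomes)
    cx.pedigree_table(plan).to_csv(out / "pedigree.tsv", sep="\t", index=False)

    qtl_sites = _pick_qtl_sites(geno, rng)
    qspec = QtlSpec(qtls={
        "length": [(qtl_sites["length"], 0.9)],
        "width": [(qtl_sites["width"], 0.9)],
    })
    pheno = simulate_phenotypes(pop, geno, qspec, rng)
    pheno.to_csv(out / "phenotypes.tsv", sep="\t")
    manifest = {
        "founders_vcf": str(out / "founders.vcf"),
        "reference_fasta": str(out / "reference.fa"),
        "gff3": str(out / "genes.gff3"),
        "population_vcf": str(out / "population.vcf"),
        "pedigree_tsv": str(out / "pedigree.tsv"),
        "phenotypes_tsv": str(out / "phenotypes.tsv"),
        "qtl_truth": qtl_sites,
        "seed": seed,
    }
    return manifest


def _pick_qtl_sites(geno: GenotypeMatrix, rng: np.random.Generator) -> dict:
    """One well-behaved (high-MAF, mid-chromosome) QTL site per base trait."""
    from .genotype import all_site_stats

    _, maf, _ = all_site_stats(geno)
    chroms = sorted({s.chrom for s in geno.sites})
    picks = {}
    for trait, chrom in (("length", chroms[0]),
                         ("width", chroms[len(chroms) // 2])):
        idx = [i for i, s in enumerate(geno.sites) if s.chrom == chrom]
        good = [i for i in idx if maf[i] >= 0.2]
        pool = good if good else idx
        mid = np.median([geno.sites[i].pos for i in pool])
        best = min(pool, key=lambda i: abs(geno.sites[i].pos - mid))
        picks[trait] = geno.sites[best].site_id
    return picks
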