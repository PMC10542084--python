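"""Forward simulator of the MAGIC funnel.

Meiosis follows the standard no-interference model: the crossover count on
a chromosome is Poisson with mean equal to its genetic length in Morgans,
crossover positions are uniform in genetic distance, and the starting
homolog is chosen fairly.  The recombination fraction between loci d cM
apart is therefore Haldane's r = (1 - exp(-2d/100)) / 2.

Founder descent is tracked as haplotype mosaics — per-homolog ordered
segments labelled by founder of origin — which are projected onto panel
sites at the end, optionally with genotyping error and missingness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .crosses import Cross, FunnelPlan
from .genotype import (HET, HOM_ALT, HOM_REF, MISSING, GenotypeMatrix,
                       VariantSite)


def haldane(d_cM: float) -> float:
    """Recombination fraction for a genetic distance of ``d_cM`` centimorgans."""
    if d_cM < 0:
        raise ValueError("distance must be >= 0")
    return 0.5 * (1.0 - math.exp(-2.0 * d_cM / 100.0))


@dataclass
class GeneticMap:
    """Physical chromosome lengths plus a recombination rate model.

    Either a constant ``rate_cM_per_Mb`` per chromosome, or monotone
    (bp, cM) anchor lists for non-uniform maps.
    """

    lengths_bp: dict[str, int]
    rate_cM_per_Mb: float | dict[str, float] = 1.0
    anchors: dict[str, np.ndarray] | None = None  # chrom -> (n, 2) [bp, cM]

    def __post_init__(self) -> None:
        for c, L in self.lengths_bp.items():
            if L <= 0:
                raise ValueError(f"zero-length chromosome {c}")
        if self.anchors:
            for c, a in self.anchors.items():
                a = np.asarray(a, float)
                if np.any(np.diff(a[:, 0]) <= 0) or np.any(np.diff(a[:, 1]) < 0):
                    raise ValueError(f"anchors not monotone for {c}")
                self.anchors[c] = a

    def _rate(self, chrom: str) -> float:
        if isinstance(self.rate_cM_per_Mb, dict):
            return self.rate_cM_per_Mb[chrom]
        return self.rate_cM_per_Mb

    def morgans(self, chrom: str) -> float:
        """Genetic length of a chromosome in Morgans."""
        if self.anchors and chrom in self.anchors:
            return float(self.anchors[chrom][-1, 1]) / 100.0
        return self.lengths_bp[chrom] * self._rate(chrom) / 1e6 / 100.0

    def cm_to_bp(self, chrom: str, cm: np.ndarray) -> np.ndarray:
        """Invert the genetic map: cM positions to bp."""
        if self.anchors and chrom in self.anchors:
            a = self.anchors[chrom]
            return np.interp(cm, a[:, 1], a[:, 0])
        return np.asarray(cm) / self._rate(chrom) * 1e6


@dataclass
class HaplotypeMosaic:
    """One homolog as founder-origin segments tiling each chromosome.

    ``ends[chrom]`` is the sorted array of segment end positions (bp,
    inclusive; the last equals the chromosome length) and
    ``labels[chrom]`` the founder index of each segment.
    """

    ends: dict[str, np.ndarray]
    labels: dict[str, np.ndarray]

    @classmethod
    def pure(cls, founder_index: int, lengths_bp: dict[str, int]) -> "HaplotypeMosaic":
        return cls(
            {c: np.array([L], dtype=np.int64) for c, L in lengths_bp.items()},
            {c: np.array([founder_index], dtype=np.int32) for c in lengths_bp},
        )

    def founder_at(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        """Founder index covering each (sorted or unsorted) bp position."""
        idx = np.searchsorted(self.ends[chrom], np.asarray(pos), side="left")
        return self.labels[chrom][idx]

    def validate(self, lengths_bp: dict[str, int]) -> None:
        """Check the tiling invariant: segments cover [1, L] without overlap."""
        for c, L in lengths_bp.items():
            e = self.ends[c]
            if e.size == 0 or e[-1] != L:
                raise AssertionError(f"mosaic does not reach end of {c}")
            if np.any(np.diff(e) <= 0):
                raise AssertionError(f"non-increasing segment ends on {c}")
            lab = self.labels[c]
            if lab.size != e.size:
                raise AssertionError(f"labels/ends length mismatch on {c}")

    def shares(self, lengths_bp: dict[str, int], n_founders: int) -> np.ndarray:
        """Fraction of total genome length carried per founder index."""
        out = np.zeros(n_founders)
        for c, L in lengths_bp.items():
            e = self.ends[c]
            widths = np.diff(np.concatenate(([0], e)))
            np.add.at(out, self.labels[c], widths)
        return out / sum(lengths_bp.values())


@dataclass
class SimIndividual:
    """A simulated line: two homologous mosaics and a pedigree reference."""

    id: str
    hap1: HaplotypeMosaic
    hap2: HaplotypeMosaic
    pedigree: str = ""


def _merge_adjacent(ends: np.ndarray, labels: np.ndarray):
    """Canonical merge of adjacent segments with equal labels."""
    if labels.size <= 1:
        return ends, labels
    keep = np.empty(labels.size, dtype=bool)
    keep[:-1] = labels[:-1] != labels[1:]
    keep[-1] = True
    return ends[keep], labels[keep]


def make_gamete(parent: SimIndividual, gmap: GeneticMap,
                rng: np.random.Generator) -> HaplotypeMosaic:
    """One meiotic product of ``parent`` under the no-interference model."""
    ends: dict[str, np.ndarray] = {}
    labels: dict[str, np.ndarray] = {}
    for chrom, L in gmap.lengths_bp.items():
        morgans = gmap.morgans(chrom)
        n_xo = rng.poisson(morgans)
        start = int(rng.integers(2))
        h = (parent.hap1, parent.hap2)
        if n_xo == 0:
            ends[chrom] = h[start].ends[chrom]
            labels[chrom] = h[start].labels[chrom]
            continue
        cm = np.sort(rng.uniform(0.0, morgans * 100.0, size=n_xo))
        bp = np.unique(np.clip(gmap.cm_to_bp(chrom, cm).astype(np.int64), 1, L - 1))
        # walk alternating homologs between crossover breakpoints
        seg_ends, seg_labels = [], []
        cur = start
        prev = 0
        for b in np.concatenate((bp, [L])):
            e, lab = h[cur].ends[chrom], h[cur].labels[chrom]
            i0 = np.searchsorted(e, prev + 1, side="left")
            i1 = np.searchsorted(e, b, side="left")
            for i in range(i0, i1 + 1):
                seg_ends.append(min(int(e[i]), int(b)))
                seg_labels.append(int(lab[i]))
            prev = b
            cur = 1 - cur
        e_arr = np.array(seg_ends, dtype=np.int64)
        l_arr = np.array(seg_labels, dtype=np.int32)
        e_arr, l_arr = _merge_adjacent(e_arr, l_arr)
        ends[chrom], labels[chrom] = e_arr, l_arr
    return HaplotypeMosaic(ends, labels)


def mate(p1: SimIndividual, p2: SimIndividual, child_id: str,
         gmap: GeneticMap, rng: np.random.Generator) -> SimIndividual:
    """Offspring of two parents (p1 contributes hap1)."""
    return SimIndividual(
        child_id, make_gamete(p1, gmap, rng), make_gamete(p2, gmap, rng),
        pedigree=f"{p1.id} x {p2.id}",
    )


def self_individual(ind: SimIndividual, child_id: str, gmap: GeneticMap,
                    rng: np.random.Generator) -> SimIndividual:
    """One selfed offspring (single seed descent carries exactly one forward)."""
    return SimIndividual(
        child_id, make_gamete(ind, gmap, rng), make_gamete(ind, gmap, rng),
        pedigree=f"{ind.id} (self)",
    )


def _cross_individual(struct, founders_ix: dict[str, int], gmap: GeneticMap,
                      rng: np.random.Generator, name: str) -> SimIndividual:
    """Recursively realize one individual of a pairing tree."""
    if isinstance(struct, str):
        ix = founders_ix[struct]
        return SimIndividual(
            struct,
            HaplotypeMosaic.pure(ix, gmap.lengths_bp),
            HaplotypeMosaic.pure(ix, gmap.lengths_bp),
        )
    p1 = _cross_individual(struct[0], founders_ix, gmap, rng, name)
    p2 = _cross_individual(struct[1], founders_ix, gmap, rng, name)
    return mate(p1, p2, name, gmap, rng)


def simulate_cross_population(
    cross: Cross,
    founder_names: list[str],
    gmap: GeneticMap,
    n_lines: int,
    selfing_generations: int,
    rng: np.random.Generator,
    id_prefix: str = "L",
) -> list[SimIndividual]:
    """``n_lines`` S-generation lines descending from one funnel cross.

    Each line realizes its own intermediate cross individuals (the field
    funnel used many plants per cross), then ``selfing_generations`` rounds
    of single seed descent.
    """
    founders_ix = {f: i for i, f in enumerate(founder_names)}
    missing = cross.founder_set - set(founders_ix)
    if missing:
        raise ValueError(f"founders {sorted(missing)} not in genotype matrix")
    out = []
    for i in range(n_lines):
        name = f"{id_prefix}{i + 1:04d}"
        ind = _cross_individual(cross.structure, founders_ix, gmap, rng,
                                f"{name}.S0")
        for g in range(selfing_generations):
            ind = self_individual(ind, f"{name}.S{g + 1}", gmap, rng)
        ind.id = name
        out.append(ind)
    return out


def simulate_funnel(
    plan: FunnelPlan,
    founders: GenotypeMatrix,
    gmap: GeneticMap,
    n_per_cross: int | None = None,
    selfing_generations: int | None = None,
    rng: np.random.Generator | None = None,
    crosses: list[Cross] | None = None,
) -> list[SimIndividual]:
    """Simulate the funnel population over the plan's advance subset.

    ``crosses`` restricts simulation to specific 8-way crosses (e.g. the
    single cross the genotyped lines descend from); default is the plan's
    full subset.  Warns if founders are heterozygous at simulated sites.
    """
    if rng is None:
        rng = np.random.default_rng()
    if n_per_cross is None:
        n_per_cross = plan.n_per_cross
    if selfing_generations is None:
        selfing_generations = plan.selfing_generations
    if np.any(founders.calls == HET):
        import warnings

        warnings.warn("founder matrix contains heterozygous calls")
    todo = crosses if crosses is not None else plan.subset
    pop: list[SimIndividual] = []
    for ci, cross in enumerate(todo):
        pop.extend(simulate_cross_population(
            cross, founders.samples, gmap, n_per_cross, selfing_generations,
            rng, id_prefix=f"C{ci + 1:02d}_",
        ))
    return pop


def mosaic_to_genotypes(
    population: list[SimIndividual],
    panel_sites: list[VariantSite],
    founders: GenotypeMatrix,
    error_rate: float = 0.0,
    missing_rate: float = 0.0,
    rng: np.random.Generator | None = None,
) -> GenotypeMatrix:
    """Project founder mosaics onto panel sites.

    Each homolog contributes the allele its covering founder carries
    (founders are taken as homozygous; a heterozygous founder call
    contributes a fair random allele).  Then symmetric genotyping error
    with probability ``error_rate`` (the call is replaced by one of the
    other two codes) and masking with probability ``missing_rate``.
    """
    if rng is None:
        rng = np.random.default_rng()
    site_ix_by_id = {s.site_id: i for i, s in enumerate(founders.sites)}
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for j, s in enumerate(panel_sites):
        by_chrom.setdefault(s.chrom, ([], []))
        by_chrom[s.chrom][0].append(s.pos)
        by_chrom[s.chrom][1].append(j)
    for c in list(by_chrom):
        pos, idx = by_chrom[c]
        by_chrom[c] = (np.array(pos), np.array(idx))
        if np.any(by_chrom[c][0] > founders_chrom_len(population, c)):
            raise ValueError(f"panel site beyond chromosome {c} bounds")

    # founder allele dosage (0 or 1 per homolog) at each panel site
    n_f = founders.n_samples
    fallele = np.zeros((len(panel_sites), n_f), dtype=np.int8)
    het_mask = np.zeros_like(fallele, dtype=bool)
    for j, s in enumerate(panel_sites):
        fi = site_ix_by_id.get(s.site_id)
        if fi is None:
            raise KeyError(f"panel site {s.site_id} absent from founder matrix")
        calls = founders.calls[fi]
        fallele[j] = (calls == HOM_ALT).astype(np.int8)
        het_mask[j] = calls == HET

    n = len(population)
    out = np.empty((len(panel_sites), n), dtype=np.int8)
    for k, ind in enumerate(population):
        col = np.empty(len(panel_sites), dtype=np.int8)
        for c, (pos, idx) in by_chrom.items():
            f1 = ind.hap1.founder_at(c, pos)
            f2 = ind.hap2.founder_at(c, pos)
            a1 = fallele[idx, f1]
            a2 = fallele[idx, f2]
            for hm, ff, aa in ((het_mask[idx, f1], f1, a1),
                               (het_mask[idx, f2], f2, a2)):
                if hm.any():
                    aa[hm] = rng.integers(0, 2, size=int(hm.sum()))
            col[idx] = a1 + a2
        out[:, k] = col
    if error_rate > 0:
        err = rng.random(out.shape) < error_rate
        shift = rng.integers(1, 3, size=out.shape)
        out = np.where(err, (out + shift) % 3, out).astype(np.int8)
    if missing_rate > 0:
        out[rng.random(out.shape) < missing_rate] = MISSING
    return GenotypeMatrix.from_calls(
        list(panel_sites), [ind.id for ind in population], out)


def founders_chrom_len(population: list[SimIndividual], chrom: str) -> int:
    return int(population[0].hap1.ends[chrom][-1])


def founder_shares(population: list[SimIndividual],
                   lengths_bp: dict[str, int], n_founders: int) -> np.ndarray:
    """Mean genome share per founder index over a population (sums to 1)."""
    acc = np.zeros(n_founders)
    for ind in population:
        acc += ind.hap1.shares(lengths_bp, n_founders)
        acc += ind.hap2.shares(lengths_bp, n_founders)
    return acc / (2 * len(population))


def write_mosaic_bed(population: list[SimIndividual], founder_names: list[str],
                     path) -> None:
    """BED-like export: chrom, start (0-based), end, founder, line, homolog."""
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tfounder\tline\thomolog\n")
        for ind in population:
            for hname, hap in (("1", ind.hap1), ("2", ind.hap2)):
                for c in sorted(hap.ends):
                    prev = 0
                    for e, lab in zip(hap.ends[c], hap.labels[c]):
                        fh.write(f"{c}\t{prev}\t{e}\t{founder_names[lab]}\t"
                                 f"{ind.id}\t{hname}\n")
                        prev = int(e)
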