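"""Diploid biallelic genotype matrices, VCF/TSV I/O, and site-level filters.

Genotypes are stored as small signed integers per (site, sample):
``0`` = homozygous reference, ``1`` = heterozygous, ``2`` = homozygous
alternate, ``-1`` = missing.  The contract is the four-category semantics;
the numeric values are an implementation detail exposed only through the
module constants below.

All coordinates are 1-based inclusive (VCF convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

HOM_REF = 0
HET = 1
HOM_ALT = 2
MISSING = -1

_VALID_CODES = frozenset({HOM_REF, HET, HOM_ALT, MISSING})


class VcfParseError(ValueError):
    """Raised for malformed VCF input."""


class PloidyError(ValueError):
    """Raised when a VCF sample call is not diploid."""


@dataclass(frozen=True)
class VariantSite:
    """A biallelic variant at a 1-based genomic position."""

    chrom: str
    pos: int
    site_id: str
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"ref and alt alleles identical at {self.site_id}")

    @property
    def variant_class(self) -> str:
        """``"SNP"`` iff both alleles are single bases, else ``"INDEL"``."""
        if len(self.ref_allele) == 1 and len(self.alt_allele) == 1:
            return "SNP"
        return "INDEL"

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref_allele, self.alt_allele)


@dataclass(frozen=True)
class SiteStats:
    """Per-site summary over samples: missing rate, MAF, het count.

    ``maf`` is computed from non-missing calls only and is NaN when every
    call is missing; a site with a single non-missing call gets MAF 0
    (effectively monomorphic).
    """

    missing_rate: float
    maf: float
    het_count: int


@dataclass
class GenotypeMatrix:
    """Sites x samples genotype codes — the common currency of all modules."""

    sites: list[VariantSite]
    samples: list[str]
    calls: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.sites), len(self.samples)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.sites)} sites x {len(self.samples)} samples"
            )
        bad = set(np.unique(self.calls)) - _VALID_CODES
        if bad:
            raise ValueError(f"invalid genotype codes {sorted(bad)}")
        keys = [s.key for s in self.sites]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (chrom, pos, ref, alt) sites")

    # -- construction ------------------------------------------------------

    @classmethod
    def from_calls(
        cls,
        sites: Sequence[VariantSite],
        samples: Sequence[str],
        calls: np.ndarray | Sequence[Sequence[int]],
    ) -> "GenotypeMatrix":
        m = cls(list(sites), list(samples), np.asarray(calls, dtype=np.int8))
        return m.sorted()

    def sorted(self) -> "GenotypeMatrix":
        """Return a copy with sites sorted by (chrom, pos, ref, alt)."""
        order = sorted(range(len(self.sites)), key=lambda i: self.sites[i].key)
        if order == list(range(len(self.sites))):
            return self
        return GenotypeMatrix(
            [self.sites[i] for i in order], list(self.samples), self.calls[order]
        )

    # -- basic accessors ---------------------------------------------------

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_index(self, sample: str) -> int:
        try:
            return self.samples.index(sample)
        except ValueError:
            raise KeyError(f"sample {sample!r} not in matrix") from None

    def site_index_by_id(self, site_id: str) -> int:
        for i, s in enumerate(self.sites):
            if s.site_id == site_id:
                return i
        raise KeyError(f"site {site_id!r} not in matrix")

    def subset_sites(self, indices: Sequence[int]) -> "GenotypeMatrix":
        idx = list(indices)
        return GenotypeMatrix([self.sites[i] for i in idx], list(self.samples),
                              self.calls[idx])

    def subset_samples(self, samples: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.sample_index(s) for s in samples]
        return GenotypeMatrix(list(self.sites), list(samples), self.calls[:, idx])

    def dosage(self, impute: bool = True) -> np.ndarray:
        """Alt-allele dosage matrix (sites x samples, float).

        Missing calls become NaN, or the per-site mean dosage if ``impute``.
        """
        d = self.calls.astype(float)
        d[self.calls == MISSING] = np.nan
        if impute:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                means = np.nanmean(d, axis=1)
            means = np.where(np.isnan(means), 0.0, means)
            nan_r, nan_c = np.where(np.isnan(d))
            d[nan_r, nan_c] = means[nan_r]
        return d

    def equal(self, other: "GenotypeMatrix") -> bool:
        return (
            self.samples == other.samples
            and self.sites == other.sites
            and np.array_equal(self.calls, other.calls)
        )


# ---------------------------------------------------------------------------
# Site statistics and filtering


def site_stats(matrix: GenotypeMatrix, site_index: int) -> SiteStats:
    """Missing rate, minor allele frequency and het count for one site."""
    calls = matrix.calls[site_index]
    n = calls.size
    missing = int(np.sum(calls == MISSING))
    het = int(np.sum(calls == HET))
    non_missing = n - missing
    if non_missing == 0:
        return SiteStats(missing_rate=1.0, maf=float("nan"), het_count=0)
    if non_missing == 1:
        return SiteStats(missing_rate=missing / n, maf=0.0, het_count=het)
    alt = 2 * int(np.sum(calls == HOM_ALT)) + het
    p = alt / (2 * non_missing)
    return SiteStats(missing_rate=missing / n, maf=min(p, 1 - p), het_count=het)


def all_site_stats(matrix: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised (missing_rate, maf, het_count) arrays over all sites."""
    c = matrix.calls
    n = matrix.n_samples
    missing = (c == MISSING).sum(axis=1)
    het = (c == HET).sum(axis=1)
    non_missing = n - missing
    alt = 2 * (c == HOM_ALT).sum(axis=1) + het
    with np.errstate(divide="ignore", invalid="ignore"):
        p = alt / (2.0 * non_missing)
    maf = np.minimum(p, 1 - p)
    maf[non_missing <= 1] = 0.0
    maf[non_missing == 0] = np.nan
    return missing / n, maf, het.astype(int)


def filter_sites(
    matrix: GenotypeMatrix,
    max_missing: float = 0.3,
    min_maf: float = 0.05,
    max_het: int | None = None,
) -> GenotypeMatrix:
    """Keep sites with missing_rate < max_missing and MAF > min_maf.

    Inequalities are strict, matching the inclusion form of the published
    pipeline ("missing rate < 0.3 and MAF > 0.05").  ``max_het`` caps the
    heterozygous-call count (inclusive) when given.  Order is preserved.
    """
    if not 0.0 <= max_missing <= 1.0:
        raise ValueError("max_missing must be in [0, 1]")
    if not 0.0 <= min_maf <= 0.5:
        raise ValueError("min_maf must be in [0, 0.5]")
    miss, maf, het = all_site_stats(matrix)
    with np.errstate(invalid="ignore"):
        keep = (miss < max_missing) & (maf > min_maf)
    keep &= ~np.isnan(maf)
    if max_het is not None:
        keep &= het <= max_het
    return matrix.subset_sites(np.flatnonzero(keep))


# ---------------------------------------------------------------------------
# VCF I/O

_GT_TO_CODE = {(0, 0): HOM_REF, (0, 1): HET, (1, 0): HET, (1, 1): HOM_ALT}


def read_vcf(path: str | Path, multiallelic: str = "reject") -> GenotypeMatrix:
    """Read a diploid VCF (GT field) into a :class:`GenotypeMatrix`.

    ``multiallelic`` is ``"reject"`` (default: error on records with more
    than one ALT) or ``"first_alt"`` (keep the first ALT allele; any call
    carrying another ALT becomes missing).
    """
    from cyvcf2 import VCF

    if multiallelic not in ("reject", "first_alt"):
        raise ValueError(f"unknown multiallelic policy {multiallelic!r}")
    path = str(path)
    try:
        vcf = VCF(path)
    except Exception as exc:  # pragma: no cover - cyvcf2 error text varies
        raise VcfParseError(f"cannot open VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    sites: list[VariantSite] = []
    rows: list[np.ndarray] = []
    for rec in vcf:
        alts = rec.ALT
        if len(alts) == 0:
            continue
        if len(alts) > 1 and multiallelic == "reject":
            raise VcfParseError(
                f"multi-allelic record at {rec.CHROM}:{rec.POS} "
                "(use multiallelic='first_alt' to split)"
            )
        site_id = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}_{rec.POS}"
        sites.append(
            VariantSite(rec.CHROM, rec.POS, site_id, rec.REF, alts[0])
        )
        row = np.full(len(samples), MISSING, dtype=np.int8)
        for j, g in enumerate(rec.genotypes):
            alleles = tuple(g[:-1])  # last entry is the phased flag
            if len(alleles) != 2:
                raise PloidyError(
                    f"non-diploid call for sample {samples[j]} at "
                    f"{rec.CHROM}:{rec.POS} (ploidy {len(alleles)})"
                )
            if -1 in alleles:
                continue
            code = _GT_TO_CODE.get(tuple(sorted(min(a, 2) for a in alleles)))
            if code is None:  # touches an ALT other than the first
                continue
            row[j] = code
        rows.append(row)
    calls = (np.vstack(rows) if rows
             else np.empty((0, len(samples)), dtype=np.int8))
    return GenotypeMatrix.from_calls(sites, samples, calls)


_CODE_TO_GT = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}


def write_vcf(matrix: GenotypeMatrix, path: str | Path,
              contig_lengths: dict[str, int] | None = None) -> None:
    """Write a minimal VCF v4.2 with GT-only FORMAT."""
    chroms: list[str] = []
    for s in matrix.sites:
        if s.chrom not in chroms:
            chroms.append(s.chrom)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=magicpanel\n")
        for c in chroms:
            if contig_lengths and c in contig_lengths:
                fh.write(f"##contig=<ID={c},length={contig_lengths[c]}>\n")
            else:
                fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(matrix.samples) + "\n")
        for i, s in enumerate(matrix.sites):
            gts = "\t".join(_CODE_TO_GT[int(c)] for c in matrix.calls[i])
            fh.write(f"{s.chrom}\t{s.pos}\t{s.site_id}\t{s.ref_allele}\t"
                     f"{s.alt_allele}\t.\tPASS\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# TSV dump

_CODE_TO_TSV = {HOM_REF: "0", HET: "1", HOM_ALT: "2", MISSING: "NA"}
_TSV_TO_CODE = {v: k for k, v in _CODE_TO_TSV.items()}


def write_tsv(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Genotype dump: site_id, chrom, pos, ref, alt then 0/1/2/NA per sample."""
    with open(path, "w") as fh:
        fh.write("site_id\tchrom\tpos\tref\talt\t" + "\t".join(matrix.samples) + "\n")
        for i, s in enumerate(matrix.sites):
            codes = "\t".join(_CODE_TO_TSV[int(c)] for c in matrix.calls[i])
            fh.write(f"{s.site_id}\t{s.chrom}\t{s.pos}\t{s.ref_allele}\t"
                     f"{s.alt_allele}\t{codes}\n")


def read_tsv(path: str | Path) -> GenotypeMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        samples = header[5:]
        sites, rows = [], []
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            sites.append(VariantSite(parts[1], int(parts[2]), parts[0],
                                     parts[3], parts[4]))
            rows.append([_TSV_TO_CODE[x] for x in parts[5:]])
    calls = (np.array(rows, dtype=np.int8) if rows
             else np.empty((0, len(samples)), dtype=np.int8))
    return GenotypeMatrix.from_calls(sites, samples, calls)
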