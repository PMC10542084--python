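"""Chip-vs-sequencing genotype concordance for single samples.

Per-site classification uses a fixed precedence so the categories are
mutually exclusive: chip-missing > indel difference > heterozygous
difference > homozygous difference > consistent.  Truth-side-missing sites
cannot be judged; they are counted as consistent-ineligible and reported in
a diagnostic column (they still enter the denominator, which is the full
panel size).  Accuracy is 100 * consistent / total with half-up rounding to
two decimals.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .genotype import GenotypeMatrix, HET, MISSING


@dataclass(frozen=True)
class ConcordanceReport:
    sample: str
    homozygous_diff: int
    heterozygous_diff: int
    indel_diff: int
    missing: int
    consistent: int
    total: int
    truth_missing: int  # diagnostic; not one of the four printed categories

    @property
    def accuracy(self) -> float:
        return accuracy(self.consistent, self.total)

    def category_sum(self) -> int:
        return (self.homozygous_diff + self.heterozygous_diff + self.indel_diff
                + self.missing + self.consistent + self.truth_missing)


def accuracy(consistent: int, total: int) -> float:
    """100 * consistent / total, half-up to 2 decimals (as printed)."""
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= consistent <= total:
        raise ValueError("consistent must be in [0, total]")
    pct = Decimal(100 * consistent) / Decimal(total)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def compare_callsets(chip: GenotypeMatrix, truth: GenotypeMatrix,
                     sample: str) -> ConcordanceReport:
    """Classify every shared site for one sample, chip against truth."""
    chip_keys = [s.key for s in chip.sites]
    truth_keys = [s.key for s in truth.sites]
    if chip_keys != truth_keys:
        diff = set(chip_keys) ^ set(truth_keys)
        raise ValueError(
            f"site universes disagree at {len(diff)} sites, "
            f"e.g. {sorted(diff)[:3]}")
    a = chip.calls[:, chip.sample_index(sample)]
    b = truth.calls[:, truth.sample_index(sample)]
    is_indel = np.array([s.variant_class == "INDEL" for s in chip.sites])

    chip_missing = a == MISSING
    truth_missing = (~chip_missing) & (b == MISSING)
    judged = ~chip_missing & ~truth_missing
    differ = judged & (a != b)
    indel_diff = differ & is_indel
    het_diff = differ & ~is_indel & ((a == HET) | (b == HET))
    hom_diff = differ & ~is_indel & ~((a == HET) | (b == HET))
    consistent = judged & (a == b)
    return ConcordanceReport(
        sample=sample,
        homozygous_diff=int(hom_diff.sum()),
        heterozygous_diff=int(het_diff.sum()),
        indel_diff=int(indel_diff.sum()),
        missing=int(chip_missing.sum()),
        consistent=int(consistent.sum()),
        total=int(a.size),
        truth_missing=int(truth_missing.sum()),
    )


def concordance_table(chip: GenotypeMatrix, truth: GenotypeMatrix,
                      samples: list[str] | None = None):
    """One report row per sample, mirroring the published comparison table."""
    import pandas as pd

    if samples is None:
        samples = [s for s in chip.samples if s in truth.samples]
    rows = []
    for s in samples:
        r = compare_callsets(chip, truth, s)
        rows.append((s, r.homozygous_diff, r.heterozygous_diff, r.indel_diff,
                     r.missing, r.consistent, r.truth_missing, r.accuracy))
    return pd.DataFrame(rows, columns=[
        "sample", "homozygous_diff", "heterozygous_diff", "indel_diff",
        "missing", "consistent", "truth_missing", "accuracy_pct"])
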