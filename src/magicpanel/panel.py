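"""Founder-diagnostic site classification and liquid-chip panel selection.

A diagnostic ("1:7") site is one where a single founder line is homozygous
for one allele and the remaining seven are homozygous for the other; "2:6"
sites split the founders 2 vs 6.  Panels are built from 1:7 and 2:6 sites
only, allocated per chromosome proportionally to physical length and then
picked for even physical spacing within each chromosome.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .genotype import HET, HOM_ALT, HOM_REF, MISSING, GenotypeMatrix, VariantSite

# Pattern labels
MONOMORPHIC = "MONOMORPHIC"
P1_7 = "P1_7"
P2_6 = "P2_6"
P3_5 = "P3_5"
P4_4 = "P4_4"
HET_PRESENT = "HET_PRESENT"
MISSING_PRESENT = "MISSING_PRESENT"

_K_TO_LABEL = {0: MONOMORPHIC, 1: P1_7, 2: P2_6, 3: P3_5, 4: P4_4}


@dataclass(frozen=True)
class SitePattern:
    """Founder-split classification of a site over the eight founders."""

    label: str
    carrier_founders: frozenset[str] = frozenset()


@dataclass(frozen=True)
class ProbeRecord:
    """Capture-probe flanks around one panel site (both directions)."""

    site_id: str
    forward_flank: str
    reverse_flank: str
    flank_length: int


@dataclass
class PanelSpec:
    """A selected panel: diagnostic sites with patterns plus per-chromosome quotas."""

    selected_sites: list[tuple[VariantSite, SitePattern]]
    quotas: dict[str, int]
    total_target: int
    probes: list[ProbeRecord] = field(default_factory=list)

    @property
    def n_selected(self) -> int:
        return len(self.selected_sites)

    def counts_by_chrom(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for site, _ in self.selected_sites:
            out[site.chrom] = out.get(site.chrom, 0) + 1
        return out

    def pattern_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for _, pat in self.selected_sites:
            out[pat.label] = out.get(pat.label, 0) + 1
        return out


# ---------------------------------------------------------------------------
# Pattern classification


def classify_founder_pattern(founder_calls, founder_labels=None) -> SitePattern:
    """Classify one site's eight founder genotype codes.

    Any missing call dominates (MISSING_PRESENT), then any heterozygous call
    (HET_PRESENT); otherwise the minority-homozygote count k in 0..4 gives
    MONOMORPHIC / P1_7 / P2_6 / P3_5 / P4_4 with the minority carriers
    recorded.  A 4:4 split has no strict minority; the HOM_ALT side is
    recorded as carriers by convention.
    """
    calls = list(founder_calls)
    if len(calls) != 8:
        raise ValueError(f"expected 8 founder calls, got {len(calls)}")
    if founder_labels is None:
        founder_labels = [f"F{i + 1}" for i in range(8)]
    if any(c == MISSING for c in calls):
        return SitePattern(MISSING_PRESENT)
    if any(c == HET for c in calls):
        return SitePattern(HET_PRESENT)
    alt_carriers = [l for l, c in zip(founder_labels, calls) if c == HOM_ALT]
    ref_carriers = [l for l, c in zip(founder_labels, calls) if c == HOM_REF]
    if len(alt_carriers) <= len(ref_carriers):
        minority = alt_carriers
    else:
        minority = ref_carriers
    k = len(minority)
    if k == 0:
        return SitePattern(MONOMORPHIC)
    return SitePattern(_K_TO_LABEL[k], frozenset(minority))


def classify_all(founders: GenotypeMatrix) -> list[SitePattern]:
    """Pattern for every site of an 8-founder matrix."""
    if founders.n_samples != 8:
        raise ValueError(f"expected 8 founder samples, got {founders.n_samples}")
    return [
        classify_founder_pattern(founders.calls[i], founders.samples)
        for i in range(founders.n_sites)
    ]


def unique_site_counts(founders: GenotypeMatrix) -> dict[str, int]:
    """Number of 1:7 sites carried by each founder (partitions the 1:7 sites)."""
    counts = {s: 0 for s in founders.samples}
    for pat in classify_all(founders):
        if pat.label == P1_7:
            (carrier,) = pat.carrier_founders
            counts[carrier] += 1
    return counts


def pairwise_polymorphic_counts(founders: GenotypeMatrix) -> dict[frozenset, int]:
    """Sites with opposite non-missing homozygotes, for each of the 28 founder pairs."""
    if founders.n_samples != 8:
        raise ValueError(f"expected 8 founder samples, got {founders.n_samples}")
    c = founders.calls
    hom_ref = c == HOM_REF
    hom_alt = c == HOM_ALT
    out: dict[frozenset, int] = {}
    names = founders.samples
    for i in range(8):
        for j in range(i + 1, 8):
            n = int(np.sum((hom_ref[:, i] & hom_alt[:, j])
                           | (hom_alt[:, i] & hom_ref[:, j])))
            out[frozenset((names[i], names[j]))] = n
    return out


# ---------------------------------------------------------------------------
# Quota allocation and even spacing


def _largest_remainder(weights: dict[str, float], total: int) -> dict[str, int]:
    keys = sorted(weights)
    wsum = sum(weights[k] for k in keys)
    if wsum <= 0:
        return {k: 0 for k in keys}
    exact = {k: total * weights[k] / wsum for k in keys}
    base = {k: math.floor(exact[k]) for k in keys}
    leftover = total - sum(base.values())
    by_rem = sorted(keys, key=lambda k: (-(exact[k] - base[k]), k))
    for k in by_rem[:leftover]:
        base[k] += 1
    return base


def allocate_quota(
    chrom_lengths: dict[str, int],
    candidate_counts: dict[str, int],
    total: int,
) -> dict[str, int]:
    """Per-chromosome panel quotas, proportional to length.

    Largest-remainder apportionment over chromosome lengths, capped at
    candidate availability; the surplus from capped chromosomes is
    re-apportioned among the others until it is placed or no capacity
    remains.  Sum of quotas = min(total, total candidates).
    """
    chroms = [c for c in chrom_lengths if candidate_counts.get(c, 0) > 0]
    if not chroms:
        warnings.warn("no candidate sites on any chromosome; empty quota")
        return {}
    total = min(total, sum(candidate_counts.get(c, 0) for c in chroms))
    quotas = {c: 0 for c in chroms}
    remaining = total
    open_set = set(chroms)
    while remaining > 0 and open_set:
        alloc = _largest_remainder(
            {c: float(chrom_lengths[c]) for c in open_set}, remaining
        )
        remaining = 0
        for c, q in alloc.items():
            cap = candidate_counts[c] - quotas[c]
            take = min(q, cap)
            quotas[c] += take
            remaining += q - take
            if quotas[c] >= candidate_counts[c]:
                open_set.discard(c)
    return quotas


def select_even_spacing(
    candidates: list[tuple[VariantSite, SitePattern]],
    quota: int,
    chrom_length: int,
) -> list[tuple[VariantSite, SitePattern]]:
    """Pick ``quota`` candidates spread evenly along one chromosome.

    The chromosome is partitioned into ``quota`` equal windows; within each
    window the pick priority is 1:7 before 2:6, then nearest the window
    midpoint, then smaller position.  Windows without candidates borrow the
    globally nearest unselected candidate.  Fully deterministic.
    """
    if quota <= 0:
        return []
    if any(candidates[i][0].pos > candidates[i + 1][0].pos
           for i in range(len(candidates) - 1)):
        raise ValueError("candidates must be sorted by position")
    if quota >= len(candidates):
        if quota > len(candidates):
            warnings.warn(
                f"quota {quota} exceeds {len(candidates)} candidates; taking all"
            )
        return list(candidates)

    width = chrom_length / quota
    taken: set[int] = set()
    pat_rank = {P1_7: 0, P2_6: 1}
    empty_windows: list[float] = []
    for w in range(quota):
        lo, hi = w * width + 1, (w + 1) * width
        mid = (lo + hi) / 2
        in_win = [i for i, (s, _) in enumerate(candidates)
                  if lo <= s.pos <= hi and i not in taken]
        if not in_win:
            empty_windows.append(mid)
            continue
        best = min(
            in_win,
            key=lambda i: (
                pat_rank.get(candidates[i][1].label, 2),
                abs(candidates[i][0].pos - mid),
                candidates[i][0].pos,
            ),
        )
        taken.add(best)
    for mid in empty_windows:
        free = [i for i in range(len(candidates)) if i not in taken]
        if not free:
            break
        best = min(free, key=lambda i: (abs(candidates[i][0].pos - mid),
                                        candidates[i][0].pos))
        taken.add(best)
    return [candidates[i] for i in sorted(taken)]


def build_panel(
    founders: GenotypeMatrix,
    chrom_lengths: dict[str, int],
    total: int,
    target_ratio: float = 3.0,
) -> PanelSpec:
    """Select a diagnostic panel of ~``total`` sites from founder genotypes.

    Only clean 1:7 / 2:6 sites (all founders homozygous, none missing) are
    candidates.  ``target_ratio`` is the desired 1:7 : 2:6 ratio, applied
    within a chromosome only when candidates exceed its quota.
    """
    patterns = classify_all(founders)
    by_chrom: dict[str, list[tuple[VariantSite, SitePattern]]] = {}
    for site, pat in zip(founders.sites, patterns):
        if pat.label in (P1_7, P2_6):
            by_chrom.setdefault(site.chrom, []).append((site, pat))
    counts = {c: len(v) for c, v in by_chrom.items()}
    quotas = allocate_quota(chrom_lengths, counts, total)
    selected: list[tuple[VariantSite, SitePattern]] = []
    for chrom in sorted(quotas):
        cands = by_chrom[chrom]
        quota = quotas[chrom]
        n17 = sum(1 for _, p in cands if p.label == P1_7)
        if len(cands) > quota and n17 > quota * target_ratio / (target_ratio + 1):
            # thin the 1:7 excess so the global mix approaches target_ratio
            want17 = int(round(quota * target_ratio / (target_ratio + 1)))
            keep17 = {id(t) for t in _thin_evenly(
                [t for t in cands if t[1].label == P1_7], want17)}
            cands = [t for t in cands
                     if t[1].label == P2_6 or id(t) in keep17]
        selected.extend(select_even_spacing(cands, quota, chrom_lengths[chrom]))
    selected.sort(key=lambda t: t[0].key)
    return PanelSpec(selected, quotas, total)


def _thin_evenly(items: list, n: int) -> list:
    if n >= len(items):
        return items
    idx = np.linspace(0, len(items) - 1, n).round().astype(int)
    return [items[i] for i in sorted(set(idx.tolist()))]


# ---------------------------------------------------------------------------
# Probe flanks


_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def extract_probe_flanks(reference, site: VariantSite, flank: int,
                         on_edge: str = "error") -> ProbeRecord:
    """Flanking sequence ``reference[pos-flank ... pos+flank]`` (1-based, inclusive).

    ``reference`` is a mapping chrom -> sequence (e.g. a ``pyfaidx.Fasta``).
    ``on_edge``: ``"error"`` raises when the window leaves the contig,
    ``"truncate"`` warns and clips.
    """
    seq = reference[site.chrom]
    length = len(seq)
    lo, hi = site.pos - flank, site.pos + flank
    if lo < 1 or hi > length:
        if on_edge == "error":
            raise ValueError(
                f"flank window [{lo}, {hi}] outside contig {site.chrom} "
                f"(length {length})"
            )
        warnings.warn(f"truncated flank at {site.site_id}")
        lo, hi = max(lo, 1), min(hi, length)
    fwd = str(seq[lo - 1:hi]).upper()
    return ProbeRecord(site.site_id, fwd, reverse_complement(fwd), flank)


# ---------------------------------------------------------------------------
# Density report


def density_report(panel_counts: dict[str, int],
                   chrom_lengths: dict[str, int]):
    """Per-chromosome marker density table.

    ``rate`` is floor(length / variants) — bp per marker, integer division
    as in the published panel table — with a final Total row.  Chromosomes
    with zero variants get a missing rate.
    """
    import pandas as pd

    if not panel_counts or sum(panel_counts.values()) == 0:
        raise ValueError("empty panel")
    rows = []
    for chrom in sorted(chrom_lengths):
        length = chrom_lengths[chrom]
        n = panel_counts.get(chrom, 0)
        rate = length // n if n > 0 else pd.NA
        rows.append((chrom, length, n, rate))
    tot_len = sum(chrom_lengths.values())
    tot_n = sum(panel_counts.get(c, 0) for c in chrom_lengths)
    rows.append(("Total", tot_len, tot_n, tot_len // tot_n))
    return pd.DataFrame(rows, columns=["chromosome", "length", "variants", "rate"])
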