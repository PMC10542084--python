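"""Half-allele funnel mating combinatorics for multi-parent populations.

A cross is a binary pairing tree over founder labels written in slash
notation: ``A/B`` (2-way), ``A/B//C/D`` (4-way), ``A/E//D/G///B/C//F/H``
(8-way) — more slashes bind later.  The half-allele constraint means no
founder appears more than once within a cross, and reciprocal crosses are
identified (``A/B`` == ``B/A``).

For eight founders the full enumeration gives 28 two-way, 210 four-way and
315 eight-way crosses; the 315 fall into 35 classes of 9 keyed by the
unordered quartet partition of the founders, and the advance subset takes
one representative per class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable, Sequence

import numpy as np

#: structure: a founder label (str) or a pair (left, right) of structures
Structure = object


class CrossParseError(ValueError):
    """Malformed slash notation or repeated founder."""


def _founders_of(struct) -> frozenset:
    if isinstance(struct, str):
        return frozenset((struct,))
    return _founders_of(struct[0]) | _founders_of(struct[1])


def _canonical(struct):
    """Order each pair so the lexicographically smaller founder set leads."""
    if isinstance(struct, str):
        return struct
    left, right = _canonical(struct[0]), _canonical(struct[1])
    if tuple(sorted(_founders_of(left))) > tuple(sorted(_founders_of(right))):
        left, right = right, left
    return (left, right)


def _depth(struct) -> int:
    if isinstance(struct, str):
        return 0
    return 1 + max(_depth(struct[0]), _depth(struct[1]))


@dataclass(frozen=True)
class Cross:
    """A funnel cross: recursive pairing tree of depth 1-3 over distinct founders."""

    structure: tuple

    def __post_init__(self) -> None:
        labels = _flatten(self.structure)
        if len(labels) != len(set(labels)):
            raise CrossParseError(
                f"founder repeated in cross {labels} (half-allele rule)")
        object.__setattr__(self, "structure", _canonical(self.structure))

    @property
    def founder_set(self) -> frozenset:
        return _founders_of(self.structure)

    @property
    def n_way(self) -> int:
        return len(self.founder_set)

    @property
    def notation(self) -> str:
        return format_cross(self)

    @property
    def quartet_partition(self) -> frozenset:
        """For an 8-way cross, the unordered pair of founder quartets."""
        if _depth(self.structure) != 3:
            raise ValueError("quartet partition defined for 8-way crosses only")
        left, right = self.structure
        return frozenset((_founders_of(left), _founders_of(right)))

    def __str__(self) -> str:
        return self.notation

    def __lt__(self, other: "Cross") -> bool:
        return self.notation < other.notation


def _flatten(struct) -> list:
    if isinstance(struct, str):
        return [struct]
    return _flatten(struct[0]) + _flatten(struct[1])


def format_cross(cross: Cross) -> str:
    """Canonical slash notation (separator depth grows toward the root)."""
    def fmt(struct, level: int) -> str:
        if isinstance(struct, str):
            return struct
        sep = "/" * level
        return fmt(struct[0], level - 1) + sep + fmt(struct[1], level - 1)

    return fmt(cross.structure, _depth(cross.structure))


def parse_cross(notation: str) -> Cross:
    """Parse slash notation; inverse of :func:`format_cross` on canonical forms."""
    def parse(text: str, level: int):
        if level == 0:
            if not text or "/" in text:
                raise CrossParseError(f"bad founder label {text!r}")
            return text
        sep = "/" * level
        # split on the exact separator (not a longer run of slashes)
        parts, cur, i = [], "", 0
        while i < len(text):
            if text.startswith(sep, i) and not text.startswith("/" + sep, i) \
                    and (i == 0 or text[i - 1] != "/"):
                parts.append(cur)
                cur = ""
                i += level
            else:
                cur += text[i]
                i += 1
        parts.append(cur)
        if len(parts) == 1:
            return parse(text, level - 1)
        if len(parts) != 2:
            raise CrossParseError(f"expected one {sep!r} separator in {text!r}")
        left, right = (parse(parts[0], level - 1), parse(parts[1], level - 1))
        # separator depth must match subtree depth (reject e.g. "A//B")
        if max(_depth(left), _depth(right)) != level - 1:
            raise CrossParseError(
                f"separator {sep!r} does not match subtree depth in {text!r}")
        return (left, right)

    if not notation or notation.startswith("/") or notation.endswith("/"):
        raise CrossParseError(f"malformed cross notation {notation!r}")
    struct = parse(notation, 3)
    if isinstance(struct, str):
        raise CrossParseError(f"not a cross: {notation!r}")
    return Cross(struct)


# ---------------------------------------------------------------------------
# Enumeration


def _check_founders(founders: Sequence[str]) -> list:
    labels = list(founders)
    if len(labels) != len(set(labels)):
        raise ValueError("duplicate founder labels")
    if len(labels) < 2:
        raise ValueError("need at least 2 founders")
    return sorted(labels)


def enumerate_two_way(founders: Sequence[str]) -> list:
    """All unordered founder pairs: C(n,2) crosses in canonical order."""
    labels = _check_founders(founders)
    return [Cross((a, b)) for a, b in combinations(labels, 2)]


def enumerate_four_way(two_ways: Sequence[Cross]) -> list:
    """All founder-disjoint unordered pairs of 2-way crosses."""
    out = []
    for c1, c2 in combinations(sorted(two_ways), 2):
        if c1.founder_set & c2.founder_set:
            continue
        out.append(Cross((c1.structure, c2.structure)))
    return sorted(set(out))


def enumerate_eight_way(four_ways: Sequence[Cross]) -> list:
    """All founder-disjoint unordered pairs of 4-way crosses."""
    out = []
    for c1, c2 in combinations(sorted(four_ways), 2):
        if c1.founder_set & c2.founder_set:
            continue
        out.append(Cross((c1.structure, c2.structure)))
    return sorted(set(out))


def partition_classes(eight_ways: Sequence[Cross]) -> dict:
    """Group 8-way crosses by their unordered quartet partition.

    For 8 founders the full set of 315 splits into 35 classes of 9 (three
    internal pairings per quartet on each side).  Raises if the input is
    not the complete enumeration.
    """
    classes: dict[frozenset, list] = {}
    for c in eight_ways:
        classes.setdefault(c.quartet_partition, []).append(c)
    for key in classes:
        classes[key] = sorted(classes[key])
    founders = sorted(set().union(*(c.founder_set for c in eight_ways)))
    expected = _expected_class_count(len(founders))
    sizes = {len(v) for v in classes.values()}
    if len(classes) != expected or sizes != {9}:
        missing = _missing_crosses(founders, eight_ways)
        raise ValueError(
            f"incomplete 8-way enumeration; missing {len(missing)} crosses, "
            f"e.g. {[str(m) for m in missing[:3]]}"
        )
    return classes


def _expected_class_count(n: int) -> int:
    from math import comb

    return comb(n, n // 2) // 2


def _missing_crosses(founders, eight_ways) -> list:
    full = enumerate_eight_way(
        enumerate_four_way(enumerate_two_way(founders)))
    have = set(eight_ways)
    return [c for c in full if c not in have]


@dataclass
class FunnelPlan:
    """Complete funnel design: all stages, class partition, advance subset."""

    founders: list
    stage1: list
    stage2: list
    stage3: list
    classes: dict
    subset: list
    selfing_generations: int = 2
    n_per_cross: int = 200

    @property
    def target_population(self) -> int:
        return len(self.subset) * self.n_per_cross


def select_subset(classes: dict, chooser: str | Callable = "first",
                  rng: np.random.Generator | None = None) -> list:
    """One representative 8-way cross per class.

    ``chooser``: ``"first"`` (lexicographically first, the default),
    ``"random"`` (uses ``rng``), or a callable class-list -> cross.
    """
    def _key(k):
        if isinstance(k, frozenset):
            return str(sorted(tuple(sorted(q)) for q in k))
        return str(k)

    keys = sorted(classes, key=_key)
    out = []
    for k in keys:
        members = sorted(classes[k])
        if chooser == "first":
            out.append(members[0])
        elif chooser == "random":
            if rng is None:
                raise ValueError("random chooser needs an rng")
            out.append(members[int(rng.integers(len(members)))])
        else:
            out.append(chooser(members))
    return out


def design_funnel(founders: Sequence[str], n_per_cross: int = 200,
                  selfing_generations: int = 2,
                  chooser: str | Callable = "first",
                  rng: np.random.Generator | None = None) -> FunnelPlan:
    """Full funnel plan for an even number of founders (n >= 4)."""
    labels = _check_founders(founders)
    if len(labels) % 2 or len(labels) < 4:
        raise ValueError("funnel design needs an even number >= 4 of founders")
    s1 = enumerate_two_way(labels)
    s2 = enumerate_four_way(s1)
    s3 = enumerate_eight_way(s2) if len(labels) >= 8 else s2
    classes = partition_classes(s3) if len(labels) == 8 else {
        c.notation: [c] for c in s3}
    subset = select_subset(classes, chooser, rng) if len(labels) == 8 else list(s3)
    return FunnelPlan(labels, s1, s2, s3, classes, subset,
                      selfing_generations, n_per_cross)


def pedigree_table(plan: FunnelPlan):
    """TSV-ready pedigree: cross_id, notation, stage, parent notations."""
    import pandas as pd

    rows = []
    stages = [("2-way", plan.stage1), ("4-way", plan.stage2)]
    if plan.stage3 is not plan.stage2:
        stages.append(("8-way", plan.stage3))
    for stage, crosses in stages:
        for i, c in enumerate(crosses):
            left, right = c.structure
            p1 = left if isinstance(left, str) else format_cross(Cross(left))
            p2 = right if isinstance(right, str) else format_cross(Cross(right))
            rows.append((f"{stage}_{i + 1:03d}", c.notation, stage, p1, p2))
    return pd.DataFrame(
        rows, columns=["cross_id", "notation", "stage", "parent1", "parent2"])
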