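"""Set algebra across peptidomes: upset-style pattern counts and overlaps."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence


@dataclass
class UpsetTable:
    """Exclusive membership-pattern counts over a declared set list.

    ``groups`` maps a sorted tuple of set names (the peptides present in
    exactly those sets) to a count; the counts partition the universe.
    """

    groups: dict[tuple[str, ...], int]
    universe: int
    names: tuple[str, ...]

    def ordered_patterns(self) -> list[tuple[tuple[str, ...], int]]:
        """Patterns by descending count, then pattern name tuple."""
        return sorted(self.groups.items(), key=lambda kv: (-kv[1], kv[0]))


def intersection_counts(
    sets: Mapping[str, Iterable[str]] | Sequence[tuple[str, Iterable[str]]],
) -> UpsetTable:
    """Exact exclusive-pattern counts over >= 2 named sets.

    Each element is counted once, under the full pattern of sets that
    contain it.
    """
    if not isinstance(sets, Mapping):
        names = [name for name, _ in sets]
        if len(names) != len(set(names)):
            raise ValueError(f"duplicate set names: {names}")
        sets = dict(sets)
    if len(sets) < 2:
        raise ValueError("need at least 2 named sets")
    frozen = {name: set(members) for name, members in sets.items()}
    membership: dict[str, list[str]] = {}
    for name, members in frozen.items():
        for item in members:
            membership.setdefault(item, []).append(name)
    groups: dict[tuple[str, ...], int] = {}
    for item, where in membership.items():
        pattern = tuple(sorted(where))
        groups[pattern] = groups.get(pattern, 0) + 1
    return UpsetTable(
        groups=groups,
        universe=len(membership),
        names=tuple(frozen),
    )


def overlap_fraction(a: Iterable[str], b: Iterable[str]) -> tuple[int, int]:
    """Shared count and integer percent of the first set shared with the second.

    The percent denominator is ``|a|`` (asymmetric); rounding is half-up to
    the nearest integer.  An empty first set yields percent 0 with a warning.
    """
    a, b = set(a), set(b)
    shared = len(a & b)
    if not a:
        warnings.warn("overlap_fraction: empty first set, reporting 0%")
        return shared, 0
    percent = int(
        (Decimal(100 * shared) / Decimal(len(a))).quantize(
            Decimal(1), rounding=ROUND_HALF_UP
        )
    )
    return shared, percent


def overlap_fraction_2dp(a: Iterable[str], b: Iterable[str]) -> tuple[int, float]:
    """As :func:`overlap_fraction` but with the percent at two decimals."""
    a, b = set(a), set(b)
    shared = len(a & b)
    if not a:
        warnings.warn("overlap_fraction: empty first set, reporting 0%")
        return shared, 0.0
    percent = float(
        (Decimal(100 * shared) / Decimal(len(a))).quantize(
            Decimal("0.01"), rounding=ROUND_HALF_UP
        )
    )
    return shared, percent
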