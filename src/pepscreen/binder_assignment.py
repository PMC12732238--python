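"""Classify peptides by %rank and summarize binder length distributions.

Peptides are assigned to the allele with the minimal %rank ("best binder"
analysis); strong and weak binders are called with inclusive cutoffs at
0.5% and 2% rank by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

from pepscreen.peptidome_io import Immunopeptidome, PeptideRecord, unique_records

STRONG_CUTOFF = 0.5
WEAK_CUTOFF = 2.0

STRONG = "strong"
WEAK = "weak"
NON_BINDER = "non_binder"

C0602 = "HLA-C*06:02"

#: lengths eligible for binder length statistics
BINDER_LENGTHS = (8, 9, 10, 11)


def classify_rank(
    rank: float, strong_cut: float = STRONG_CUTOFF, weak_cut: float = WEAK_CUTOFF
) -> str:
    """Map a %rank to ``strong`` / ``weak`` / ``non_binder``.

    Cutoffs are inclusive on the binder side: ``rank <= strong_cut`` is
    strong, ``strong_cut < rank <= weak_cut`` is weak.
    """
    if rank < 0:
        raise ValueError(f"%rank must be non-negative, got {rank!r}")
    if not 0 < strong_cut < weak_cut:
        raise ValueError(
            f"require 0 < strong_cut < weak_cut, got {strong_cut!r}, {weak_cut!r}"
        )
    if rank <= strong_cut:
        return STRONG
    if rank <= weak_cut:
        return WEAK
    return NON_BINDER


@dataclass(frozen=True)
class BinderCall:
    """Best-binder assignment: allele (or None), category, assigned %rank."""

    allele: str | None
    category: str
    rank: float


def best_binder(
    record: PeptideRecord,
    alleles: Sequence[str],
    strong_cut: float = STRONG_CUTOFF,
    weak_cut: float = WEAK_CUTOFF,
) -> BinderCall:
    """Assign *record* to its minimal-%rank allele among *alleles*.

    Ties are broken by allele-list order (first wins).  A record with no
    rank among the given alleles, or whose minimal rank exceeds the weak
    cutoff, is a non-binder with allele ``None``.
    """
    best_allele: str | None = None
    best_rank = math.inf
    for allele in alleles:
        rank = record.ranks.get(allele)
        if rank is not None and rank < best_rank:
            best_allele, best_rank = allele, rank
    if best_allele is None:
        return BinderCall(None, NON_BINDER, math.inf)
    category = classify_rank(best_rank, strong_cut, weak_cut)
    if category == NON_BINDER:
        return BinderCall(None, NON_BINDER, best_rank)
    return BinderCall(best_allele, category, best_rank)


def c0602_binder_set(
    p: Immunopeptidome,
    allele: str = C0602,
    strong_cut: float = STRONG_CUTOFF,
    weak_cut: float = WEAK_CUTOFF,
) -> set[str]:
    """Unique sequences whose best-binder allele is *allele* (strong or weak).

    A peptide that binds the target allele but binds another allele more
    strongly is excluded (best-binder semantics).  Duplicate rows are
    collapsed to their minimum-q_value representative first.
    """
    if allele not in p.alleles:
        raise PeptidomeConfigError(
            f"peptidome {p.name!r} does not carry ranks for {allele!r}"
        )
    out: set[str] = set()
    for seq, rec in unique_records(p).items():
        call = best_binder(rec, p.alleles, strong_cut, weak_cut)
        if call.allele == allele:
            out.add(seq)
    return out


class PeptidomeConfigError(ValueError):
    """Requested allele is not part of the peptidome's declared panel."""


def _round_half_up(value: Decimal, places: int = 2) -> float:
    return float(value.quantize(Decimal(10) ** -places, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class LengthDistribution:
    """Counts and half-up-rounded percent shares per peptide length."""

    counts: Mapping[int, int]
    percents: Mapping[int, float] = field(default_factory=dict)

    @classmethod
    def from_counts(cls, counts: Mapping[int, int]) -> "LengthDistribution":
        total = sum(counts.values())
        if total == 0:
            percents = {length: 0.0 for length in counts}
        else:
            percents = {
                length: _round_half_up(Decimal(100 * n) / Decimal(total))
                for length, n in counts.items()
            }
        return cls(counts=dict(counts), percents=percents)

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def length_distribution(
    sequences: Iterable[str], lengths: Sequence[int] = BINDER_LENGTHS
) -> LengthDistribution:
    """Length distribution of a sequence set over the listed lengths.

    Percent shares use the listed lengths as denominator and round half-up
    to two decimals; sequences of other lengths are ignored here and should
    be reported separately.
    """
    counts = {length: 0 for length in lengths}
    for seq in sequences:
        if len(seq) in counts:
            counts[len(seq)] += 1
    return LengthDistribution.from_counts(counts)


def non_binder_fraction(
    p: Immunopeptidome,
    strong_cut: float = STRONG_CUTOFF,
    weak_cut: float = WEAK_CUTOFF,
) -> float:
    """Percent of unique peptides that map to no allele (best rank > weak cutoff)."""
    uniq = unique_records(p)
    if not uniq:
        return 0.0
    n_non = sum(
        best_binder(rec, p.alleles, strong_cut, weak_cut).category == NON_BINDER
        for rec in uniq.values()
    )
    return _round_half_up(Decimal(100 * n_non) / Decimal(len(uniq)))
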