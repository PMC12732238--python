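"""Read, validate, filter and deduplicate immunopeptidome tables.

A peptidome table is delimited text (TSV by default, comma accepted) with a
header row and at least the columns ``sequence`` and ``q_value``.  An
optional ``category`` column carries the upstream identification category,
and any further column whose header names an HLA allele (e.g.
``HLA-C*06:02``) holds that allele's %rank for the row's peptide.
Nonstandard headers are remapped through a *dialect* mapping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)

#: canonical column names; everything else is treated as an allele %rank column
_CANONICAL = ("sequence", "q_value", "category", "cell_line")


class PeptideTableError(ValueError):
    """Raised for unusable table layouts (missing mandatory columns)."""


def is_valid_sequence(sequence: str) -> bool:
    """True if *sequence* is a non-empty string over the 20-letter alphabet."""
    return bool(sequence) and set(sequence) <= _AA_SET


@dataclass(frozen=True)
class PeptideRecord:
    """One identified HLA ligand.

    Attributes
    ----------
    sequence:
        Upper-case amino-acid string (ACDEFGHIKLMNPQRSTVWY).
    q_value:
        Identification q-value, a fraction in [0, 1].
    category:
        Free-text identification category from the upstream search.
    ranks:
        Mapping allele name -> %rank (percent, non-negative).
    cell_line:
        Source cell-line identifier.
    """

    sequence: str
    q_value: float
    category: str = ""
    ranks: Mapping[str, float] = field(default_factory=dict)
    cell_line: str = ""

    def __post_init__(self) -> None:
        if not is_valid_sequence(self.sequence):
            raise ValueError(f"invalid peptide sequence: {self.sequence!r}")
        if not 0.0 <= self.q_value <= 1.0:
            raise ValueError(f"q_value out of [0,1]: {self.q_value!r}")
        for allele, rank in self.ranks.items():
            if rank < 0:
                raise ValueError(f"negative %rank for {allele}: {rank!r}")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class Immunopeptidome:
    """A named collection of :class:`PeptideRecord` with its allele panel."""

    name: str
    alleles: list[str] = field(default_factory=list)
    erap1: str | None = None
    records: list[PeptideRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("peptidome name must be non-empty")
        for rec in self.records:
            unknown = set(rec.ranks) - set(self.alleles)
            if unknown:
                raise ValueError(
                    f"record {rec.sequence} has ranks for undeclared "
                    f"alleles: {sorted(unknown)}"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


@dataclass(frozen=True, order=True)
class ProteomeHit:
    """Exact occurrence of a peptide in a protein, 0-based half-open."""

    protein_id: str
    start: int
    end: int
    peptide: str


def read_peptide_table(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    name: str | None = None,
    cell_line: str | None = None,
) -> Immunopeptidome:
    """Load a delimited peptide table into a validated :class:`Immunopeptidome`.

    *dialect* maps actual file headers to canonical names (``sequence``,
    ``q_value``, ``category``) or to allele names.  Rows violating the
    alphabet or range invariants are dropped with a row-indexed warning;
    input order is preserved for surviving rows.

    Raises
    ------
    PeptideTableError
        If a mandatory column cannot be resolved.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    try:
        df = pd.read_csv(path, sep=sep, dtype=str)
    except pd.errors.EmptyDataError:
        warnings.warn(f"{path}: empty peptide table")
        return Immunopeptidome(name=name or path.stem)

    if dialect:
        df = df.rename(columns=dict(dialect))
    for col in ("sequence", "q_value"):
        if col not in df.columns:
            raise PeptideTableError(f"{path}: mandatory column {col!r} missing")

    allele_cols = [c for c in df.columns if c not in _CANONICAL]
    line = cell_line or (
        str(df["cell_line"].iloc[0]) if "cell_line" in df.columns and len(df) else ""
    )

    records: list[PeptideRecord] = []
    bad: list[tuple[int, str]] = []
    for idx, row in df.iterrows():
        seq = str(row["sequence"]).strip().upper()
        try:
            q = float(row["q_value"])
            ranks = {
                a: float(row[a])
                for a in allele_cols
                if pd.notna(row[a]) and str(row[a]).strip() != ""
            }
            rec = PeptideRecord(
                sequence=seq,
                q_value=q,
                category=str(row.get("category", "") or ""),
                ranks=ranks,
                cell_line=line,
            )
        except (ValueError, TypeError) as exc:
            bad.append((int(idx), str(exc)))
            continue
        records.append(rec)

    if bad:
        detail = "; ".join(f"row {i}: {msg}" for i, msg in bad[:10])
        warnings.warn(f"{path}: rejected {len(bad)} row(s): {detail}")
    if not records and len(df) == 0:
        warnings.warn(f"{path}: empty peptide table")

    return Immunopeptidome(
        name=name or path.stem, alleles=allele_cols, records=records
    )


def write_peptide_table(p: Immunopeptidome, path: str | Path) -> None:
    """Write a peptidome back to delimited text (lossless round-trip)."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    rows = []
    for rec in p.records:
        row = {
            "sequence": rec.sequence,
            "q_value": rec.q_value,
            "category": rec.category,
            "cell_line": rec.cell_line,
        }
        for allele in p.alleles:
            row[allele] = rec.ranks.get(allele, "")
        rows.append(row)
    cols = ["sequence", "q_value", "category", "cell_line", *p.alleles]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep=sep, index=False)


def filter_by_fdr(
    p: Immunopeptidome, threshold: float, per_category: bool = False
) -> Immunopeptidome:
    """Keep records with ``q_value <= threshold`` (inclusive comparison).

    The comparison is inclusive so that a record at exactly the threshold
    survives.  With ``per_category`` the same per-record rule is applied
    within each category label; partitioning affects only the per-category
    accounting available through :func:`fdr_category_report`, not
    membership.  The input is not modified.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"FDR threshold must be in (0,1], got {threshold!r}")
    if per_category:
        kept: list[PeptideRecord] = []
        for cat in _category_order(p):
            kept.extend(
                r for r in p.records if r.category == cat and r.q_value <= threshold
            )
        # restore input order
        index = {id(r): i for i, r in enumerate(p.records)}
        kept.sort(key=lambda r: index[id(r)])
    else:
        kept = [r for r in p.records if r.q_value <= threshold]
    return Immunopeptidome(
        name=p.name, alleles=list(p.alleles), erap1=p.erap1, records=kept
    )


def fdr_category_report(
    p: Immunopeptidome, threshold: float
) -> dict[str, tuple[int, int]]:
    """Per-category (kept, total) record counts at *threshold*."""
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"FDR threshold must be in (0,1], got {threshold!r}")
    out: dict[str, tuple[int, int]] = {}
    for cat in _category_order(p):
        recs = [r for r in p.records if r.category == cat]
        out[cat] = (sum(r.q_value <= threshold for r in recs), len(recs))
    return out


def _category_order(p: Immunopeptidome) -> list[str]:
    seen: dict[str, None] = {}
    for r in p.records:
        seen.setdefault(r.category)
    return list(seen)


def deduplicate(p: Immunopeptidome) -> set[str]:
    """Set of unique (case-normalized) peptide sequences."""
    return {rec.sequence for rec in p.records}


def unique_records(p: Immunopeptidome) -> dict[str, PeptideRecord]:
    """One representative record per unique sequence, minimum q_value wins."""
    best: dict[str, PeptideRecord] = {}
    for rec in p.records:
        cur = best.get(rec.sequence)
        if cur is None or rec.q_value < cur.q_value:
            best[rec.sequence] = rec
    return best


def pool_peptidomes(
    peptidomes: Iterable[Immunopeptidome], name: str = "pooled"
) -> Immunopeptidome:
    """Concatenate peptidomes into one (allele panels are unioned)."""
    alleles: list[str] = []
    records: list[PeptideRecord] = []
    for p in peptidomes:
        for a in p.alleles:
            if a not in alleles:
                alleles.append(a)
        records.extend(p.records)
    return Immunopeptidome(name=name, alleles=alleles, records=records)


def map_to_proteome(
    peptides: Iterable[str], proteome: str | Path
) -> list[ProteomeHit]:
    """Exact substring search of *peptides* against a FASTA proteome.

    All occurrences are reported, ordered by (protein id, offset, peptide).
    Coordinates are 0-based half-open.
    """
    for pep in peptides:
        if not is_valid_sequence(pep):
            raise ValueError(f"invalid peptide sequence: {pep!r}")
    queries = sorted(set(peptides))
    hits: list[ProteomeHit] = []
    try:
        parsed = list(SeqIO.parse(str(proteome), "fasta"))
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read proteome FASTA {proteome}: {exc}") from exc
    for record in parsed:
        seq = str(record.seq).upper()
        for pep in queries:
            start = seq.find(pep)
            while start != -1:
                hits.append(
                    ProteomeHit(
                        protein_id=record.id,
                        start=start,
                        end=start + len(pep),
                        peptide=pep,
                    )
                )
                start = seq.find(pep, start + 1)
    hits.sort()
    return hits
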