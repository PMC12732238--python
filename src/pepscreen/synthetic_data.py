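"""Reproducible synthetic fixtures for the whole analysis pipeline.

Generates cell-line peptidomes with the statistical structure the analysis
assumes — unequal depth, a 9-mer-dominant length spectrum, per-allele
%rank strata, q-values straddling the 1%/10% FDR boundary, partial
inter-line sharing, planted motif-conforming "stimulatory" peptides, and a
proteome FASTA embedding every emitted peptide — together with the gold
labels needed to validate each pipeline stage.  All output is a pure
function of the seed.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from pepscreen.peptidome_io import (
    AMINO_ACIDS,
    Immunopeptidome,
    PeptideRecord,
    write_peptide_table,
)
from pepscreen.tcr_motif import (
    DEFAULT_ANCHOR_POSITIONS,
    DEFAULT_CONTACT_POSITIONS,
    DEFAULT_CONTACT_RESIDUES,
    NON_STIMULATORY,
    STIMULATORY,
    LigandPanel,
    PanelPeptide,
)

_AA = np.array(list(AMINO_ACIDS))

ALANINE_SCAN = "alanine_scan"
ANCHOR_EXCHANGE = "anchor_exchange"
LIBRARY = "library"


@dataclass(frozen=True)
class TruthRules:
    """Generating motif rules: anchor allowed sets and contact requirements.

    These are the generator's ground truth; the screening defaults
    reconstruct a compatible rule set from panel data.
    """

    anchor_positions: Mapping[int, tuple[int, ...]] = field(
        default_factory=lambda: dict(DEFAULT_ANCHOR_POSITIONS)
    )
    contact_positions: Mapping[int, tuple[int, ...]] = field(
        default_factory=lambda: dict(DEFAULT_CONTACT_POSITIONS)
    )
    anchor_allowed: Mapping[int, Mapping[int, str]] = field(
        default_factory=lambda: {
            9: {2: "RK", 7: "LIVM", 9: "LIVM"},
            8: {2: "RK", 8: "LIVMR"},
        }
    )
    contact_required: str = "".join(sorted(DEFAULT_CONTACT_RESIDUES))
    contact_mode: str = "any"
    enrichment: float = 0.85  # probability mass on allowed/required residues

    def conforms(self, sequence: str) -> bool:
        """True if *sequence* satisfies anchors and the contact rule."""
        length = len(sequence)
        if length not in self.anchor_allowed:
            return False
        for pos, allowed in self.anchor_allowed[length].items():
            if sequence[pos - 1] not in allowed:
                return False
        checks = [
            sequence[pos - 1] in self.contact_required
            for pos in self.contact_positions[length]
        ]
        return all(checks) if self.contact_mode == "all" else any(checks)

    def generating_matrix(self, length: int) -> np.ndarray:
        """Position-probability matrix concentrating mass on rule residues."""
        matrix = np.full((length, 20), 1.0 / 20)
        targets: dict[int, str] = dict(self.anchor_allowed[length])
        for pos in self.contact_positions[length]:
            targets.setdefault(pos, self.contact_required)
        for pos, residues in targets.items():
            row = np.full(20, (1 - self.enrichment) / (20 - len(residues)))
            for aa in residues:
                row[AMINO_ACIDS.index(aa)] = self.enrichment / len(residues)
            matrix[pos - 1] = row
        return matrix


def _random_peptide(rng: np.random.Generator, length: int) -> str:
    return "".join(_AA[rng.integers(0, 20, size=length)])


def _sample_from_matrix(rng: np.random.Generator, matrix: np.ndarray) -> str:
    return "".join(
        _AA[rng.choice(20, p=matrix[pos])] for pos in range(matrix.shape[0])
    )


def _sample_conforming(
    rng: np.random.Generator, rules: TruthRules, length: int, max_tries: int = 10000
) -> str:
    matrix = rules.generating_matrix(length)
    for _ in range(max_tries):
        seq = _sample_from_matrix(rng, matrix)
        if rules.conforms(seq):
            return seq
    raise RuntimeError("could not sample a motif-conforming peptide")


def generate_ligand_panel(
    seed_peptide: str,
    scheme: str,
    rng: np.random.Generator,
    rules: TruthRules | None = None,
    n_library: int = 100,
    exchange_residues: str | None = None,
) -> LigandPanel:
    """Build a labelled ligand panel around *seed_peptide*.

    ``alanine_scan`` yields one A-substitution per position (no-op
    positions skipped with a note); a variant is non-stimulatory when the
    substitution removes a required contact residue or breaks an anchor.
    ``anchor_exchange`` substitutes P2 and the C-terminus over a residue
    set; ``library`` draws random peptides accepted by the truth rules.
    The seed peptide itself is included, labelled stimulatory.
    """
    rules = rules or TruthRules()
    length = len(seed_peptide)
    if length not in (8, 9):
        raise ValueError(f"seed peptide must be 8- or 9-mer, got {length}")
    peptides = [PanelPeptide(seed_peptide, STIMULATORY, "proteome_match")]

    if scheme == ALANINE_SCAN:
        anchors = rules.anchor_allowed[length]
        contacts = set(rules.contact_positions[length])
        for pos in range(1, length + 1):
            original = seed_peptide[pos - 1]
            if original == "A":
                warnings.warn(f"alanine scan: P{pos} already A, substitution skipped")
                continue
            variant = seed_peptide[: pos - 1] + "A" + seed_peptide[pos:]
            lost_contact = (
                pos in contacts
                and original in rules.contact_required
                and "A" not in rules.contact_required
            )
            broke_anchor = pos in anchors and "A" not in anchors[pos]
            label = NON_STIMULATORY if (lost_contact or broke_anchor) else STIMULATORY
            peptides.append(PanelPeptide(variant, label, ALANINE_SCAN))
    elif scheme == ANCHOR_EXCHANGE:
        for pos in (2, length):
            pool = exchange_residues or rules.anchor_allowed[length][pos]
            for aa in pool:
                if aa == seed_peptide[pos - 1]:
                    continue
                variant = seed_peptide[: pos - 1] + aa + seed_peptide[pos:]
                label = STIMULATORY if rules.conforms(variant) else NON_STIMULATORY
                peptides.append(PanelPeptide(variant, label, ANCHOR_EXCHANGE))
    elif scheme == LIBRARY:
        seen = {seed_peptide}
        while len(peptides) < n_library + 1:
            seq = _sample_conforming(rng, rules, length)
            if seq in seen:
                continue
            seen.add(seq)
            peptides.append(PanelPeptide(seq, STIMULATORY, LIBRARY))
    else:
        raise ValueError(f"unknown panel scheme: {scheme!r}")
    return LigandPanel(peptides=peptides)


@dataclass
class SimulationConfig:
    """Knobs for :func:`generate_peptidome_suite`; the seed fixes everything."""

    seed: int = 17
    cell_lines: tuple[str, ...] = ("SYN-A", "SYN-B", "SYN-C", "SYN-D")
    depths: tuple[int, ...] = (3200, 2100, 8600, 8500)
    length_probs: Mapping[int, float] = field(
        default_factory=lambda: {8: 0.03, 9: 0.95, 10: 0.015, 11: 0.005}
    )
    shared_allele: str = "HLA-C*06:02"
    extra_alleles: tuple[tuple[str, ...], ...] = (
        ("HLA-A*02:01", "HLA-B*57:01"),
        ("HLA-A*24:02", "HLA-B*08:01"),
        ("HLA-A*01:01", "HLA-B*44:02"),
        ("HLA-A*01:01", "HLA-B*18:01"),
    )
    #: probability that a background peptide falls in each %rank stratum of
    #: the shared allele
    strata_probs: Mapping[str, float] = field(
        default_factory=lambda: {"strong": 0.04, "weak": 0.06, "non_binder": 0.90}
    )
    #: per-stratum log-normal rank model: (mu, sigma, (low, high)) in %rank
    rank_params: Mapping[str, tuple[float, float, tuple[float, float]]] = field(
        default_factory=lambda: {
            "strong": (math.log(0.15), 0.7, (1e-4, 0.5)),
            "weak": (math.log(1.0), 0.5, (0.5, 2.0)),
            "non_binder": (math.log(8.0), 1.0, (2.0, 100.0)),
        }
    )
    q_boundary_frac: float = 0.03  # fraction of q-values in (0.01, 0.10]
    #: retention probability that a peptide of line i also appears in line j
    sharing: Mapping[tuple[int, int], float] = field(
        default_factory=lambda: {(2, 3): 0.35}
    )
    default_sharing: float = 0.04
    n_planted: int = 10
    n_duplicates: int = 5  # duplicate rows appended per line
    categories: tuple[str, ...] = ("CDS", "UTR5", "OffFrame")
    erap1: tuple[str, ...] = ("Hap2/Hap2", "Hap10/Hap10", "Hap2/Hap10", "Hap1/Hap2")
    rules: TruthRules = field(default_factory=TruthRules)

    def validate(self) -> None:
        n = len(self.cell_lines)
        if not (len(self.depths) == len(self.extra_alleles) == len(self.erap1) == n):
            raise ValueError("per-line config tuples must match cell_lines length")
        if not math.isclose(sum(self.length_probs.values()), 1.0, abs_tol=1e-9):
            raise ValueError("length_probs must sum to 1")
        if not math.isclose(sum(self.strata_probs.values()), 1.0, abs_tol=1e-9):
            raise ValueError("strata_probs must sum to 1")
        for depth in self.depths:
            if self.n_planted + 1 > depth:
                raise ValueError("n_planted exceeds configured depth")

    def share_prob(self, i: int, j: int) -> float:
        return self.sharing.get((i, j), self.sharing.get((j, i), self.default_sharing))


@dataclass
class SuiteGold:
    """Generator bookkeeping used as test oracles."""

    planted: dict[str, list[str]]  # line -> planted stimulatory sequences
    nonbinder_planted: tuple[str, str]  # (line, sequence), RNF111-like case
    membership: dict[str, frozenset[str]]  # sequence -> lines containing it
    duplicates: dict[str, int]  # line -> duplicate row count
    strata: dict[str, dict[str, str]]  # line -> sequence -> stratum
    plantings: list[tuple[str, int, str]]  # (protein_id, offset, peptide)


@dataclass
class SuiteResult:
    peptidomes: list[Immunopeptidome]
    gold: SuiteGold
    proteome: dict[str, str]  # protein id -> sequence
    config: SimulationConfig

    def write(self, outdir: str | Path) -> None:
        """Emit peptide tables, gold labels, proteome FASTA and config echo."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for p in self.peptidomes:
            write_peptide_table(p, outdir / f"{p.name}.tsv")
        with open(outdir / "proteome.fasta", "w") as fh:
            for pid, seq in self.proteome.items():
                fh.write(f">{pid}\n")
                for i in range(0, len(seq), 60):
                    fh.write(seq[i : i + 60] + "\n")
        with open(outdir / "gold_planted.tsv", "w") as fh:
            fh.write("cell_line\tsequence\tstratum\n")
            for line, seqs in self.gold.planted.items():
                for seq in seqs:
                    fh.write(f"{line}\t{seq}\tstrong\n")
            line, seq = self.gold.nonbinder_planted
            fh.write(f"{line}\t{seq}\tnon_binder\n")
        cfg = asdict(self.config)
        cfg["sharing"] = {f"{i},{j}": v for (i, j), v in self.config.sharing.items()}
        cfg["rules"] = {
            k: (dict(v) if isinstance(v, Mapping) else v)
            for k, v in asdict(self.config.rules).items()
        }
        (outdir / "config.json").write_text(json.dumps(cfg, indent=1, default=str))


def _draw_rank(
    rng: np.random.Generator,
    params: tuple[float, float, tuple[float, float]],
) -> float:
    mu, sigma, (low, high) = params
    for _ in range(1000):
        value = float(np.exp(rng.normal(mu, sigma)))
        if low < value <= high:
            return round(value, 4)
    return round(min(max(float(np.exp(mu)), low * 1.001), high), 4)


def _draw_q(rng: np.random.Generator, boundary_frac: float) -> float:
    if rng.random() < boundary_frac:
        return round(float(rng.uniform(0.0101, 0.10)), 6)
    return round(float(rng.uniform(1e-6, 0.01)), 6)


def generate_peptidome_suite(cfg: SimulationConfig | None = None) -> SuiteResult:
    """Generate the full synthetic suite (peptidomes, gold labels, proteome).

    Per line, the unique-sequence count equals the configured depth;
    ``n_duplicates`` extra duplicate rows (with inflated q-values) are
    appended on top.  Planted motif-conforming peptides are forced into
    the strong-binder stratum of the shared allele, except one RNF111-like
    peptide on the last line which is forced into the non-binder stratum
    with a q-value in (0.01, 0.10].
    """
    cfg = cfg or SimulationConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    lengths = sorted(cfg.length_probs)
    length_p = np.array([cfg.length_probs[length] for length in lengths])
    strata = list(cfg.strata_probs)
    strata_p = np.array([cfg.strata_probs[s] for s in strata])

    taken: set[str] = set()
    line_seqs: list[list[str]] = []
    planted: dict[str, list[str]] = {}
    rnf_line = cfg.cell_lines[-1]
    rnf_seq = ""

    for i, line in enumerate(cfg.cell_lines):
        seqs: list[str] = []
        present: set[str] = set()

        # planted stimulatory peptides (motif-conforming, unique suite-wide
        # except for deliberate cross-line sharing below)
        mine: list[str] = []
        while len(mine) < cfg.n_planted:
            length = 9 if rng.random() < 0.8 else 8
            seq = _sample_conforming(rng, cfg.rules, length)
            if seq in taken or seq in present:
                continue
            mine.append(seq)
            present.add(seq)
            seqs.append(seq)
        planted[line] = mine

        if line == rnf_line:
            while True:
                seq = _sample_conforming(rng, cfg.rules, 8)
                if seq not in taken and seq not in present:
                    rnf_seq = seq
                    present.add(seq)
                    seqs.append(seq)
                    break

        # shared-in background from earlier lines
        for j in range(i):
            p_share = cfg.share_prob(j, i)
            if p_share <= 0:
                continue
            donors = [s for s in line_seqs[j] if s not in planted[cfg.cell_lines[j]]]
            keep = rng.random(len(donors)) < p_share
            for seq, kept in zip(donors, keep):
                if kept and seq not in present and len(seqs) < cfg.depths[i]:
                    present.add(seq)
                    seqs.append(seq)

        # fresh background to fill the configured depth
        while len(seqs) < cfg.depths[i]:
            length = int(rng.choice(lengths, p=length_p))
            seq = _random_peptide(rng, length)
            if seq in present or seq in taken:
                continue
            present.add(seq)
            seqs.append(seq)

        taken |= present
        line_seqs.append(seqs)

    membership: dict[str, set[str]] = {}
    for line, seqs in zip(cfg.cell_lines, line_seqs):
        for seq in seqs:
            membership.setdefault(seq, set()).add(line)

    peptidomes: list[Immunopeptidome] = []
    strata_gold: dict[str, dict[str, str]] = {}
    duplicates: dict[str, int] = {}
    for i, line in enumerate(cfg.cell_lines):
        alleles = [cfg.shared_allele, *cfg.extra_alleles[i]]
        records: list[PeptideRecord] = []
        line_strata: dict[str, str] = {}
        for seq in line_seqs[i]:
            if seq in planted[line]:
                stratum = "strong"
            elif line == rnf_line and seq == rnf_seq:
                stratum = "non_binder"
            else:
                stratum = strata[int(rng.choice(len(strata), p=strata_p))]
            line_strata[seq] = stratum
            ranks = {cfg.shared_allele: _draw_rank(rng, cfg.rank_params[stratum])}
            for extra in cfg.extra_alleles[i]:
                ranks[extra] = _draw_rank(rng, cfg.rank_params["non_binder"])
            if line == rnf_line and seq == rnf_seq:
                q = round(float(rng.uniform(0.0101, 0.10)), 6)
            else:
                q = _draw_q(rng, cfg.q_boundary_frac)
            records.append(
                PeptideRecord(
                    sequence=seq,
                    q_value=q,
                    category=str(rng.choice(cfg.categories)),
                    ranks=ranks,
                    cell_line=line,
                )
            )
        # duplicate rows: same sequence, strictly larger q-value
        n_dup = min(cfg.n_duplicates, len(records))
        dup_idx = rng.choice(len(records), size=n_dup, replace=False)
        for idx in dup_idx:
            src = records[int(idx)]
            records.append(
                PeptideRecord(
                    sequence=src.sequence,
                    q_value=round(min(src.q_value * 2 + 1e-6, 1.0), 6),
                    category=src.category,
                    ranks=dict(src.ranks),
                    cell_line=line,
                )
            )
        duplicates[line] = n_dup
        strata_gold[line] = line_strata
        order = rng.permutation(len(records))
        records = [records[int(k)] for k in order]
        peptidomes.append(
            Immunopeptidome(
                name=line, alleles=alleles, erap1=cfg.erap1[i], records=records
            )
        )

    proteome, plantings = _build_proteome(sorted(taken))

    gold = SuiteGold(
        planted=planted,
        nonbinder_planted=(rnf_line, rnf_seq),
        membership={seq: frozenset(lines) for seq, lines in membership.items()},
        duplicates=duplicates,
        strata=strata_gold,
        plantings=plantings,
    )
    return SuiteResult(peptidomes=peptidomes, gold=gold, proteome=proteome, config=cfg)


def _build_proteome(
    peptides: Sequence[str], per_protein: int = 40
) -> tuple[dict[str, str], list[tuple[str, int, str]]]:
    """Embed every peptide in a synthetic protein by concatenation."""
    proteome: dict[str, str] = {}
    plantings: list[tuple[str, int, str]] = []
    for chunk_no, start in enumerate(range(0, len(peptides), per_protein)):
        pid = f"SYNP{chunk_no + 1:05d}"
        offset = 0
        parts: list[str] = []
        for pep in peptides[start : start + per_protein]:
            plantings.append((pid, offset, pep))
            parts.append(pep)
            offset += len(pep)
        proteome[pid] = "".join(parts)
    return proteome, plantings


def plant_in_proteome(
    peptides: Sequence[str],
    rng: np.random.Generator,
    n_proteins: int = 3,
    protein_length: int = 200,
    copies: Mapping[str, int] | None = None,
) -> tuple[dict[str, str], list[tuple[str, int, str]]]:
    """Plant peptides at recorded positions inside random protein sequences.

    Returns (proteome, plantings); *copies* requests multiple plantings of
    a peptide across distinct proteins.  Intended for targeted
    proteome-mapping tests where the planting position is the oracle.
    """
    proteome = {
        f"RNDP{i + 1:04d}": _random_peptide(rng, protein_length)
        for i in range(n_proteins)
    }
    ids = sorted(proteome)
    used: dict[str, list[tuple[int, int]]] = {pid: [] for pid in ids}
    plantings: list[tuple[str, int, str]] = []
    for k, pep in enumerate(peptides):
        for copy_no in range((copies or {}).get(pep, 1)):
            pid = ids[(k + copy_no) % len(ids)]
            seq = proteome[pid]
            for _ in range(1000):
                pos = int(rng.integers(0, len(seq) - len(pep)))
                span = (pos, pos + len(pep))
                if all(span[1] <= lo or span[0] >= hi for lo, hi in used[pid]):
                    break
            else:
                raise RuntimeError("could not place peptide without overlap")
            used[pid].append(span)
            proteome[pid] = seq[: span[0]] + pep + seq[span[1] :]
            plantings.append((pid, pos, pep))
    return proteome, sorted(plantings)
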