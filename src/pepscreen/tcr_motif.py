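"""Build a TCR peptide-recognition motif and screen peptidomes with it.

The motif combines three layers per peptide length (8 and 9):

1. a position-probability matrix estimated from stimulatory panel peptides
   (with a pseudocount), and the derived log-odds matrix in bits against a
   background residue distribution;
2. anchor-position constraints — each anchor position carries a set of
   allowed residues (data-driven from the stimulatory panel by default, or
   pinned in the config);
3. TCR-contact constraints — contact positions must carry a residue from a
   required (basic) set, by default at least one contact position
   ("any" mode) with an "all" mode available.

A peptide passes when its length has a motif, all anchors are satisfied,
the contact rule holds, and the summed log-odds score reaches the
threshold.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from pepscreen.peptidome_io import AMINO_ACIDS, is_valid_sequence

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

STIMULATORY = "stimulatory"
NON_STIMULATORY = "non_stimulatory"

#: default position layout (1-based): nonamer anchors P2/P7/P9 with
#: contacts P5/P8; octamer positions scaled by C-terminal alignment.
DEFAULT_ANCHOR_POSITIONS: dict[int, tuple[int, ...]] = {9: (2, 7, 9), 8: (2, 8)}
DEFAULT_CONTACT_POSITIONS: dict[int, tuple[int, ...]] = {9: (5, 8), 8: (5, 7)}
DEFAULT_CONTACT_RESIDUES = frozenset("RK")


@dataclass(frozen=True)
class PanelPeptide:
    sequence: str
    label: str  # stimulatory | non_stimulatory
    provenance: str = "library"  # library | anchor_exchange | alanine_scan | proteome_match

    def __post_init__(self) -> None:
        if not is_valid_sequence(self.sequence):
            raise ValueError(f"invalid panel sequence: {self.sequence!r}")
        if self.label not in (STIMULATORY, NON_STIMULATORY):
            raise ValueError(f"invalid panel label: {self.label!r}")


@dataclass
class LigandPanel:
    """Labelled stimulatory / non-stimulatory peptides of length 8 or 9."""

    peptides: list[PanelPeptide]

    def __post_init__(self) -> None:
        bad = {p.sequence for p in self.peptides if len(p.sequence) not in (8, 9)}
        if bad:
            raise ValueError(f"panel peptides must be 8- or 9-mers: {sorted(bad)}")

    def stimulatory(self, length: int) -> list[str]:
        return [
            p.sequence
            for p in self.peptides
            if p.label == STIMULATORY and len(p.sequence) == length
        ]

    def non_stimulatory(self, length: int) -> list[str]:
        return [
            p.sequence
            for p in self.peptides
            if p.label == NON_STIMULATORY and len(p.sequence) == length
        ]

    def lengths(self) -> list[int]:
        return sorted({len(p.sequence) for p in self.peptides})


@dataclass(frozen=True)
class MotifConfig:
    """Position layout and constraint sets for motif construction.

    ``anchor_allowed`` pins explicit allowed-residue sets per length and
    position; when absent for a position, the residues observed among
    stimulatory panel peptides at that position are used.  ``allow_q_at_p5``
    admits Q as an alternative contact residue at position 5.
    """

    anchor_positions: Mapping[int, tuple[int, ...]] = field(
        default_factory=lambda: dict(DEFAULT_ANCHOR_POSITIONS)
    )
    contact_positions: Mapping[int, tuple[int, ...]] = field(
        default_factory=lambda: dict(DEFAULT_CONTACT_POSITIONS)
    )
    anchor_allowed: Mapping[int, Mapping[int, frozenset[str]]] | None = None
    contact_required: frozenset[str] = DEFAULT_CONTACT_RESIDUES
    contact_mode: str = "any"  # "any" | "all"
    allow_q_at_p5: bool = False

    def __post_init__(self) -> None:
        if self.contact_mode not in ("any", "all"):
            raise ValueError(f"contact_mode must be any|all, got {self.contact_mode!r}")

    def contact_set(self, position: int) -> frozenset[str]:
        if self.allow_q_at_p5 and position == 5:
            return self.contact_required | {"Q"}
        return self.contact_required


@dataclass(frozen=True)
class MatchResult:
    sequence: str
    length_ok: bool
    anchor_ok: bool
    contact_ok: bool
    score: float
    passed: bool
    rank: int = 0


@dataclass
class LengthMotif:
    """Matrices and constraints for one peptide length."""

    length: int
    ppm: np.ndarray  # (L, 20) probabilities
    log_odds: np.ndarray  # (L, 20) bits vs background
    anchors: dict[int, frozenset[str]]  # 1-based position -> allowed residues
    contacts: dict[int, frozenset[str]]  # 1-based position -> required residues
    contact_mode: str
    n_stimulatory: int


@dataclass
class RecognitionMotif:
    """Per-length motifs plus the shared background distribution."""

    background: np.ndarray  # (20,)
    by_length: dict[int, LengthMotif] = field(default_factory=dict)
    config: MotifConfig = field(default_factory=MotifConfig)

    def __contains__(self, length: int) -> bool:
        return length in self.by_length


def build_motif(
    panel: LigandPanel,
    pseudocount: float = 1.0,
    background: Sequence[float] | None = None,
    config: MotifConfig | None = None,
    discriminative: bool = False,
) -> RecognitionMotif:
    """Estimate the recognition motif from a ligand panel.

    Probability at (position, residue) is
    ``(count among stimulatory peptides + pseudocount) /
    (n_stimulatory + 20 * pseudocount)``; the log-odds matrix is
    ``log2(probability / background)``.  Counts only, so the result is
    independent of panel order.  With ``discriminative`` the background is
    replaced per length by the non-stimulatory panel members' positional
    frequencies (uniform-smoothed with the same pseudocount).
    """
    if pseudocount < 0:
        raise ValueError(f"pseudocount must be non-negative, got {pseudocount!r}")
    config = config or MotifConfig()
    if background is None:
        bg = np.full(20, 1.0 / 20)
    else:
        bg = np.asarray(background, dtype=float)
        if bg.shape != (20,) or not math.isclose(float(bg.sum()), 1.0, abs_tol=1e-6):
            raise ValueError("background must be a 20-vector summing to 1")

    motif = RecognitionMotif(background=bg, config=config)
    for length in (8, 9):
        stim = panel.stimulatory(length)
        if length in panel.lengths() and not stim:
            import warnings

            warnings.warn(f"no stimulatory {length}-mers in panel; motif absent")
        if not stim:
            continue
        ppm = _count_matrix(stim, length, pseudocount)
        if discriminative:
            nonstim = panel.non_stimulatory(length)
            ref = (
                _count_matrix(nonstim, length, max(pseudocount, 1.0))
                if nonstim
                else np.tile(bg, (length, 1))
            )
        else:
            ref = np.tile(bg, (length, 1))
        with np.errstate(divide="ignore"):
            lod = np.where(ppm > 0, np.log2(np.where(ppm > 0, ppm, 1.0) / ref), -np.inf)

        anchors: dict[int, frozenset[str]] = {}
        pinned = (config.anchor_allowed or {}).get(length, {})
        for pos in config.anchor_positions.get(length, ()):
            if pos in pinned:
                allowed = frozenset(pinned[pos])
            else:
                allowed = frozenset(seq[pos - 1] for seq in stim)
            if not allowed:
                raise ValueError(f"empty anchor set at P{pos} for {length}-mers")
            anchors[pos] = allowed
        contacts = {
            pos: config.contact_set(pos)
            for pos in config.contact_positions.get(length, ())
        }
        motif.by_length[length] = LengthMotif(
            length=length,
            ppm=ppm,
            log_odds=lod,
            anchors=anchors,
            contacts=contacts,
            contact_mode=config.contact_mode,
            n_stimulatory=len(stim),
        )
    return motif


def _count_matrix(sequences: Sequence[str], length: int, pseudocount: float) -> np.ndarray:
    counts = np.zeros((length, 20), dtype=float)
    for seq in sequences:
        for pos, aa in enumerate(seq):
            counts[pos, _AA_INDEX[aa]] += 1
    return (counts + pseudocount) / (len(sequences) + 20 * pseudocount)


def position_information_content(m: RecognitionMotif, length: int) -> np.ndarray:
    """Per-position information content in bits: log2(20) + sum p log2 p."""
    lm = m.by_length[length]
    p = lm.ppm
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
    return np.log2(20) + plogp.sum(axis=1)


def match_peptide(
    m: RecognitionMotif, peptide: str, threshold: float = 0.0
) -> MatchResult:
    """Evaluate one peptide against the motif.

    ``passed`` requires length coverage, all anchors satisfied, the contact
    rule, and summed log-odds >= *threshold*.
    """
    if not is_valid_sequence(peptide):
        raise ValueError(f"invalid peptide sequence: {peptide!r}")
    if len(peptide) not in m.by_length:
        return MatchResult(peptide, False, False, False, -math.inf, False)
    lm = m.by_length[len(peptide)]

    anchor_ok = all(peptide[pos - 1] in allowed for pos, allowed in lm.anchors.items())
    checks = [peptide[pos - 1] in req for pos, req in lm.contacts.items()]
    contact_ok = all(checks) if lm.contact_mode == "all" else any(checks)
    score = float(
        sum(lm.log_odds[pos, _AA_INDEX[aa]] for pos, aa in enumerate(peptide))
    )
    passed = anchor_ok and contact_ok and score >= threshold
    return MatchResult(peptide, True, anchor_ok, contact_ok, score, passed)


def screen_peptidome(
    m: RecognitionMotif,
    peptides: Iterable[str],
    threshold: float = 0.0,
    top_k: int | None = None,
) -> list[MatchResult]:
    """Screen a sequence set; return passed candidates ranked by score.

    Every 8-/9-mer is evaluated with :func:`match_peptide`; candidates are
    sorted by descending score with lexicographic tie-break, then truncated
    to *top_k* if set.  Output is order-invariant in the input.
    """
    results = [
        match_peptide(m, pep, threshold) for pep in sorted(set(peptides))
    ]
    candidates = [r for r in results if r.passed]
    candidates.sort(key=lambda r: (-r.score, r.sequence))
    if top_k is not None:
        candidates = candidates[:top_k]
    return [
        MatchResult(
            r.sequence, r.length_ok, r.anchor_ok, r.contact_ok, r.score, r.passed, i + 1
        )
        for i, r in enumerate(candidates)
    ]


# -- serialization ----------------------------------------------------------


def motif_to_json(m: RecognitionMotif) -> str:
    """Serialize a motif to a canonical (sorted-key) JSON document."""
    doc = {
        "alphabet": AMINO_ACIDS,
        "background": [float(x) for x in m.background],
        "config": {
            "contact_mode": m.config.contact_mode,
            "contact_required": sorted(m.config.contact_required),
            "allow_q_at_p5": m.config.allow_q_at_p5,
        },
        "lengths": {
            str(L): {
                "ppm": [[float(x) for x in row] for row in lm.ppm],
                "log_odds": [
                    [None if math.isinf(x) else float(x) for x in row]
                    for row in lm.log_odds
                ],
                "anchors": {str(p): sorted(s) for p, s in lm.anchors.items()},
                "contacts": {str(p): sorted(s) for p, s in lm.contacts.items()},
                "contact_mode": lm.contact_mode,
                "n_stimulatory": lm.n_stimulatory,
            }
            for L, lm in m.by_length.items()
        },
    }
    return json.dumps(doc, sort_keys=True, indent=1)


def motif_from_json(text: str) -> RecognitionMotif:
    doc = json.loads(text)
    cfgdoc = doc["config"]
    config = MotifConfig(
        contact_required=frozenset(cfgdoc["contact_required"]),
        contact_mode=cfgdoc["contact_mode"],
        allow_q_at_p5=cfgdoc["allow_q_at_p5"],
    )
    motif = RecognitionMotif(
        background=np.asarray(doc["background"], dtype=float), config=config
    )
    for key, sub in doc["lengths"].items():
        length = int(key)
        lod = np.asarray(
            [[-math.inf if x is None else x for x in row] for row in sub["log_odds"]],
            dtype=float,
        )
        motif.by_length[length] = LengthMotif(
            length=length,
            ppm=np.asarray(sub["ppm"], dtype=float),
            log_odds=lod,
            anchors={int(p): frozenset(s) for p, s in sub["anchors"].items()},
            contacts={int(p): frozenset(s) for p, s in sub["contacts"].items()},
            contact_mode=sub["contact_mode"],
            n_stimulatory=int(sub["n_stimulatory"]),
        )
    return motif
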