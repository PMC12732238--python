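"""Call ERAP1 haplotype pairs from phased genotypes at the 9 defining SNPs.

The SNP -> residue-state translation and the residue-string -> haplotype
table are shipped as an editable JSON key; the bundled key is a validated
placeholder, not an authoritative transcription.  Input genotypes come as
a 9-column delimited table (alleles like ``C|T``) or a minimal VCF
restricted to GT extraction.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

SNP_ORDER = (
    "rs3734016",
    "rs26653",
    "rs26618",
    "rs27895",
    "rs2287987",
    "rs30187",
    "rs10050860",
    "rs17482078",
    "rs27044",
)

UNASSIGNED = "unassigned"


class Erap1KeyError(ValueError):
    """Malformed haplotype key."""


class PhasingError(ValueError):
    """Unphased heterozygous genotype cannot be translated unambiguously."""


@dataclass
class Erap1HaplotypeKey:
    """SNP->residue translation plus residue-string->haplotype mapping."""

    snp_alleles: dict[str, dict[str, str]]  # rsid -> nucleotide -> residue state
    haplotypes: dict[str, str]  # label -> 9-state string
    note: str = ""

    def __post_init__(self) -> None:
        missing = set(SNP_ORDER) - set(self.snp_alleles)
        if missing:
            raise Erap1KeyError(f"key lacks SNPs: {sorted(missing)}")
        strings = list(self.haplotypes.values())
        if len(strings) != len(set(strings)):
            raise Erap1KeyError("haplotype state strings are not unique")
        for label, states in self.haplotypes.items():
            if len(states) != len(SNP_ORDER):
                raise Erap1KeyError(f"{label}: expected 9 states, got {states!r}")
            for rsid, state in zip(SNP_ORDER, states):
                if state not in self.snp_alleles[rsid].values():
                    raise Erap1KeyError(
                        f"{label}: state {state!r} not producible at {rsid}"
                    )

    @classmethod
    def from_json(cls, text: str) -> "Erap1HaplotypeKey":
        doc = json.loads(text)
        return cls(
            snp_alleles={s["rsid"]: dict(s["alleles"]) for s in doc["snps"]},
            haplotypes=dict(doc["haplotypes"]),
            note=doc.get("note", ""),
        )

    @classmethod
    def load(cls, path: str | Path | None = None) -> "Erap1HaplotypeKey":
        """Load a key file, defaulting to the bundled placeholder key."""
        if path is None:
            text = (
                resources.files("pepscreen").joinpath("data/erap1_key.json").read_text()
            )
        else:
            text = Path(path).read_text()
        return cls.from_json(text)

    def translate_allele(self, rsid: str, nucleotide: str) -> str:
        table = self.snp_alleles[rsid]
        if nucleotide not in table:
            raise ValueError(f"{rsid}: allele {nucleotide!r} not in key")
        return table[nucleotide]

    def lookup(self, states: str) -> str:
        for label, reference in self.haplotypes.items():
            if states == reference:
                return label
        return UNASSIGNED

    def nucleotides_for(self, rsid: str, state: str) -> str:
        """Invert the residue translation (used to compose test genotypes)."""
        for nucleotide, residue in self.snp_alleles[rsid].items():
            if residue == state:
                return nucleotide
        raise ValueError(f"{rsid}: no allele produces state {state!r}")


@dataclass
class Erap1Genotype:
    """Phased allele pairs at the nine defining SNPs for one sample."""

    sample: str
    calls: dict[str, tuple[str, str]] = field(default_factory=dict)
    phased: bool = True

    def __post_init__(self) -> None:
        missing = set(SNP_ORDER) - set(self.calls)
        if missing:
            raise ValueError(f"{self.sample}: missing SNPs {sorted(missing)}")

    def heterozygous_sites(self) -> list[str]:
        return [rsid for rsid in SNP_ORDER if len(set(self.calls[rsid])) == 2]


def genotype_to_residue_strings(
    g: Erap1Genotype, key: Erap1HaplotypeKey
) -> tuple[str, str]:
    """Translate a phased genotype into its two 9-residue-state strings.

    SNP order is fixed (:data:`SNP_ORDER`).  Unphased genotypes with
    heterozygous sites raise :class:`PhasingError` listing all consistent
    phasings.
    """
    het = g.heterozygous_sites()
    if not g.phased and het:
        phasings = _enumerate_phasings(g, key)
        raise PhasingError(
            f"{g.sample}: unphased genotype with {len(het)} heterozygous "
            f"site(s); {2 ** len(het)} consistent phasings: {sorted(phasings)}"
        )
    first = "".join(key.translate_allele(r, g.calls[r][0]) for r in SNP_ORDER)
    second = "".join(key.translate_allele(r, g.calls[r][1]) for r in SNP_ORDER)
    return first, second


def _enumerate_phasings(
    g: Erap1Genotype, key: Erap1HaplotypeKey
) -> set[tuple[str, str]]:
    choices = [sorted(set(g.calls[r])) for r in SNP_ORDER]
    out: set[tuple[str, str]] = set()
    for combo in itertools.product(*(range(len(c)) for c in choices)):
        first = "".join(
            key.translate_allele(r, choices[i][pick])
            for i, (r, pick) in enumerate(zip(SNP_ORDER, combo))
        )
        second = "".join(
            key.translate_allele(r, choices[i][-1 - pick])
            for i, (r, pick) in enumerate(zip(SNP_ORDER, combo))
        )
        out.add((first, second))
    return out


def _hap_sort_key(label: str) -> tuple[int, int | str]:
    if label == UNASSIGNED:
        return (2, label)
    if label.startswith("Hap") and label[3:].isdigit():
        return (0, int(label[3:]))
    return (1, label)


def call_diplotype(states: tuple[str, str], key: Erap1HaplotypeKey) -> str:
    """Canonical ``HapX/HapY`` label (X <= Y ordinally; unassigned sorts last)."""
    labels = sorted((key.lookup(states[0]), key.lookup(states[1])), key=_hap_sort_key)
    return f"{labels[0]}/{labels[1]}"


def compose_genotype(
    key: Erap1HaplotypeKey, hap_a: str, hap_b: str, sample: str = "synthetic"
) -> Erap1Genotype:
    """Build a phased genotype whose haplotypes are two key entries."""
    states_a, states_b = key.haplotypes[hap_a], key.haplotypes[hap_b]
    calls = {
        rsid: (key.nucleotides_for(rsid, sa), key.nucleotides_for(rsid, sb))
        for rsid, sa, sb in zip(SNP_ORDER, states_a, states_b)
    }
    return Erap1Genotype(sample=sample, calls=calls, phased=True)


# -- genotype input ---------------------------------------------------------


def read_genotypes(path: str | Path) -> list[Erap1Genotype]:
    """Read genotypes from a 9-column TSV or a minimal VCF.

    The TSV layout is one row per sample: a ``sample`` column plus one
    column per rsID holding ``A|G``-style phased pairs (``A/G`` marks
    unphased).  VCF input is parsed for CHROM/POS/ID/REF/ALT and the GT
    field only.
    """
    path = Path(path)
    head = path.read_text().lstrip()
    if head.startswith("##fileformat=VCF") or path.suffix.lower() == ".vcf":
        return _read_vcf(path)
    return _read_tsv(path)


def _split_pair(value: str) -> tuple[tuple[str, str], bool]:
    phased = "|" in value
    sep = "|" if phased else "/"
    a, b = value.split(sep)
    return (a.strip(), b.strip()), phased


def _read_tsv(path: Path) -> list[Erap1Genotype]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample" not in df.columns:
        raise ValueError(f"{path}: genotype table needs a 'sample' column")
    out = []
    for _, row in df.iterrows():
        calls: dict[str, tuple[str, str]] = {}
        phased = True
        for rsid in SNP_ORDER:
            pair, p = _split_pair(str(row[rsid]))
            calls[rsid] = pair
            phased = phased and p
        out.append(Erap1Genotype(sample=str(row["sample"]), calls=calls, phased=phased))
    return out


def _read_vcf(path: Path) -> list[Erap1Genotype]:
    samples: list[str] = []
    calls: dict[str, dict[str, tuple[str, str]]] = {}
    phase: dict[str, bool] = {}
    for line in path.read_text().splitlines():
        if line.startswith("##") or not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if line.startswith("#CHROM"):
            samples = fields[9:]
            calls = {s: {} for s in samples}
            phase = {s: True for s in samples}
            continue
        rsid, ref, alt = fields[2], fields[3], fields[4]
        if rsid not in SNP_ORDER:
            continue
        alleles = [ref, *alt.split(",")]
        fmt = fields[8].split(":")
        gt_index = fmt.index("GT")
        for sample, value in zip(samples, fields[9:]):
            gt = value.split(":")[gt_index]
            phased = "|" in gt
            sep = "|" if phased else "/"
            a, b = (alleles[int(i)] for i in gt.split(sep))
            calls[sample][rsid] = (a, b)
            phase[sample] = phase[sample] and phased
    return [
        Erap1Genotype(sample=s, calls=calls[s], phased=phase[s]) for s in samples
    ]
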