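import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pepscreen import peptidome_io as pio
from pepscreen import synthetic_data as sd


def write_table(path, rows, header="sequence\tq_value\tcategory\tHLA-C*06:02"):
    lines = [header] + ["\t".join(str(x) for x in row) for row in rows]
    path.write_text("\n".join(lines) + "\n")
    return path


class TestPeptideRecord:
    def test_fields_and_length(self):
        rec = pio.PeptideRecord("RRLPCRKR", q_value=0.0106)
        assert rec.length == 8
        assert rec.q_value == 0.0106

    @pytest.mark.parametrize("seq", ["", "RRB", "rrl", "RX1"])
    def test_invalid_sequence_rejected(self, seq):
        with pytest.raises(ValueError):
            pio.PeptideRecord(seq, q_value=0.5)

    def test_q_value_range(self):
        with pytest.raises(ValueError):
            pio.PeptideRecord("ACDEF", q_value=1.5)

    def test_negative_rank(self):
        with pytest.raises(ValueError):
            pio.PeptideRecord("ACDEF", q_value=0.1, ranks={"HLA-C*06:02": -1.0})


class TestImmunopeptidome:
    def test_rank_keys_must_be_declared(self):
        rec = pio.PeptideRecord("ACDEF", 0.1, ranks={"HLA-B*08:01": 1.0})
        with pytest.raises(ValueError):
            pio.Immunopeptidome(name="x", alleles=["HLA-C*06:02"], records=[rec])

    def test_name_required(self):
        with pytest.raises(ValueError):
            pio.Immunopeptidome(name="")


class TestReadPeptideTable:
    def test_three_row_table(self, tmp_path):
        path = write_table(
            tmp_path / "t.tsv",
            [
                ("VRSRRCLRL", 0.001, "CDS", 0.2),
                ("RRLPCRKR", 0.0106, "CDS", 5.0),
                ("ACDEFGHIK", 0.002, "UTR5", 1.1),
            ],
        )
        p = pio.read_peptide_table(path)
        assert len(p) == 3
        assert p.alleles == ["HLA-C*06:02"]
        assert [r.sequence for r in p] == ["VRSRRCLRL", "RRLPCRKR", "ACDEFGHIK"]

    def test_rnf111_row(self, tmp_path):
        path = write_table(tmp_path / "t.tsv", [("RRLPCRKR", 0.0106, "CDS", 5.0)])
        rec = pio.read_peptide_table(path).records[0]
        assert rec.length == 8
        assert rec.q_value == 0.0106

    def test_bad_alphabet_row_rejected_others_loaded(self, tmp_path):
        path = write_table(
            tmp_path / "t.tsv",
            [("VRSRRCLRL", 0.001, "CDS", 0.2), ("VRBRRCLRL", 0.001, "CDS", 0.2)],
        )
        with pytest.warns(UserWarning, match="rejected 1 row"):
            p = pio.read_peptide_table(path)
        assert [r.sequence for r in p] == ["VRSRRCLRL"]

    def test_missing_mandatory_column(self, tmp_path):
        path = write_table(tmp_path / "t.tsv", [("PEPTIDE",)], header="sequence")
        with pytest.raises(pio.PeptideTableError, match="q_value"):
            pio.read_peptide_table(path)

    def test_dialect_remap(self, tmp_path):
        path = write_table(
            tmp_path / "t.tsv", [("VRSRRCLRL", 0.001)], header="Peptide\tFDR"
        )
        p = pio.read_peptide_table(
            path, dialect={"Peptide": "sequence", "FDR": "q_value"}
        )
        assert p.records[0].sequence == "VRSRRCLRL"

    def test_empty_file(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("")
        with pytest.warns(UserWarning, match="empty"):
            p = pio.read_peptide_table(path)
        assert len(p) == 0

    def test_round_trip_lossless(self, tmp_path, suite):
        p = suite.peptidomes[0]
        out = tmp_path / "round.tsv"
        pio.write_peptide_table(p, out)
        p2 = pio.read_peptide_table(out, name=p.name)
        assert p2.alleles == p.alleles
        assert [r.sequence for r in p2] == [r.sequence for r in p]
        assert [r.q_value for r in p2] == pytest.approx([r.q_value for r in p])
        assert [r.category for r in p2] == [r.category for r in p]
        for a, b in zip(p2.records, p.records):
            assert a.ranks == pytest.approx(b.ranks)


class TestFilterByFdr:
    def _one(self, q):
        return pio.Immunopeptidome(
            name="x", records=[pio.PeptideRecord("RRLPCRKR", q_value=q)]
        )

    def test_rnf111_kept_at_10pct(self):
        assert len(pio.filter_by_fdr(self._one(0.0106), 0.10)) == 1

    def test_rnf111_removed_at_1pct(self):
        assert len(pio.filter_by_fdr(self._one(0.0106), 0.01)) == 0

    def test_threshold_inclusive(self):
        assert len(pio.filter_by_fdr(self._one(0.01), 0.01)) == 1

    def test_vacuous_threshold(self, suite):
        p = suite.peptidomes[0]
        assert len(pio.filter_by_fdr(p, 1.0)) == len(p)

    @pytest.mark.parametrize("bad", [0.0, -0.1, 1.5])
    def test_bad_threshold(self, bad):
        with pytest.raises(ValueError):
            pio.filter_by_fdr(self._one(0.5), bad)

    def test_input_unmodified_and_idempotent(self, suite):
        p = suite.peptidomes[1]
        n = len(p)
        once = pio.filter_by_fdr(p, 0.01)
        assert len(p) == n
        twice = pio.filter_by_fdr(once, 0.01)
        assert [r.sequence for r in twice] == [r.sequence for r in once]

    def test_per_category_same_membership(self, suite):
        p = suite.peptidomes[0]
        a = pio.filter_by_fdr(p, 0.01, per_category=False)
        b = pio.filter_by_fdr(p, 0.01, per_category=True)
        assert [r.sequence for r in a] == [r.sequence for r in b]

    def test_category_report(self):
        p = pio.Immunopeptidome(
            name="x",
            records=[
                pio.PeptideRecord("AAAAAAAA", 0.001, category="CDS"),
                pio.PeptideRecord("CCCCCCCC", 0.05, category="CDS"),
                pio.PeptideRecord("DDDDDDDD", 0.002, category="UTR5"),
            ],
        )
        assert pio.fdr_category_report(p, 0.01) == {"CDS": (1, 2), "UTR5": (1, 1)}

    @given(
        qs=st.lists(st.floats(0, 1, allow_nan=False), max_size=30),
        t1=st.floats(0.001, 1),
        t2=st.floats(0.001, 1),
    )
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_threshold(self, qs, t1, t2):
        t1, t2 = sorted((t1, t2))
        p = pio.Immunopeptidome(
            name="x",
            records=[
                pio.PeptideRecord("ACDEFGHIK", q_value=q, category=str(i))
                for i, q in enumerate(qs)
            ],
        )
        low = {r.category for r in pio.filter_by_fdr(p, t1)}
        high = {r.category for r in pio.filter_by_fdr(p, t2)}
        assert low <= high


class TestDeduplicate:
    def test_simple(self):
        p = pio.Immunopeptidome(
            name="x",
            records=[
                pio.PeptideRecord("AAAAAAAA", 0.1),
                pio.PeptideRecord("AAAAAAAA", 0.2),
                pio.PeptideRecord("CCCCCCCC", 0.1),
            ],
        )
        assert pio.deduplicate(p) == {"AAAAAAAA", "CCCCCCCC"}

    def test_empty(self):
        assert pio.deduplicate(pio.Immunopeptidome(name="x")) == set()

    def test_idempotent_and_bounded(self, suite):
        p = suite.peptidomes[0]
        uniq = pio.deduplicate(p)
        assert len(uniq) <= len(p)
        p2 = pio.Immunopeptidome(
            name="u",
            alleles=p.alleles,
            records=list(pio.unique_records(p).values()),
        )
        assert pio.deduplicate(p2) == uniq

    def test_generator_duplicate_count(self, suite):
        # generator bookkeeping: unique count == depth, records == depth + dups
        for p, depth in zip(suite.peptidomes, suite.config.depths):
            assert len(pio.deduplicate(p)) == depth
            assert len(p) == depth + suite.gold.duplicates[p.name]

    def test_min_q_representative(self):
        p = pio.Immunopeptidome(
            name="x",
            records=[
                pio.PeptideRecord("AAAAAAAA", 0.2, category="late"),
                pio.PeptideRecord("AAAAAAAA", 0.05, category="early"),
            ],
        )
        assert pio.unique_records(p)["AAAAAAAA"].category == "early"


def brute_force_hits(peptides, proteome):
    hits = []
    for pid, seq in proteome.items():
        for pep in set(peptides):
            for start in range(len(seq) - len(pep) + 1):
                if seq[start : start + len(pep)] == pep:
                    hits.append(pio.ProteomeHit(pid, start, start + len(pep), pep))
    return sorted(hits)


def write_fasta(path, proteome, width=60):
    with open(path, "w") as fh:
        for pid, seq in proteome.items():
            fh.write(f">{pid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
    return path


class TestMapToProteome:
    def test_planted_once(self, tmp_path, rng):
        proteome, plantings = sd.plant_in_proteome(["VRSRRCLRL"], rng, n_proteins=1)
        path = write_fasta(tmp_path / "p.fasta", proteome)
        hits = pio.map_to_proteome(["VRSRRCLRL"], path)
        assert len(hits) == 1
        pid, offset, pep = plantings[0]
        assert hits[0] == pio.ProteomeHit(pid, offset, offset + 9, pep)

    def test_absent_peptide(self, tmp_path, rng):
        proteome, _ = sd.plant_in_proteome(["VRSRRCLRL"], rng, n_proteins=1)
        path = write_fasta(tmp_path / "p.fasta", proteome)
        assert pio.map_to_proteome(["WWWWWWWWW"], path) == []

    def test_planted_twice_ordered(self, tmp_path, rng):
        proteome, plantings = sd.plant_in_proteome(
            ["RRLPCRKR"], rng, n_proteins=2, copies={"RRLPCRKR": 2}
        )
        path = write_fasta(tmp_path / "p.fasta", proteome)
        hits = pio.map_to_proteome(["RRLPCRKR"], path)
        assert len(hits) == 2
        assert [h.protein_id for h in hits] == sorted(h.protein_id for h in hits)
        assert {(h.protein_id, h.start) for h in hits} == {
            (pid, pos) for pid, pos, _ in plantings
        }

    def test_invalid_peptide(self, tmp_path):
        with pytest.raises(ValueError):
            pio.map_to_proteome(["BXZ"], tmp_path / "none.fasta")

    def test_unreadable_fasta(self, tmp_path):
        with pytest.raises(OSError):
            pio.map_to_proteome(["ACDEF"], tmp_path / "missing.fasta")

    def test_agrees_with_brute_force(self, tmp_path):
        rng = np.random.default_rng(3)
        for trial in range(5):
            peptides = ["".join(sd._AA[rng.integers(0, 20, 9)]) for _ in range(6)]
            proteome, _ = sd.plant_in_proteome(
                peptides[:3], rng, n_proteins=2, protein_length=120
            )
            path = write_fasta(tmp_path / f"bf{trial}.fasta", proteome)
            assert pio.map_to_proteome(peptides, path) == brute_force_hits(
                peptides, proteome
            )

    def test_suite_proteome_contains_all_peptides(self, tmp_path, suite):
        path = write_fasta(tmp_path / "suite.fasta", suite.proteome)
        sample = sorted(suite.gold.membership)[:50]
        hits = pio.map_to_proteome(sample, path)
        assert {h.peptide for h in hits} == set(sample)
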