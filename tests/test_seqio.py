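"""Sequence I/O, back-translation, codon-column filtering, and identities."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from seldiv.seqio import (
    CodonAlignment,
    GroupAssignment,
    ProteinAlignment,
    SeqIOError,
    SequenceRecord,
    backtranslate,
    filter_codon_columns,
    pairwise_identity,
    read_fasta,
    write_fasta,
)


class TestReadFasta:
    def test_parses_records_in_order(self, tmp_path):
        p = tmp_path / "x.fasta"
        p.write_text(">a\nMKV\n>b\nMQV\n")
        recs = read_fasta(p, "protein")
        assert [(r.id, r.seq) for r in recs] == [("a", "MKV"), ("b", "MQV")]

    def test_normalizes_whitespace_and_case(self, tmp_path):
        p = tmp_path / "x.fasta"
        p.write_text(">a\natg gta\n")
        (rec,) = read_fasta(p, "nucleotide")
        assert rec.seq == "ATGGTA"

    @pytest.mark.parametrize(
        "content,match",
        [
            (">a\nMKV\n>a\nMQV\n", "duplicate"),
            ("", "no FASTA records"),
            (">a\nM1V\n", "illegal"),
        ],
    )
    def test_rejects_malformed_input(self, tmp_path, content, match):
        p = tmp_path / "x.fasta"
        p.write_text(content)
        with pytest.raises(SeqIOError, match=match):
            read_fasta(p, "protein")

    def test_round_trip(self, tmp_path):
        recs = [SequenceRecord("a", "MKV"), SequenceRecord("b", "MQVL")]
        write_fasta(recs, tmp_path / "y.fasta")
        assert read_fasta(tmp_path / "y.fasta", "protein") == recs


class TestBacktranslate:
    def test_expands_gaps_to_gap_codons(self):
        aln = ProteinAlignment(
            [SequenceRecord("a", "M-K"), SequenceRecord("b", "MQK")]
        )
        cds = [SequenceRecord("a", "ATGAAA"), SequenceRecord("b", "ATGCAAAAA")]
        out = backtranslate(aln, cds)
        assert out.row("a") == "ATG---AAA"
        assert out.row("b") == "ATGCAAAAA"

    def test_strips_terminal_stop(self):
        aln = ProteinAlignment([SequenceRecord("a", "MK"), SequenceRecord("b", "MK")])
        cds = [SequenceRecord("a", "ATGAAATAA"), SequenceRecord("b", "ATGAAG")]
        assert backtranslate(aln, cds).row("a") == "ATGAAA"

    def test_translation_mismatch_names_site(self):
        aln = ProteinAlignment([SequenceRecord("a", "MK"), SequenceRecord("b", "MK")])
        cds = [SequenceRecord("a", "ATGGGG"), SequenceRecord("b", "ATGAAA")]
        with pytest.raises(SeqIOError, match="column 1.*translates to G"):
            backtranslate(aln, cds)

    def test_internal_stop_is_error(self):
        aln = ProteinAlignment([SequenceRecord("a", "MKV"), SequenceRecord("b", "MKV")])
        cds = [SequenceRecord("a", "ATGTAAGTT"), SequenceRecord("b", "ATGAAAGTT")]
        with pytest.raises(SeqIOError, match="stop"):
            backtranslate(aln, cds)

    def test_length_mismatch_reports_lengths(self):
        aln = ProteinAlignment([SequenceRecord("a", "MK"), SequenceRecord("b", "MK")])
        cds = [SequenceRecord("a", "ATGAAAGTT"), SequenceRecord("b", "ATGAAA")]
        with pytest.raises(SeqIOError, match="mismatch"):
            backtranslate(aln, cds)

    def test_roundtrip_translation_recovers_protein(self):
        aln = ProteinAlignment(
            [SequenceRecord("a", "MK-V"), SequenceRecord("b", "MKLV")]
        )
        cds = [SequenceRecord("a", "ATGAAAGTT"), SequenceRecord("b", "ATGAAACTGGTT")]
        codon = backtranslate(aln, cds)
        assert [r.seq for r in codon.to_protein().records] == [r.seq for r in aln.records]


class TestFilterCodonColumns:
    def _aln(self, *rows):
        return CodonAlignment([SequenceRecord(f"s{i}", r) for i, r in enumerate(rows)])

    def test_removes_columns_with_two_or_fewer_sequences(self):
        gap = "---"
        aa = "AAA"
        rows = [aa + aa, aa + aa, aa + gap, aa + gap, aa + gap]
        filtered, removed = filter_codon_columns(self._aln(*rows), min_present=3)
        assert removed == [1]
        assert filtered.n_codon_cols == 1
        assert filtered.column_map == [0]

    def test_ungapped_alignment_unchanged(self):
        aln = self._aln("AAAGTT", "AAAGTC", "AAAGTG")
        filtered, removed = filter_codon_columns(aln)
        assert removed == []
        assert [r.seq for r in filtered.records] == [r.seq for r in aln.records]

    def test_intermediate_gap_columns_kept(self):
        # 10 rows, second column has data in 5: kept under the default rule
        rows = ["AAAGTT"] * 5 + ["AAA---"] * 5
        filtered, removed = filter_codon_columns(self._aln(*rows), min_present=3)
        assert removed == []
        assert filtered.n_codon_cols == 2

    def test_idempotent(self):
        rows = ["AAAGTT---", "AAA------", "AAAGTTAAA", "AAAGTT---", "AAA---AAA"]
        once, removed1 = filter_codon_columns(self._aln(*rows))
        twice, removed2 = filter_codon_columns(once)
        assert removed2 == []
        assert [r.seq for r in twice.records] == [r.seq for r in once.records]
        assert twice.column_map == once.column_map

    def test_emptying_alignment_is_error(self):
        with pytest.raises(SeqIOError, match="every codon column"):
            filter_codon_columns(self._aln("AAA", "---", "---"))


class TestPairwiseIdentity:
    def test_hand_counted_values(self, toy_protein_alignment):
        assert pairwise_identity(toy_protein_alignment, "b", "c") == 100.0
        # a vs b: comparable positions M,K/Q,V,A -> 3 of 4 match
        assert pairwise_identity(toy_protein_alignment, "a", "b") == pytest.approx(75.0)

    def test_two_of_three_match(self):
        aln = ProteinAlignment([SequenceRecord("x", "MKV"), SequenceRecord("y", "MQV")])
        assert pairwise_identity(aln, "x", "y") == pytest.approx(66.666667, abs=1e-6)

    def test_gap_positions_excluded(self):
        aln = ProteinAlignment([SequenceRecord("x", "M-V"), SequenceRecord("y", "MQV")])
        assert pairwise_identity(aln, "x", "y") == 100.0

    def test_no_comparable_positions_is_nan(self):
        aln = ProteinAlignment([SequenceRecord("x", "M-"), SequenceRecord("y", "-Q")])
        assert math.isnan(pairwise_identity(aln, "x", "y"))

    def test_unknown_id_raises(self, toy_protein_alignment):
        with pytest.raises(KeyError):
            pairwise_identity(toy_protein_alignment, "a", "zz")

    @given(
        st.lists(
            st.text(alphabet="MKVQA-", min_size=6, max_size=6), min_size=2, max_size=2
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_symmetry(self, rows):
        try:
            aln = ProteinAlignment(
                [SequenceRecord("x", rows[0]), SequenceRecord("y", rows[1])]
            )
        except SeqIOError:
            return
        ab = pairwise_identity(aln, "x", "y")
        ba = pairwise_identity(aln, "y", "x")
        assert (math.isnan(ab) and math.isnan(ba)) or ab == ba


class TestGroupAssignment:
    def test_tsv_round_trip_with_comments(self, tmp_path):
        p = tmp_path / "g.tsv"
        p.write_text("# clusters\na\tmonocot\nb\tdicot\n")
        g = GroupAssignment.from_tsv(p)
        assert g == {"a": "monocot", "b": "dicot"}
        g.to_tsv(tmp_path / "g2.tsv")
        assert GroupAssignment.from_tsv(tmp_path / "g2.tsv") == g

    def test_validation_catches_missing_ids_and_single_label(self):
        g = GroupAssignment({"a": "m", "b": "m"})
        with pytest.raises(SeqIOError, match="missing"):
            g.validate_against(["a", "b", "c"])
        with pytest.raises(SeqIOError, match="distinct"):
            g.validate_against(["a", "b"])
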