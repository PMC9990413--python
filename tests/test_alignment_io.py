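import numpy as np
import pytest

from dolphin.alignment_io import (
    AlignedSequence,
    DomainAlignment,
    TaxonomyMap,
    column_to_residue,
    filter_taxa,
    read_alignment,
    residue_to_column,
    write_fasta,
    write_stockholm,
)
from dolphin.errors import (
    AlignmentShapeError,
    AlignmentValidationError,
    EmptyAfterFilterError,
    EmptyInputError,
    LookupFailedError,
    OutOfRangeError,
)

STOCKHOLM_TOY = """\
# STOCKHOLM 1.0
#=GF AC PFTOY
#=GS s1 TX eukaryota
#=GS s2 TX bacteria
s1 ACDEF
s2 AC-EF
s3 GCDEF
//
"""


def test_read_stockholm_toy(tmp_path):
    path = tmp_path / "toy.sto"
    path.write_text(STOCKHOLM_TOY)
    aln = read_alignment(path, "stockholm")
    assert aln.domain_id == "PFTOY"
    assert aln.length == 5
    assert aln.n_sequences == 3
    assert aln.row("s1").taxon_group == "eukaryota"
    assert aln.row("s3").taxon_group is None


def test_read_aligned_fasta(tmp_path):
    path = tmp_path / "toy.fasta"
    path.write_text(">a\nAC-DE\n>b\nACWDE\n")
    aln = read_alignment(path, "aligned-fasta")
    assert aln.length == 5 and aln.n_sequences == 2


def test_ragged_row_names_offender(tmp_path):
    path = tmp_path / "bad.fasta"
    path.write_text(">a\nACDE\n>b\nACDEF\n")
    with pytest.raises(AlignmentShapeError, match="'a'|'b'"):
        read_alignment(path, "aligned-fasta")


def test_ragged_stockholm(tmp_path):
    path = tmp_path / "bad.sto"
    path.write_text("# STOCKHOLM 1.0\ns1 ACDE\ns2 ACDEF\n//\n")
    with pytest.raises(AlignmentShapeError):
        read_alignment(path, "stockholm")


def test_empty_file(tmp_path):
    path = tmp_path / "empty.sto"
    path.write_text("")
    with pytest.raises(EmptyInputError):
        read_alignment(path, "stockholm")


def test_unknown_characters_listed():
    with pytest.raises(AlignmentValidationError, match=r"\['\*', '1'\]"):
        DomainAlignment("X", (AlignedSequence("s", "AC*1"),))


def test_lowercase_and_dot_normalization(tmp_path):
    """Insert-state letters uppercase; '.' and '-' unify — checked
    character by character against an independent normalization."""
    raw = "aC.d-E"
    path = tmp_path / "ins.fasta"
    path.write_text(f">a\n{raw}\n")
    aln = read_alignment(path, "aligned-fasta")
    expected = "".join(
        "-" if ch in ".-" else ch.upper() for ch in raw
    )
    assert aln.row("a").residues == expected


def test_match_columns_only_turns_inserts_into_gaps(tmp_path):
    path = tmp_path / "ins.fasta"
    path.write_text(">a\naC.d-E\n")
    aln = read_alignment(path, "aligned-fasta", match_columns_only=True)
    assert aln.row("a").residues == "-C---E"


def test_stockholm_round_trip(tmp_path, toy_alignment):
    p1 = tmp_path / "a.sto"
    write_stockholm(toy_alignment, p1)
    again = read_alignment(p1, "stockholm")
    assert again == toy_alignment
    # write-read once more: idempotent
    p2 = tmp_path / "b.sto"
    write_stockholm(again, p2)
    assert read_alignment(p2, "stockholm") == toy_alignment


def test_fasta_round_trip(tmp_path, toy_alignment):
    path = tmp_path / "a.fasta"
    write_fasta(toy_alignment, path)
    again = read_alignment(path, "aligned-fasta", domain_id="TOY")
    assert [s.residues for s in again.sequences] == [
        s.residues for s in toy_alignment.sequences
    ]


class TestFilterTaxa:
    def test_keeps_only_group(self, toy_alignment, toy_taxonomy):
        out = filter_taxa(toy_alignment, toy_taxonomy, keep="eukaryota")
        assert [s.sequence_id for s in out.sequences] == ["s1", "s2", "s4"]
        assert out.length == toy_alignment.length

    def test_identity_when_all_match(self, toy_alignment):
        tax = TaxonomyMap({s.sequence_id: "eukaryota" for s in toy_alignment.sequences})
        out = filter_taxa(toy_alignment, tax, keep="eukaryota")
        assert out == DomainAlignment(
            toy_alignment.domain_id, toy_alignment.sequences
        )

    def test_unknown_ids_become_other_and_drop(self):
        """6-row fixture: survivors enumerated by hand."""
        rows = tuple(
            AlignedSequence(f"s{i}", "ACDE") for i in range(6)
        )
        aln = DomainAlignment("X", rows)
        tax = TaxonomyMap({"s0": "eukaryota", "s2": "eukaryota", "s3": "viruses"})
        out = filter_taxa(aln, tax, keep="eukaryota")
        assert [s.sequence_id for s in out.sequences] == ["s0", "s2"]

    def test_empty_result_raises(self, toy_alignment, toy_taxonomy):
        with pytest.raises(EmptyAfterFilterError):
            filter_taxa(toy_alignment, toy_taxonomy, keep="archaea")

    def test_content_untouched(self, toy_alignment, toy_taxonomy):
        out = filter_taxa(toy_alignment, toy_taxonomy, keep="eukaryota")
        for s in out.sequences:
            assert s.residues == toy_alignment.row(s.sequence_id).residues


class TestResidueToColumn:
    def test_hand_counted(self):
        aln = DomainAlignment("X", (AlignedSequence("s", "A-CD-"),))
        assert residue_to_column(aln, "s", 1) == 1
        assert residue_to_column(aln, "s", 2) == 3
        assert residue_to_column(aln, "s", 3) == 4

    def test_identity_without_gaps(self):
        aln = DomainAlignment("X", (AlignedSequence("s", "ACDEF"),))
        for k in range(1, 6):
            assert residue_to_column(aln, "s", k) == k

    def test_out_of_range(self):
        aln = DomainAlignment("X", (AlignedSequence("s", "A-C"),))
        with pytest.raises(OutOfRangeError):
            residue_to_column(aln, "s", 3)
        with pytest.raises(OutOfRangeError):
            residue_to_column(aln, "s", 0)

    def test_unknown_sequence(self):
        aln = DomainAlignment("X", (AlignedSequence("s", "AC"),))
        with pytest.raises(LookupFailedError):
            residue_to_column(aln, "nope", 1)

    def test_round_trip_and_monotonicity_random_rows(self):
        """residue→column→residue is identity; columns strictly increase.

        Checked against a linear-scan oracle on random gapped rows.
        """
        rng = np.random.default_rng(11)
        for _ in range(20):
            chars = [
                "-" if rng.random() < 0.3 else "ACDEFGHIKLMNPQRSTVWY"[int(rng.integers(20))]
                for _ in range(30)
            ]
            row = "".join(chars)
            if all(ch == "-" for ch in row):
                continue
            aln = DomainAlignment("X", (AlignedSequence("s", row),))
            n_res = sum(ch != "-" for ch in row)
            # independent linear scan
            expected_cols = [i + 1 for i, ch in enumerate(row) if ch != "-"]
            cols = [residue_to_column(aln, "s", k) for k in range(1, n_res + 1)]
            assert cols == expected_cols
            assert cols == sorted(cols) and len(set(cols)) == len(cols)
            for k, col in enumerate(cols, start=1):
                assert column_to_residue(aln, "s", col) == k
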