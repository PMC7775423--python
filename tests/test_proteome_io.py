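import logging

import pytest

from tmdmap.proteome_io import (
    DetectedPeptide,
    ProteinRecord,
    TMDInterval,
    parse_tmhmm,
    read_fasta,
    read_peptide_table,
    strip_peptide_cell,
    validate_intervals,
    write_fasta,
    write_peptide_table,
    write_tmhmm_long,
)


class TestFasta:
    def test_basic_record(self, tmp_path):
        path = tmp_path / "p.fasta"
        path.write_text(">P1 desc here\nMKT\n")
        (rec,) = read_fasta(path)
        assert rec == ProteinRecord("P1", "desc here", "MKT")

    def test_case_folding_and_stop_strip(self, tmp_path):
        path = tmp_path / "p.fasta"
        path.write_text(">P2\nmkt*\n")
        (rec,) = read_fasta(path)
        assert rec.sequence == "MKT"

    def test_duplicate_accession_rejected(self, tmp_path):
        path = tmp_path / "p.fasta"
        path.write_text(">P1\nMKT\n>P1\nMKV\n")
        with pytest.raises(ValueError, match="P1"):
            read_fasta(path)

    def test_non_alphabet_character_names_position(self, tmp_path):
        path = tmp_path / "p.fasta"
        path.write_text(">P1\nMKZT\n")
        with pytest.raises(ValueError, match="position 3"):
            read_fasta(path)

    def test_x_admitted_only_with_allow_x(self, tmp_path):
        path = tmp_path / "p.fasta"
        path.write_text(">P1\nMXT\n")
        with pytest.raises(ValueError):
            read_fasta(path)
        assert read_fasta(path, allow_x=True)[0].sequence == "MXT"

    def test_round_trip(self, tmp_path, toy_proteome):
        path = tmp_path / "out.fasta"
        write_fasta(toy_proteome, path)
        assert read_fasta(path) == toy_proteome


class TestTmhmm:
    def test_long_line(self, tmp_path):
        path = tmp_path / "t.txt"
        path.write_text("P1\tTMHMM2.0\tTMhelix\t7\t29\n")
        assert parse_tmhmm(path) == [TMDInterval("P1", 7, 29, 1)]

    def test_long_ignores_topology_lines(self, tmp_path):
        path = tmp_path / "t.txt"
        path.write_text(
            "# comment\n"
            "P1\tTMHMM2.0\toutside\t1\t9\n"
            "P1\tTMHMM2.0\tTMhelix\t10\t32\n"
            "P1\tTMHMM2.0\tinside\t33\t43\n"
            "P1\tTMHMM2.0\tTMhelix\t44\t66\n"
        )
        assert parse_tmhmm(path, dialect="long") == [
            TMDInterval("P1", 10, 32, 1),
            TMDInterval("P1", 44, 66, 2),
        ]

    def test_short_dialect(self, tmp_path):
        path = tmp_path / "t.txt"
        path.write_text(
            "P1\tlen=120\tExpAA=44\tFirst60=20\tPredHel=2\t"
            "Topology=o10-32i44-66o\n"
            "P2\tlen=80\tExpAA=0\tFirst60=0\tPredHel=0\tTopology=o\n"
        )
        assert parse_tmhmm(path, dialect="short") == [
            TMDInterval("P1", 10, 32, 1),
            TMDInterval("P1", 44, 66, 2),
        ]

    def test_dialects_agree_on_paired_fixtures(self, tmp_path):
        long_path = tmp_path / "long.txt"
        long_path.write_text(
            "P1\tTMHMM2.0\tTMhelix\t10\t32\n"
            "P1\tTMHMM2.0\tTMhelix\t44\t66\n"
            "P3\tTMHMM2.0\tTMhelix\t7\t29\n"
        )
        short_path = tmp_path / "short.txt"
        short_path.write_text(
            "P1\tlen=120\tPredHel=2\tTopology=o10-32i44-66o\n"
            "P2\tlen=80\tPredHel=0\tTopology=o\n"
            "P3\tlen=40\tPredHel=1\tTopology=i7-29o\n"
        )
        assert parse_tmhmm(long_path, "auto") == parse_tmhmm(short_path, "auto")

    def test_predhel_topology_disagreement(self, tmp_path):
        path = tmp_path / "t.txt"
        path.write_text("P9\tPredHel=2\tTopology=o10-32i\n")
        with pytest.raises(ValueError, match="P9"):
            parse_tmhmm(path, dialect="short")

    def test_malformed_coordinate_names_line(self, tmp_path):
        path = tmp_path / "t.txt"
        path.write_text(
            "P1\tTMHMM2.0\tTMhelix\t10\t32\n"
            "P1\tTMHMM2.0\tTMhelix\t44\tXX\n"
        )
        with pytest.raises(ValueError, match="line 2"):
            parse_tmhmm(path, dialect="long")

    def test_overlapping_intervals_rejected(self, tmp_path):
        path = tmp_path / "t.txt"
        path.write_text(
            "P1\tTMHMM2.0\tTMhelix\t10\t32\nP1\tTMHMM2.0\tTMhelix\t30\t50\n"
        )
        with pytest.raises(ValueError, match="P1"):
            parse_tmhmm(path, dialect="long")

    def test_round_trip_long(self, tmp_path, toy_tmds):
        path = tmp_path / "t.txt"
        write_tmhmm_long(toy_tmds, path)
        assert parse_tmhmm(path) == sorted(toy_tmds)

    def test_validation_against_proteome(self, toy_proteome):
        validate_intervals([TMDInterval("P1", 10, 30, 1)], toy_proteome)
        with pytest.raises(ValueError, match="exceeds length"):
            validate_intervals([TMDInterval("P2", 10, 400, 1)], toy_proteome)
        with pytest.raises(ValueError, match="unknown protein"):
            validate_intervals([TMDInterval("NOPE", 1, 5, 1)], toy_proteome)


class TestPeptideTable:
    @pytest.mark.parametrize(
        "cell,plain,mods",
        [
            ("K.GGILR.A", "GGILR", ()),
            ("AAM(Hse)K", "AAMK", ((3, "Hse"),)),
            ("pepTIDEk", "PEPTIDEK", ()),
            ("R.AAM(Hsl)GGK.L", "AAMGGK", ((3, "Hsl"),)),
            ("AA[+57.02]CK", "AACK", ((2, "+57.02"),)),
        ],
    )
    def test_cell_normalisation(self, cell, plain, mods):
        assert strip_peptide_cell(cell) == (plain, mods)

    def test_read_write_round_trip(self, tmp_path):
        peptides = [
            DetectedPeptide("GGILRK", "rep1", "UR-TLC", ("P1",)),
            DetectedPeptide("AAMGGK", "rep2", "FA-CTLC", ("P1", "P3"), "transport"),
        ]
        path = tmp_path / "peps.tsv"
        write_peptide_table(peptides, path)
        back = read_peptide_table(
            path,
            {"peptide": "peptide", "replicate": "replicate",
             "method": "method", "proteins": "proteins",
             "category": "category"},
        )
        assert back == peptides

    def test_missing_mapped_column_errors(self, tmp_path):
        path = tmp_path / "peps.csv"
        path.write_text("seq,rep\nGGILRK,rep1\n")
        with pytest.raises(ValueError, match="nope"):
            read_peptide_table(path, {"peptide": "nope"})

    def test_rows_missing_labels_rejected_with_warning(self, tmp_path, caplog):
        path = tmp_path / "peps.tsv"
        path.write_text(
            "peptide\tmethod\treplicate\n"
            "GGILRK\tUR-TLC\trep1\n"
            "AAMGGK\t\trep1\n"      # missing method
            "\tUR-TLC\trep1\n"      # empty peptide
            "SHORT\tUR-TLC\trep1\n"  # below min length 6
        )
        with caplog.at_level(logging.WARNING):
            peptides = read_peptide_table(
                path,
                {"peptide": "peptide", "method": "method",
                 "replicate": "replicate"},
            )
        assert [p.sequence for p in peptides] == ["GGILRK"]
        assert len(caplog.records) == 3

    def test_comma_delimiter_sniffed(self, tmp_path):
        path = tmp_path / "peps.csv"
        path.write_text("peptide,method,replicate\nGGILRK,UR-TLC,rep1\n")
        (pep,) = read_peptide_table(
            path,
            {"peptide": "peptide", "method": "method", "replicate": "replicate"},
        )
        assert pep.sequence == "GGILRK" and pep.method == "UR-TLC"
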