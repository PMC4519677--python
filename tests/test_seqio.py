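"""I/O round trips, normalization and named-error behaviour."""

import numpy as np
import pytest

from barcodekit import seqio
from barcodekit.distances import DistanceMatrix
from barcodekit.errors import (
    DuplicateIdError,
    IllegalCharacterError,
    LengthMismatchError,
    SequenceFormatError,
    SpeciesMapError,
)
from barcodekit.marker_design import MarkerPair, PrimerCandidate
from barcodekit.nj_phylo import PhyloTree, _Node


def write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestFasta:
    def test_round_trip_preserves_ids_and_order(self, tmp_path):
        p = write(tmp_path, "a.fasta", ">s2\nACGT\n>s1\nGGTT\n")
        seqs = seqio.read_fasta(p)
        assert list(seqs) == ["s2", "s1"]
        out = tmp_path / "b.fasta"
        seqio.write_fasta(seqs, out)
        assert seqio.read_fasta(out) == seqs

    def test_lowercase_and_u_normalized(self, tmp_path):
        p = write(tmp_path, "a.fasta", ">s\nacgu\n")
        assert seqio.read_fasta(p) == {"s": "ACGT"}

    def test_illegal_character_names_record(self, tmp_path):
        p = write(tmp_path, "a.fasta", ">ok\nACGT\n>bad\nAXGT\n")
        with pytest.raises(IllegalCharacterError, match="bad"):
            seqio.read_fasta(p)

    def test_duplicate_id_rejected(self, tmp_path):
        p = write(tmp_path, "a.fasta", ">s\nACGT\n>s\nACGT\n")
        with pytest.raises(DuplicateIdError):
            seqio.read_fasta(p)

    def test_empty_file_rejected(self, tmp_path):
        with pytest.raises(SequenceFormatError):
            seqio.read_fasta(write(tmp_path, "a.fasta", ""))


class TestQuality:
    def test_fastq_sanger_offset(self, tmp_path):
        p = write(tmp_path, "a.fastq", "@r1\nACGT\n+\nIIII\n")
        q = seqio.read_quality(p)["r1"]
        assert list(q.phred) == [40, 40, 40, 40]

    def test_fasta_qual_pairing(self, tmp_path):
        fa = write(tmp_path, "a.fasta", ">r1\nACG\n")
        ql = write(tmp_path, "a.qual", ">r1\n20 19 40\n")
        q = seqio.read_quality(fa, ql)["r1"]
        assert list(q.phred) == [20, 19, 40]

    def test_length_mismatch_names_record(self, tmp_path):
        fa = write(tmp_path, "a.fasta", ">r1\nACGT\n")
        ql = write(tmp_path, "a.qual", ">r1\n20 19 40\n")
        with pytest.raises(LengthMismatchError, match="r1"):
            seqio.read_quality(fa, ql)

    def test_id_in_one_file_only(self, tmp_path):
        fa = write(tmp_path, "a.fasta", ">r1\nACG\n")
        ql = write(tmp_path, "a.qual", ">r2\n20 19 40\n")
        with pytest.raises(SequenceFormatError):
            seqio.read_quality(fa, ql)


class TestSpeciesMap:
    def test_parse(self, tmp_path):
        p = write(tmp_path, "m.tsv", "sample_id\tspecies\nChe1\tA. cherimola\n")
        recs = seqio.read_species_map(p)
        assert recs["Che1"].species == "A. cherimola"

    def test_empty_file(self, tmp_path):
        with pytest.raises(SpeciesMapError):
            seqio.read_species_map(write(tmp_path, "m.tsv", ""))

    def test_duplicate_sample(self, tmp_path):
        p = write(tmp_path, "m.tsv",
                  "sample_id\tspecies\nChe1\tx\nChe1\ty\n")
        with pytest.raises(DuplicateIdError):
            seqio.read_species_map(p)

    def test_empty_species(self, tmp_path):
        p = write(tmp_path, "m.tsv", "sample_id\tspecies\nChe1\t\n")
        with pytest.raises(SpeciesMapError):
            seqio.read_species_map(p)


class TestDistanceTsv:
    def test_six_decimal_cells_and_round_trip(self, tmp_path):
        m = DistanceMatrix(labels=["A", "B"],
                           d=np.array([[0.0, 0.0085], [0.0085, 0.0]]),
                           sites_used=None, model="K2P")
        p = tmp_path / "d.tsv"
        seqio.write_distance_tsv(m, p)
        assert "0.008500" in p.read_text()
        back = seqio.read_distance_tsv(p)
        assert back.labels == ["A", "B"]
        np.testing.assert_allclose(back.d, m.d, atol=5e-7)


class TestNewick:
    def test_three_taxon_star(self, tmp_path):
        root = _Node(children=[(_Node(label="A"), 0.1),
                               (_Node(label="B"), 0.1),
                               (_Node(label="C"), 0.1)])
        tree = PhyloTree(root=root, labels=["A", "B", "C"])
        p = tmp_path / "t.nwk"
        seqio.write_newick(tree, p)
        assert p.read_text().strip() == "(A:0.100000,B:0.100000,C:0.100000);"

    def test_round_trip_topology_via_dendropy(self, tmp_path):
        inner = _Node(children=[(_Node(label="A"), 0.1), (_Node(label="B"), 0.2)],
                      support=87)
        root = _Node(children=[(inner, 0.05), (_Node(label="C"), 0.15),
                               (_Node(label="D"), 0.25)])
        tree = PhyloTree(root=root, labels=["A", "B", "C", "D"])
        p = tmp_path / "t.nwk"
        seqio.write_newick(tree, p)
        parsed = seqio.read_newick(p)
        taxa = {leaf.taxon.label for leaf in parsed.leaf_node_iter()}
        assert taxa == {"A", "B", "C", "D"}
        lengths = sorted(e.length for e in parsed.edges() if e.length is not None)
        assert lengths == sorted([0.1, 0.2, 0.05, 0.15, 0.25])


class TestMarkerReport:
    def test_one_pair_one_row_seven_columns(self, tmp_path):
        fwd = PrimerCandidate("m1_F", "F", "ACGTACGTACGTACGTA", (0, 17), 58.3, True)
        rev = PrimerCandidate("m1_R", "R", "TGCATGCATGCATGCAT", (300, 317), 58.6, False)
        pair = MarkerPair("m1", fwd, rev, "speciesX", 317, 65)
        p = tmp_path / "markers.tsv"
        seqio.write_marker_report([pair], p)
        lines = p.read_text().strip().splitlines()
        assert len(lines) == 2  # header + one data row
        assert len(lines[1].split("\t")) == 7
        assert lines[0].split("\t") == seqio.MARKER_REPORT_COLUMNS
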