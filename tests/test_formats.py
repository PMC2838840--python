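"""I/O layer: parsing, validation errors, coordinate conventions, round-trips."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from estkit.formats import (
    ClusterTable,
    FormatError,
    GoAnnotation,
    HitRecord,
    MsaBlock,
    SeqRecord,
    read_clusters,
    read_fasta,
    read_gff,
    read_go,
    read_hits,
    read_msa,
    write_fasta,
    write_gff,
    write_msa,
)

HIT_LINE = "q1\ts1\t98.0\t100\t2\t0\t1\t100\t5\t104\t1e-30\t180"


class TestFasta:
    def test_parse_multiline_and_uppercase(self, tmp_path):
        f = tmp_path / "a.fa"
        f.write_text(">s1 desc\nacgt\nACGT\n")
        recs = read_fasta(f)
        assert len(recs) == 1
        assert recs[0].id == "s1"
        assert recs[0].description == "desc"
        assert recs[0].sequence == "ACGTACGT"

    def test_two_records(self, tmp_path):
        f = tmp_path / "a.fa"
        f.write_text(">a\nA\n>b\nC\n")
        assert [r.id for r in read_fasta(f)] == ["a", "b"]

    @pytest.mark.parametrize(
        "content, fragment",
        [
            (">a\nACGT\n>a\nACGT\n", "duplicate"),
            ("", "no FASTA records"),
            (">a\nAC!T\n", "illegal"),
            (">a\n\n>b\nAC\n", "no sequence"),
        ],
    )
    def test_errors(self, tmp_path, content, fragment):
        f = tmp_path / "bad.fa"
        f.write_text(content)
        with pytest.raises(FormatError, match=fragment):
            read_fasta(f)

    @given(
        seqs=st.lists(
            st.text(alphabet="ACGTN", min_size=1, max_size=200),
            min_size=1,
            max_size=5,
        )
    )
    def test_round_trip(self, tmp_path_factory, seqs):
        recs = [SeqRecord(id=f"s{i}", sequence=s) for i, s in enumerate(seqs)]
        path = tmp_path_factory.mktemp("rt") / "rt.fa"
        write_fasta(recs, path)
        back = read_fasta(path)
        assert [(r.id, r.sequence) for r in back] == [
            (r.id, r.sequence) for r in recs
        ]


class TestHits:
    def test_twelve_columns(self, tmp_path):
        f = tmp_path / "h.tsv"
        f.write_text(HIT_LINE + "\n")
        (h,) = read_hits(f)
        assert h.qseqid == "q1" and h.evalue == 1e-30 and h.frame is None

    def test_comments_and_blanks_skipped(self, tmp_path):
        f = tmp_path / "h.tsv"
        f.write_text("# comment\n\n" + HIT_LINE + "\n")
        assert len(read_hits(f)) == 1

    def test_thirteenth_column_is_frame(self, tmp_path):
        f = tmp_path / "h.tsv"
        f.write_text(HIT_LINE + "\t-2\n")
        assert read_hits(f)[0].frame == -2

    def test_wrong_column_count(self, tmp_path):
        f = tmp_path / "h.tsv"
        f.write_text("\t".join(HIT_LINE.split("\t")[:11]) + "\n")
        with pytest.raises(FormatError, match="12 or 13"):
            read_hits(f)

    def test_minus_orientation_preserved(self, tmp_path):
        f = tmp_path / "h.tsv"
        cols = HIT_LINE.split("\t")
        cols[8], cols[9] = "200", "101"
        f.write_text("\t".join(cols) + "\n")
        (h,) = read_hits(f)
        assert h.sstart == 200 and h.send == 101
        assert h.subject_minus
        assert h.subject_interval == (100, 200)


class TestGff:
    def test_coordinate_convention(self, tmp_path):
        f = tmp_path / "a.gff3"
        f.write_text("chr1\tsrc\tCDS\t1\t10\t.\t+\t0\tID=c1\n")
        (feat,) = read_gff(f)
        assert (feat.start, feat.end) == (0, 10)
        assert feat.feature_id == "c1"

    def test_length_one_interval(self, tmp_path):
        f = tmp_path / "a.gff3"
        f.write_text("chr1\tsrc\tCDS\t100\t100\t.\t-\t0\tID=c1\n")
        (feat,) = read_gff(f)
        assert (feat.start, feat.end) == (99, 100)

    def test_bad_strand(self, tmp_path):
        f = tmp_path / "a.gff3"
        f.write_text("chr1\tsrc\tCDS\t1\t10\t.\t?\t0\tID=c1\n")
        with pytest.raises(FormatError, match="strand"):
            read_gff(f)

    def test_round_trip_identity(self, tmp_path):
        from estkit.formats import GenomeFeature

        feats = [
            GenomeFeature("chr1", 0, 10, "+", "CDS", "a"),
            GenomeFeature("chr2", 99, 100, "-", "gene", "b"),
        ]
        p = tmp_path / "rt.gff3"
        write_gff(feats, p)
        assert read_gff(p) == feats


class TestClustersAndMsa:
    def test_cluster_parse(self, tmp_path):
        f = tmp_path / "c.txt"
        f.write_text("c1: e1 e2 e3\nc2: e4 e5\ne9\ne10\n")
        t = read_clusters(f)
        assert t.contig_members == {"c1": ["e1", "e2", "e3"], "c2": ["e4", "e5"]}
        assert t.singletons == ["e9", "e10"]
        assert t.n_ests == 7

    def test_singleton_listed_as_contig_is_error(self, tmp_path):
        f = tmp_path / "c.txt"
        f.write_text("c1: e1\n")
        with pytest.raises(FormatError, match="contigs need"):
            read_clusters(f)

    def test_duplicate_est_rejected(self):
        with pytest.raises(ValueError, match="twice"):
            ClusterTable(contig_members={"c1": ["e1", "e2"]}, singletons=["e1"])

    def test_msa_blocks_round_trip(self, tmp_path):
        blocks = [
            MsaBlock("c1", [("e1", "ACGT"), ("e2", "ACGA")]),
            MsaBlock("c2", [("e3", "--GT-"), ("e4", "ACGTN")]),
        ]
        p = tmp_path / "m.afa"
        write_msa(blocks, p)
        back = read_msa(p)
        assert [(b.contig_id, b.rows) for b in back] == [
            (b.contig_id, b.rows) for b in blocks
        ]

    def test_ragged_msa_is_error(self, tmp_path):
        f = tmp_path / "m.afa"
        f.write_text("# contig: c1\n>e1\nACGT\n>e2\nACG\n")
        with pytest.raises(FormatError, match="ragged"):
            read_msa(f)


class TestGo:
    def test_iea_is_parsed_not_filtered(self, tmp_path):
        f = tmp_path / "go.tsv"
        f.write_text(
            "seq_id\tgo_id\tevidence_code\tnamespace\n"
            "s1\tGO:0005524\tIEA\tmolecular_function\n"
        )
        (a,) = read_go(f)
        assert a.evidence_code == "IEA"

    def test_malformed_go_id(self):
        with pytest.raises(ValueError, match="GO id"):
            GoAnnotation("s1", "GO:12", "IDA", "molecular_function")


class TestHitRecordInvariants:
    def test_negative_evalue_rejected(self):
        with pytest.raises(ValueError):
            HitRecord("q", "s", 90.0, 50, 0, 0, 1, 50, 1, 50, -1.0, 10.0)

    def test_qstart_after_qend_rejected(self):
        with pytest.raises(ValueError):
            HitRecord("q", "s", 90.0, 50, 0, 0, 60, 50, 1, 50, 0.0, 10.0)
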