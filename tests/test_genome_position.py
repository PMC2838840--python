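"""Positional classification of genome hits against CDS annotations."""

import numpy as np
import pytest

from estkit.formats import GenomeFeature, HitRecord, read_fasta, read_gff, read_hits
from estkit.genome_position import (
    classify_all,
    classify_hit,
    seqid_distribution,
)

from .oracles import classify_oracle


def _cds(seqid, start, end, fid):
    return GenomeFeature(seqid, start, end, "+", "CDS", fid)


def _genome_hit(q, seqid, sstart, send, e=1e-20):
    length = abs(send - sstart) + 1
    return HitRecord(q, seqid, 99.0, length, 0, 0, 1, length, sstart, send, e, 100.0)


class TestClassifyHit:
    FEATS = [_cds("chr1", 50, 300, "c1")]

    @pytest.mark.parametrize(
        "interval, expected",
        [
            ((100, 200), "inside"),
            ((40, 120), "spanning"),
            ((300, 400), "spanning"),  # abutting: gap 0
            ((301, 400), "utr_range"),
        ],
    )
    def test_classes(self, interval, expected):
        c = classify_hit("q", "chr1", *interval, self.FEATS)
        assert c.cls == expected

    def test_utr_boundary_inclusive(self):
        # hit ends at 1000; CDS starts at 5375 -> gap exactly 4375
        feats = [_cds("chr1", 5375, 6000, "c1")]
        c = classify_hit("q", "chr1", 900, 1000, feats)
        assert c.distance_to_nearest_cds == 4375 and c.cls == "utr_range"
        feats = [_cds("chr1", 5376, 6000, "c1")]
        c = classify_hit("q", "chr1", 900, 1000, feats)
        assert c.distance_to_nearest_cds == 4376 and c.cls == "distal"

    def test_no_cds_on_seqid_is_distal_with_sentinel(self):
        c = classify_hit("q", "chrX", 0, 100, self.FEATS)
        assert c.cls == "distal"
        assert c.distance_to_nearest_cds is None
        assert c.nearest_feature_id is None

    def test_nearest_tie_broken_by_feature_id(self):
        feats = [_cds("chr1", 200, 300, "b"), _cds("chr1", 0, 100, "a")]
        c = classify_hit("q", "chr1", 150, 150 + 1, feats)
        assert c.distance_to_nearest_cds == 49
        # equidistant features: [0,100) and [200,300) around [149,151)
        c = classify_hit("q", "chr1", 149, 151, feats)
        assert c.nearest_feature_id == "a"

    def test_matches_interval_scan_oracle(self):
        rng = np.random.default_rng(13)
        for _ in range(300):
            n_feats = int(rng.integers(0, 8))
            feats, triples = [], []
            for i in range(n_feats):
                s = int(rng.integers(0, 20000))
                e = s + int(rng.integers(1, 3000))
                feats.append(_cds("chr1", s, e, f"f{i}"))
                triples.append((s, e, f"f{i}"))
            hs = int(rng.integers(0, 22000))
            he = hs + int(rng.integers(1, 2500))
            got = classify_hit("q", "chr1", hs, he, feats, utr_max=4375)
            cls, gap, fid = classify_oracle(hs, he, triples, utr_max=4375)
            assert got.cls == cls
            assert got.distance_to_nearest_cds == gap
            assert got.nearest_feature_id == fid

    def test_monotone_in_utr_max(self):
        rng = np.random.default_rng(17)
        feats = [_cds("chr1", 10000, 12000, "c")]
        for _ in range(50):
            hs = int(rng.integers(0, 9000))
            he = hs + int(rng.integers(1, 800))
            small = classify_hit("q", "chr1", hs, he, feats, utr_max=2000).cls
            large = classify_hit("q", "chr1", hs, he, feats, utr_max=6000).cls
            if small == "utr_range":
                assert large == "utr_range"
            if large == "distal":
                assert small == "distal"


class TestClassifyAll:
    def test_partition_conservation(self):
        feats = [_cds("chr1", 100, 200, "c1")]
        hits = [
            _genome_hit("q1", "chr1", 120, 150),
            _genome_hit("q2", "chr1", 90, 130),
            _genome_hit("q3", "chr1", 300, 380),
            _genome_hit("q4", "chr1", 9000, 9100),
        ]
        cls, summary = classify_all(hits, feats, utr_max=4375)
        assert sum(summary.values()) == len(cls) == 4
        assert summary == {"inside": 1, "spanning": 1, "utr_range": 1, "distal": 1}

    def test_minus_orientation_normalised(self):
        feats = [_cds("chr1", 100, 200, "c1")]
        (c,), _ = classify_all([_genome_hit("q1", "chr1", 150, 121)], feats)
        assert (c.start, c.end) == (120, 150) and c.cls == "inside"

    def test_duplicate_query_rejected(self):
        hits = [_genome_hit("q1", "chr1", 1, 10), _genome_hit("q1", "chr1", 5, 14)]
        with pytest.raises(ValueError, match="best-hit"):
            classify_all(hits, [])

    def test_simulated_transcript_hits_never_distal(self, sim_fixture):
        gt, d = sim_fixture
        hits = read_hits(d / "hits_genome.tsv")
        feats = read_gff(d / "annotation.gff3")
        cls, summary = classify_all(hits, feats)
        got = {c.qseqid: c.cls for c in cls}
        assert got == gt.expected_class
        transcript_queries = {q for q, cl in gt.expected_class.items()
                              if not q.startswith("frag")}
        assert all(got[q] != "distal" for q in transcript_queries)
        frag_queries = {q for q in gt.expected_class if q.startswith("frag")}
        assert frag_queries and all(got[q] == "distal" for q in frag_queries)


class TestSeqidDistribution:
    def test_percents(self):
        feats = [_cds("chr1", 0, 10, "a"), _cds("chr2", 0, 10, "b")]
        hits = [
            _genome_hit("q1", "chr1", 1, 5),
            _genome_hit("q2", "chr2", 1, 5),
            _genome_hit("q3", "chr2", 11, 15),
            _genome_hit("q4", "chr2", 21, 25),
        ]
        cls, _ = classify_all(hits, feats)
        df = seqid_distribution(cls, feats).set_index("seqid")
        assert df.loc["chr1", "pct_hits"] == 25.0
        assert df.loc["chr2", "pct_hits"] == 75.0
        assert df["pct_hits"].sum() == pytest.approx(100.0)
        assert df["pct_cds"].sum() == pytest.approx(100.0)

    def test_uniform_placement_tracks_cds_density(self, sim_fixture):
        gt, d = sim_fixture
        hits = read_hits(d / "hits_genome.tsv")
        feats = read_gff(d / "annotation.gff3")
        cls, _ = classify_all(hits, feats)
        df = seqid_distribution(cls, feats).set_index("seqid")
        # genes are placed round-robin; hit share should track CDS share
        main = df.loc[[s for s in df.index if s != "chrD"]]
        n = main["n_hits"].sum()
        for _, row in main.iterrows():
            p = row["pct_cds"] / 100
            se = (p * (1 - p) / n) ** 0.5 * 100
            assert abs(row["pct_hits"] - row["pct_cds"]) < 3 * se + 1e-9
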