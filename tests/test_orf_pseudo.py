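"""Six-frame ORF scanning and the premature-stop pseudogene screen."""

import numpy as np
import pytest

from estkit.formats import SeqRecord, read_fasta, read_hits
from estkit.orf_pseudo import (
    find_orfs,
    orf_stats,
    premature_stop_screen,
)

from .oracles import _rc, orf_oracle

SENSE = "GCT"  # alanine


def _seq(s, sid="s"):
    return SeqRecord(id=sid, sequence=s)


def _rand_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestFindOrfs:
    def test_simple_orf_length_includes_stop(self):
        s = "ATG" + SENSE * 38 + "TAA"  # 120 nt
        (orf,) = find_orfs(_seq(s), min_len=100, both_strands=False)
        assert orf.length_nt == 120
        assert (orf.start, orf.end) == (0, 120)
        assert not orf.incomplete_3prime

    def test_no_orfs_in_poly_c(self):
        assert find_orfs(_seq("C" * 300)) == []

    def test_leftmost_atg_absorbs_nested(self):
        s = "ATG" + "ATG" + SENSE * 37 + "TAA"
        orfs = find_orfs(_seq(s), min_len=100, both_strands=False)
        assert len(orfs) == 1 and orfs[0].start == 0

    def test_incomplete_3prime_flagged(self):
        s = "ATG" + SENSE * 40  # no stop
        (orf,) = find_orfs(_seq(s), min_len=100, both_strands=False)
        assert orf.incomplete_3prime

    def test_revcomp_mirror(self):
        rng = np.random.default_rng(4)
        for _ in range(30):
            s = _rand_seq(rng, int(rng.integers(60, 500)))
            fwd = find_orfs(_seq(s), min_len=30)
            rev = find_orfs(_seq(_rc(s)), min_len=30)
            L = len(s)
            mirrored = sorted(
                (L - o.end, L - o.start, {"+": "-", "-": "+"}[o.strand],
                 o.length_nt, o.incomplete_3prime)
                for o in rev
            )
            assert mirrored == sorted(
                (o.start, o.end, o.strand, o.length_nt, o.incomplete_3prime)
                for o in fwd
            )

    def test_every_orf_translates_without_internal_stop(self):
        from Bio.Seq import Seq

        rng = np.random.default_rng(8)
        for _ in range(50):
            s = _rand_seq(rng, 400)
            for o in find_orfs(_seq(s), min_len=60):
                sub = s[o.start : o.end]
                if o.strand == "-":
                    sub = _rc(sub)
                aa = str(Seq(sub).translate())
                body = aa[:-1] if not o.incomplete_3prime else aa
                assert "*" not in body

    def test_matches_atg_walk_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(200):
            s = _rand_seq(rng, int(rng.integers(10, 600)))
            if len(s) < 3:
                continue
            got = sorted(
                (o.start, o.end, o.strand, o.frame, o.length_nt, o.incomplete_3prime)
                for o in find_orfs(_seq(s), min_len=60)
            )
            # oracle frame is the offset on the scanned strand
            exp = orf_oracle(s, min_len=60)
            assert got == sorted(exp)


class TestOrfStats:
    def test_lower_middle_median(self):
        orfs = [
            # one ORF per sequence with the given lengths
            find_orfs(_seq("ATG" + SENSE * ((n - 6) // 3) + "TAA", f"s{n}"),
                      min_len=30, both_strands=False)[0]
            for n in (102, 225, 1464)
        ]
        st = orf_stats(orfs)
        assert st["median_longest_orf"] == 225
        assert (st["min"], st["max"]) == (102, 1464)
        even = orf_stats(orfs[:2])
        assert even["median_longest_orf"] == 102  # lower-middle of even count

    def test_empty_is_empty_not_error(self):
        assert orf_stats([]) == {}

    def test_planted_lengths_recovered(self):
        rng = np.random.default_rng(21)
        planted = sorted(int(3 * rng.integers(34, 200)) for _ in range(15))
        seqs = []
        for i, ln in enumerate(planted):
            body = "ATG" + SENSE * (ln // 3 - 2) + "TAA"
            pad = "CCCCC"  # no ORFs in padding
            seqs.append(_seq(pad + body + pad, f"p{i}"))
        all_orfs = []
        for rec in seqs:
            all_orfs.extend(find_orfs(rec, min_len=100))
        st = orf_stats(all_orfs)
        assert st["median_longest_orf"] == planted[(len(planted) - 1) // 2]
        assert st["min"] == planted[0] and st["max"] == planted[-1]


class TestStopScreen:
    def _backtranslate(self, n_codons):
        return "ATG" + SENSE * (n_codons - 2) + "TAA"

    def test_clean_region_verdict_unknown(self):
        region = _seq(self._backtranslate(100))
        sc = premature_stop_screen("M" + "A" * 98, region, 1, (0, 100))
        assert sc.n_premature_stops == 0 and sc.verdict == "unknown"

    def test_one_planted_stop_found(self):
        s = self._backtranslate(100)
        s = s[: 50 * 3] + "TGA" + s[51 * 3 :]
        sc = premature_stop_screen("", _seq(s), 1, (0, 100))
        assert sc.n_premature_stops == 1
        assert sc.verdict == "stop_codon"
        assert sc.stop_positions == (50,)

    def test_terminal_stop_not_counted(self):
        region = _seq(self._backtranslate(60))
        sc = premature_stop_screen("", region, 1, (0, 60))
        assert sc.n_premature_stops == 0  # codon 59 is the terminator

    def test_negative_frame_translates_revcomp(self):
        s = self._backtranslate(80)
        sc = premature_stop_screen("", _seq(_rc(s)), -1, (0, 80))
        assert sc.n_premature_stops == 0 and sc.span_end == 80

    def test_padding_outside_span_is_invariant(self):
        s = self._backtranslate(50)
        s_mut = s[: 20 * 3] + "TAG" + s[21 * 3 :]
        base = premature_stop_screen("", _seq(s_mut), 1, (0, 50))
        padded = premature_stop_screen("", _seq(s_mut + "TAATAA"), 1, (0, 50))
        assert padded.n_premature_stops == base.n_premature_stops == 1

    @pytest.mark.parametrize("frame", [0, 4, -4])
    def test_frame_out_of_range(self, frame):
        with pytest.raises(ValueError, match="frame"):
            premature_stop_screen("", _seq("ATGTAA"), frame, (0, 1))

    def test_span_outside_translation(self):
        with pytest.raises(ValueError, match="span"):
            premature_stop_screen("", _seq("ATGTAA"), 1, (0, 5))

    def test_planted_pseudogene_stops_recovered(self, sim_fixture):
        gt, d = sim_fixture
        genome = {r.id: r for r in read_fasta(d / "genome.fasta")}
        hits = {h.qseqid: h for h in read_hits(d / "hits_pseudo.tsv")}
        assert len(hits) == len(gt.pseudogenes)
        for reg in gt.pseudogenes:
            h = hits[reg["protein_id"]]
            lo, hi = h.subject_interval
            region = SeqRecord(id="r", sequence=genome[h.sseqid].sequence[lo:hi])
            sc = premature_stop_screen(
                reg["protein"], region, h.frame, (0, (hi - lo) // 3)
            )
            assert sc.n_premature_stops == reg["n_stops"]
            expected_verdict = "stop_codon" if reg["n_stops"] else "unknown"
            assert sc.verdict == expected_verdict
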