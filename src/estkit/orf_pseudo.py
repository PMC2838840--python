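"""ORF scanning and premature-stop-codon pseudogene screening.

ORFs are maximal ATG-to-stop codon runs (leftmost ATG per stop) in up to six
frames under the standard genetic code; ORFs truncated by the sequence end are
flagged `incomplete_3prime` and excluded from summary statistics by default.

The pseudogene screen translates a genomic region in a stated frame and counts
stop codons strictly inside the protein-aligned span — a premature in-frame
stop in a region that otherwise matches a reference protein is the classic
signature of a pseudogenized gene copy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from Bio.Seq import Seq

from .formats import SeqRecord

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
START_CODON = "ATG"
DEFAULT_MIN_ORF_NT = 100


@dataclass(frozen=True)
class OrfRecord:
    seq_id: str
    strand: str  # '+' or '-'
    frame: int  # 0..2, offset within the scanned strand
    start: int  # 0-based half-open on the FORWARD strand
    end: int
    length_nt: int
    incomplete_3prime: bool = False


@dataclass(frozen=True)
class StopScreen:
    query_id: str
    region_id: str
    frame: int
    span_start: int  # codon interval within the translated region
    span_end: int
    n_premature_stops: int
    stop_positions: tuple[int, ...]  # codon indices relative to span start
    verdict: str  # 'stop_codon' or 'unknown'


def _revcomp(s: str) -> str:
    return str(Seq(s).reverse_complement())


def find_orfs(
    seq: SeqRecord,
    min_len: int = DEFAULT_MIN_ORF_NT,
    both_strands: bool = True,
) -> list[OrfRecord]:
    """All maximal ATG->stop ORFs of length >= min_len (length includes the
    stop codon). Within one frame, only the leftmost ATG before each stop is
    reported; nested ATGs are absorbed. Coordinates are on the forward strand.
    """
    if len(seq.sequence) < 3:
        raise ValueError(f"sequence {seq.id} shorter than one codon")
    L = len(seq.sequence)
    out: list[OrfRecord] = []
    strands = [("+", seq.sequence)]
    if both_strands:
        strands.append(("-", _revcomp(seq.sequence)))
    for strand, s in strands:
        for frame in range(3):
            atg: Optional[int] = None
            pos = frame
            while pos + 3 <= len(s):
                codon = s[pos : pos + 3]
                if atg is None:
                    if codon == START_CODON:
                        atg = pos
                elif codon in STOP_CODONS:
                    _emit(out, seq.id, strand, frame, atg, pos + 3, L, min_len, False)
                    atg = None
                pos += 3
            if atg is not None:
                # ran off the end without a stop: incomplete at the 3' end
                last = frame + ((len(s) - frame) // 3) * 3
                _emit(out, seq.id, strand, frame, atg, last, L, min_len, True)
    out.sort(key=lambda o: (o.start, o.end, o.strand, o.frame))
    return out


def _emit(out, seq_id, strand, frame, s_start, s_end, L, min_len, incomplete):
    length = s_end - s_start
    if length < min_len:
        return
    if strand == "+":
        f_start, f_end = s_start, s_end
    else:
        f_start, f_end = L - s_end, L - s_start
    out.append(
        OrfRecord(
            seq_id=seq_id, strand=strand, frame=frame, start=f_start, end=f_end,
            length_nt=length, incomplete_3prime=incomplete,
        )
    )


def orf_stats(
    orfs: Sequence[OrfRecord], include_incomplete: bool = False
) -> dict:
    """Median/min/max of the per-sequence longest ORF length.

    The median of an even count is the lower-middle value. Sequences are
    grouped by id; ORFs flagged incomplete at the 3' end are excluded unless
    requested. No ORFs anywhere -> empty dict.
    """
    pool = [o for o in orfs if include_incomplete or not o.incomplete_3prime]
    longest: dict[str, int] = {}
    for o in pool:
        longest[o.seq_id] = max(longest.get(o.seq_id, 0), o.length_nt)
    if not longest:
        return {}
    lengths = sorted(longest.values())
    median = lengths[(len(lengths) - 1) // 2]  # lower-middle for even counts
    return {
        "median_longest_orf": median,
        "min": lengths[0],
        "max": lengths[-1],
        "n_sequences": len(lengths),
    }


def premature_stop_screen(
    protein: str,
    genome_region: SeqRecord,
    frame: int,
    aligned_span: tuple[int, int],
    query_id: str = "",
) -> StopScreen:
    """Count premature stop codons inside the protein-aligned span of a
    translated genomic region.

    `frame` follows the tabular-hit convention: 1..3 translate the region
    forward from offset frame-1; -1..-3 reverse-complement first. The span is
    a 0-based half-open codon interval within the translated peptide. A stop
    at the span's final codon is a legitimate terminator and is not counted.
    """
    if frame not in (-3, -2, -1, 1, 2, 3):
        raise ValueError(f"frame {frame} out of range")
    if len(genome_region.sequence) < 3:
        raise ValueError("region shorter than one codon")
    s = genome_region.sequence if frame > 0 else _revcomp(genome_region.sequence)
    offset = abs(frame) - 1
    coding = s[offset : offset + ((len(s) - offset) // 3) * 3]
    peptide = str(Seq(coding).translate())
    cs, ce = aligned_span
    if not (0 <= cs < ce <= len(peptide)):
        raise ValueError(
            f"aligned span [{cs},{ce}) outside translation of {len(peptide)} codons"
        )
    stops = [i for i in range(cs, ce) if peptide[i] == "*"]
    if stops and stops[-1] == ce - 1:
        stops = stops[:-1]  # terminal stop at the span's 3' end
    n = len(stops)
    return StopScreen(
        query_id=query_id or f"protein[{len(protein)}aa]",
        region_id=genome_region.id,
        frame=frame,
        span_start=cs,
        span_end=ce,
        n_premature_stops=n,
        stop_positions=tuple(i - cs for i in stops),
        verdict="stop_codon" if n >= 1 else "unknown",
    )
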