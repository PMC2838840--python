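"""Microsatellite (SSR) detection with MISA-style criteria.

A reportable SSR is a maximal tandem run of a primitive 2-6 nt motif with at
least 6 complete units for di-nucleotide motifs and at least 5 for longer
motifs. Only complete units count; runs are broken at ambiguous bases;
mononucleotide repeats are out of scope. Two SSRs on one sequence separated
by at most 100 bases form a compound SSR.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from typing import Optional, Sequence

from .formats import SeqRecord, UNAMBIGUOUS

DEFAULT_THRESHOLDS: dict[int, int] = {2: 6, 3: 5, 4: 5, 5: 5, 6: 5}
DEFAULT_MAX_COMPOUND_GAP = 100

_COMP = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class SSRRecord:
    seq_id: str
    motif: str
    repeats: int  # complete units
    start: int  # 0-based half-open
    end: int
    compound_group: Optional[str] = None

    @property
    def motif_len(self) -> int:
        return len(self.motif)

    @property
    def canonical_motif(self) -> str:
        """Lexicographically smallest among all rotations of the motif and of
        its reverse complement — a strand/phase-independent class label."""
        rc = self.motif.translate(_COMP)[::-1]
        rots = [m[i:] + m[:i] for m in (self.motif, rc) for i in range(len(m))]
        return min(rots)


def _primitive(motif: str) -> bool:
    p = len(motif)
    for d in range(1, p):
        if p % d == 0 and motif == motif[:d] * (p // d):
            return False
    return True


def find_ssrs(
    seq: SeqRecord, thresholds: dict[int, int] = DEFAULT_THRESHOLDS
) -> list[SSRRecord]:
    """Scan one sequence for maximal primitive repeat runs meeting the
    per-period unit thresholds; records are reported leftmost-first.

    Candidate runs are maximal stretches of the self-match relation
    s[j] == s[j-p] (restricted to unambiguous bases), truncated to whole
    units. A run whose motif is a repetition of a shorter motif belongs to
    the shorter period and is not re-reported. Where candidates of different
    periods overlap (possible at period boundaries), the left-to-right,
    smallest-period-first candidate wins, so reported records never overlap.
    """
    s = seq.sequence
    n = len(s)
    candidates: list[tuple[int, int, int, str, int]] = []  # start, p, end, motif, units
    for p in sorted(thresholds):
        if p < 2:
            raise ValueError("mononucleotide repeats are out of scope")
        j = p
        while j < n:
            if s[j] == s[j - p] and s[j] in UNAMBIGUOUS:
                a = j - p  # stretch start
                while j < n and s[j] in UNAMBIGUOUS and s[j] == s[j - p]:
                    j += 1
                b = j  # stretch end (exclusive)
                units = (b - a) // p
                motif = s[a : a + p]
                if (
                    units >= thresholds[p]
                    and set(motif) <= UNAMBIGUOUS
                    and _primitive(motif)
                ):
                    candidates.append((a, p, a + p * units, motif, units))
            else:
                j += 1
    candidates.sort(key=lambda c: (c[0], c[1]))
    out: list[SSRRecord] = []
    last_end = -1
    for a, p, end, motif, units in candidates:
        if a >= last_end:
            out.append(
                SSRRecord(seq_id=seq.id, motif=motif, repeats=units, start=a, end=end)
            )
            last_end = end
    return out


def group_compound(
    ssrs: Sequence[SSRRecord], max_gap: int = DEFAULT_MAX_COMPOUND_GAP
) -> list[SSRRecord]:
    """Assign compound-group ids to SSRs of one sequence.

    Consecutive records (sorted by start) whose gap is <= max_gap share a
    group; grouping is the transitive closure of that relation. Singleton
    groups carry no id. Overlapping input records are a consistency error.
    """
    recs = sorted(ssrs, key=lambda r: r.start)
    seq_ids = {r.seq_id for r in recs}
    if len(seq_ids) > 1:
        raise ValueError("group_compound expects SSRs of a single sequence")
    for prev, nxt in itertools.pairwise(recs):
        if nxt.start < prev.end:
            raise ValueError(
                f"overlapping SSR spans on {prev.seq_id}: "
                f"[{prev.start},{prev.end}) and [{nxt.start},{nxt.end})"
            )
    out: list[SSRRecord] = []
    group: list[SSRRecord] = []
    n_groups = 0

    def flush():
        nonlocal n_groups
        if len(group) >= 2:
            n_groups += 1
            gid = f"{group[0].seq_id}:G{n_groups}"
            out.extend(replace(r, compound_group=gid) for r in group)
        else:
            out.extend(group)
        group.clear()

    for r in recs:
        if group and r.start - group[-1].end > max_gap:
            flush()
        group.append(r)
    flush()
    return out


def ssr_summary(records: Sequence[SSRRecord]) -> dict:
    """Totals by motif class, repeat-count statistics, and compound counts."""
    by_class: dict[int, list[SSRRecord]] = {p: [] for p in range(2, 7)}
    for r in records:
        by_class.setdefault(r.motif_len, []).append(r)
    classes = {}
    for p in sorted(by_class):
        recs = by_class[p]
        reps = [r.repeats for r in recs]
        classes[p] = {
            "count": len(recs),
            "mean_repeats": (sum(reps) / len(reps)) if reps else 0.0,
            "min_repeats": min(reps, default=0),
            "max_repeats": max(reps, default=0),
        }
    in_compound = [r for r in records if r.compound_group is not None]
    return {
        "classes": classes,
        "total": len(records),
        "n_sequences_with_ssr": len({r.seq_id for r in records}),
        "n_records_in_compound": len(in_compound),
        "n_compound_groups": len({r.compound_group for r in in_compound}),
    }
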