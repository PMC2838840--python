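"""Independent brute-force oracles used to validate the fast implementations.

Each oracle is written in the most naive way possible — exhaustive
enumeration, quadratic scans, exact integer arithmetic — and shares no code
with the implementation it checks.
"""

from __future__ import annotations

import math
from collections import Counter

UNAMBIG = set("ACGT")
STOPS = {"TAA", "TAG", "TGA"}


# ---------------------------------------------------------------------------
# SSR: enumerate every (position, period) pair, count complete units, keep
# maximal primitive runs over threshold, then apply the same deterministic
# left-to-right overlap resolution the scanner documents.

def ssr_oracle(seq: str, thresholds=None) -> list[tuple[int, int, str, int]]:
    """Returns (start, end, motif, units) tuples, non-overlapping."""
    if thresholds is None:
        thresholds = {2: 6, 3: 5, 4: 5, 5: 5, 6: 5}
    n = len(seq)
    cands = []
    for a in range(n):
        for p in sorted(thresholds):
            motif = seq[a : a + p]
            if len(motif) < p or not set(motif) <= UNAMBIG:
                continue
            # primitive?
            if any(p % d == 0 and motif == motif[:d] * (p // d) for d in range(1, p)):
                continue
            # count complete units at a
            k = 0
            while seq[a + k * p : a + (k + 1) * p] == motif:
                k += 1
            if k < thresholds[p]:
                continue
            # maximal: not extendable by one full unit on either side
            if a - p >= 0 and seq[a - p : a] == motif:
                continue
            if seq[a + k * p : a + (k + 1) * p] == motif:  # pragma: no cover
                continue
            cands.append((a, p, a + k * p, motif, k))
    cands.sort(key=lambda c: (c[0], c[1]))
    out = []
    last_end = -1
    for a, p, end, motif, k in cands:
        if a >= last_end:
            out.append((a, end, motif, k))
            last_end = end
    return out


# ---------------------------------------------------------------------------
# SNP: naive per-column counter over the raw row strings.

def snp_oracle(rows, min_depth=4, min_maf=0.1, min_occurrence=2):
    """Returns (column, major, minor, depth, minor_count) tuples."""
    if not rows:
        return []
    width = len(rows[0])
    out = []
    for col in range(width):
        chars = [r[col] for r in rows]
        if any(c == "-" for c in chars):
            continue
        counts = Counter(c for c in chars if c in UNAMBIG)
        depth = sum(counts.values())
        if depth < min_depth or len(counts) < 2:
            continue
        ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        major, minor = ranked[0][0], ranked[1][0]
        mc = ranked[1][1]
        if mc >= min_occurrence and mc / depth >= min_maf - 1e-9:
            out.append((col, major, minor, depth, mc))
    return out


# ---------------------------------------------------------------------------
# hit classification: O(n*m) scan over every CDS feature.

def classify_oracle(start, end, cds_list, utr_max=4375):
    """cds_list: (seqid-filtered) list of (start, end, feature_id).
    Returns (cls, gap_or_None, feature_id_or_None)."""
    if not cds_list:
        return "distal", None, None
    best_gap, best_id, contained = None, None, False
    for cs, ce, fid in cds_list:
        if cs <= start and end <= ce:
            contained = True
        gap = max(cs - end, start - ce, 0)
        if best_gap is None or gap < best_gap or (gap == best_gap and fid < best_id):
            best_gap, best_id = gap, fid
    if contained:
        return "inside", best_gap, best_id
    if best_gap == 0:
        return "spanning", best_gap, best_id
    if best_gap <= utr_max:
        return "utr_range", best_gap, best_id
    return "distal", best_gap, best_id


# ---------------------------------------------------------------------------
# ORFs: enumerate every ATG, walk to the next in-frame stop, keep the
# leftmost ATG per stop (and per frame-end for incomplete ORFs).

_COMP = str.maketrans("ACGT", "TGCA")


def _rc(s):
    return s.translate(_COMP)[::-1]


def orf_oracle(seq: str, min_len=100, both_strands=True):
    """Returns (start, end, strand, frame, length, incomplete) tuples on the
    forward strand, sorted."""
    L = len(seq)
    out = []
    strands = [("+", seq)] + ([("-", _rc(seq))] if both_strands else [])
    for strand, s in strands:
        atg_positions = [i for i in range(len(s) - 2) if s[i : i + 3] == "ATG"]
        by_terminus = {}
        for a in atg_positions:
            pos = a
            stop = None
            while pos + 3 <= len(s):
                if pos > a and s[pos : pos + 3] in STOPS:
                    stop = pos
                    break
                pos += 3
            if stop is not None:
                key = ("stop", a % 3, stop)
                end, incomplete = stop + 3, False
            else:
                last = a + ((len(s) - a) // 3) * 3
                key = ("end", a % 3)
                end, incomplete = last, True
            if key not in by_terminus or a < by_terminus[key][0]:
                by_terminus[key] = (a, end, incomplete)
        for (a, end, incomplete) in by_terminus.values():
            length = end - a
            if length < min_len:
                continue
            if strand == "+":
                f_start, f_end = a, end
            else:
                f_start, f_end = L - end, L - a
            out.append((f_start, f_end, strand, a % 3, length, incomplete))
    out.sort()
    return out


# ---------------------------------------------------------------------------
# Fisher exact: full enumeration with exact integer weights; tie comparison
# is exact (w <= w_obs on integers), the final division is the only float op.

def fisher_oracle(a, b, c, d) -> float:
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or (b + d) == 0:
        return 1.0
    w_obs = math.comb(r1, a) * math.comb(r2, c)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    total = sum(
        w
        for x in range(lo, hi + 1)
        if (w := math.comb(r1, x) * math.comb(r2, c1 - x)) <= w_obs
    )
    return total / math.comb(n, c1)


# ---------------------------------------------------------------------------
# best hit: per-query brute scan.

def best_hit_oracle(rows, cutoff):
    """rows: (qseqid, sseqid, evalue, bitscore). Returns {q: (s, e, b)}."""
    out = {}
    for q in {r[0] for r in rows}:
        passing = [r for r in rows if r[0] == q and r[2] <= cutoff]
        if not passing:
            continue
        winner = min(passing, key=lambda r: (r[2], -r[3], r[1]))
        out[q] = (winner[1], winner[2], winner[3])
    return out
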