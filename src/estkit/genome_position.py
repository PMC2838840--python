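"""Classify genome hits of unique sequences relative to annotated coding regions.

A hit is `inside` when its interval lies entirely within a CDS, `spanning`
when it crosses (or abuts) a CDS boundary, `utr_range` when the gap to the
nearest CDS is positive but within the maximum plausible UTR length, and
`distal` beyond that. The default UTR bound of 4,375 bases is the largest
annotated honeybee UTR; the boundary is inclusive (gap == utr_max is still
utr_range). Distances are strand-agnostic gaps in bases.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .formats import GenomeFeature, HitRecord

DEFAULT_UTR_MAX = 4375

CLASSES = ("inside", "spanning", "utr_range", "distal")


@dataclass(frozen=True)
class HitClassification:
    qseqid: str
    seqid: str
    start: int  # strand-normalised, 0-based half-open
    end: int
    cls: str
    distance_to_nearest_cds: Optional[int]  # None: no CDS on that seqid
    nearest_feature_id: Optional[str]


class _CdsIndex:
    """Per-seqid arrays of CDS intervals for vectorised gap queries."""

    def __init__(self, features: Iterable[GenomeFeature]):
        cds = [f for f in features if f.ftype == "CDS"]
        self._by_seqid: dict[str, tuple[np.ndarray, np.ndarray, list[str]]] = {}
        grouped: dict[str, list[GenomeFeature]] = {}
        for f in cds:
            grouped.setdefault(f.seqid, []).append(f)
        for seqid, feats in grouped.items():
            feats.sort(key=lambda f: (f.start, f.end, f.feature_id))
            starts = np.array([f.start for f in feats], dtype=np.int64)
            ends = np.array([f.end for f in feats], dtype=np.int64)
            ids = [f.feature_id for f in feats]
            self._by_seqid[seqid] = (starts, ends, ids)

    def nearest(self, seqid: str, start: int, end: int):
        """(gap, contained, feature_id) of the nearest CDS, or None if the
        seqid carries no CDS. gap is 0 for overlap or abutment; ties on gap
        are broken by smallest feature_id."""
        entry = self._by_seqid.get(seqid)
        if entry is None:
            return None
        starts, ends, ids = entry
        gaps = np.maximum(0, np.maximum(starts - end, start - ends))
        best_gap = int(gaps.min())
        tie_idx = np.flatnonzero(gaps == best_gap)
        best_id = min(ids[i] for i in tie_idx)
        contained = bool(np.any((starts <= start) & (end <= ends)))
        return best_gap, contained, best_id


def classify_hit(
    qseqid: str,
    seqid: str,
    start: int,
    end: int,
    features: Iterable[GenomeFeature] | _CdsIndex,
    utr_max: int = DEFAULT_UTR_MAX,
) -> HitClassification:
    """Classify one strand-normalised hit interval against the CDS set."""
    index = features if isinstance(features, _CdsIndex) else _CdsIndex(features)
    near = index.nearest(seqid, start, end)
    if near is None:
        return HitClassification(
            qseqid=qseqid, seqid=seqid, start=start, end=end, cls="distal",
            distance_to_nearest_cds=None, nearest_feature_id=None,
        )
    gap, contained, fid = near
    if contained:
        cls = "inside"
    elif gap == 0:
        cls = "spanning"
    elif gap <= utr_max:
        cls = "utr_range"
    else:
        cls = "distal"
    return HitClassification(
        qseqid=qseqid, seqid=seqid, start=start, end=end, cls=cls,
        distance_to_nearest_cds=gap, nearest_feature_id=fid,
    )


def classify_all(
    best_genome_hits: Sequence[HitRecord],
    features: Iterable[GenomeFeature],
    utr_max: int = DEFAULT_UTR_MAX,
    start_only: bool = False,
) -> tuple[list[HitClassification], dict[str, int]]:
    """Classify one best hit per query; returns classifications plus per-class
    counts (which always sum to the number of hits).

    With `start_only`, only the 5'-most subject coordinate of each alignment
    (a 1-base interval) is classified, reproducing a start-position-based
    variant of the rule.
    """
    seen: set[str] = set()
    index = _CdsIndex(features)
    out: list[HitClassification] = []
    for h in best_genome_hits:
        if h.qseqid in seen:
            raise ValueError(f"multiple hits for query {h.qseqid}; best-hit first")
        seen.add(h.qseqid)
        start, end = h.subject_interval
        if start_only:
            pos = h.sstart - 1  # alignment start as printed, 0-based
            start, end = pos, pos + 1
        out.append(classify_hit(h.qseqid, h.sseqid, start, end, index, utr_max))
    summary = {cls: 0 for cls in CLASSES}
    for c in out:
        summary[c.cls] += 1
    return out, summary


def seqid_distribution(
    classifications: Sequence[HitClassification],
    features: Iterable[GenomeFeature],
) -> pd.DataFrame:
    """Percent of hits and percent of CDS features per genomic sequence.

    Each column sums to 100 (up to rounding); seqids seen in either input
    appear as rows.
    """
    hit_counts = Counter(c.seqid for c in classifications)
    cds_counts = Counter(f.seqid for f in features if f.ftype == "CDS")
    seqids = sorted(set(hit_counts) | set(cds_counts))
    n_hits = sum(hit_counts.values())
    n_cds = sum(cds_counts.values())
    rows = []
    for s in seqids:
        rows.append(
            {
                "seqid": s,
                "n_hits": hit_counts.get(s, 0),
                "pct_hits": hit_counts.get(s, 0) / n_hits * 100 if n_hits else 0.0,
                "n_cds": cds_counts.get(s, 0),
                "pct_cds": cds_counts.get(s, 0) / n_cds * 100 if n_cds else 0.0,
            }
        )
    return pd.DataFrame(rows, columns=["seqid", "n_hits", "pct_hits", "n_cds", "pct_cds"])
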