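"""Candidate-SNP mining from per-contig multiple alignments.

A column of a contig alignment is called a candidate SNP when, among its
unambiguous bases, the second-most-frequent allele reaches both a minimum
count (occurrence) and a minimum frequency (MAF), at a minimum column depth.
Columns containing alignment gaps are skipped entirely; N counts neither as
an allele nor toward depth.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .formats import ClusterTable, MsaBlock, UNAMBIGUOUS

DEFAULT_MIN_DEPTH = 4
DEFAULT_MIN_MAF = 0.1
DEFAULT_MIN_OCCURRENCE = 2

_EPS = 1e-9  # tolerance for the MAF >= threshold comparison in floats


@dataclass(frozen=True)
class SNPRecord:
    contig_id: str
    column: int  # 0-based alignment column
    major_allele: str
    minor_allele: str
    depth: int
    minor_count: int
    multiallelic: bool = False

    @property
    def maf(self) -> float:
        return self.minor_count / self.depth


def call_snps(
    msa: MsaBlock,
    min_depth: int = DEFAULT_MIN_DEPTH,
    min_maf: float = DEFAULT_MIN_MAF,
    min_occurrence: int = DEFAULT_MIN_OCCURRENCE,
    quality_mask: Optional[Sequence[bool]] = None,
) -> list[SNPRecord]:
    """Call candidate SNP columns in one contig alignment.

    `quality_mask`, if given, marks alignment columns eligible for calling
    (True = usable); it is a hook for per-base quality screens and defaults
    to all-usable. Allele ties are broken alphabetically so output is
    deterministic under row permutation.
    """
    if quality_mask is not None and len(quality_mask) != msa.width:
        raise ValueError("quality mask length != alignment width")
    out: list[SNPRecord] = []
    for col in range(msa.width):
        if quality_mask is not None and not quality_mask[col]:
            continue
        chars = msa.column(col)
        if "-" in chars:
            continue  # gapped columns are unreliable; skip entirely
        counts = Counter(c for c in chars if c in UNAMBIGUOUS)
        depth = sum(counts.values())
        if depth < min_depth or len(counts) < 2:
            continue
        # order alleles by count desc, then alphabetically
        ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        major, _ = ranked[0]
        minor, minor_count = ranked[1]
        if minor_count < min_occurrence:
            continue
        if minor_count / depth < min_maf - _EPS:
            continue
        qualifying_minors = [
            al for al, ct in ranked[1:]
            if ct >= min_occurrence and ct / depth >= min_maf - _EPS
        ]
        out.append(
            SNPRecord(
                contig_id=msa.contig_id, column=col, major_allele=major,
                minor_allele=minor, depth=depth, minor_count=minor_count,
                multiallelic=len(qualifying_minors) >= 2,
            )
        )
    return out


def consensus_length(msa: MsaBlock) -> int:
    """Ungapped consensus length: alignment columns holding >= 1 base."""
    return sum(
        1 for col in range(msa.width)
        if any(c in UNAMBIGUOUS or c == "N" for c in msa.column(col))
    )


def eligible_contigs(
    clusters: ClusterTable,
    msas: Iterable[MsaBlock],
    min_depth: int = DEFAULT_MIN_DEPTH,
) -> dict:
    """Contigs deep enough for SNP calling, the consensus bases they cover,
    and contigs whose alignment is missing."""
    by_id = {b.contig_id: b for b in msas}
    eligible: list[str] = []
    missing: list[str] = []
    coverage = 0
    for cid, members in clusters.contig_members.items():
        if len(members) < min_depth:
            continue
        block = by_id.get(cid)
        if block is None:
            missing.append(cid)
            continue
        eligible.append(cid)
        coverage += consensus_length(block)
    return {
        "eligible": sorted(eligible),
        "missing": sorted(missing),
        "coverage_bases": coverage,
    }


def snp_summary(records: Sequence[SNPRecord]) -> dict:
    return {
        "n_snps": len(records),
        "n_contigs_with_snp": len({r.contig_id for r in records}),
    }
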