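"""Assembly composition and base-composition statistics of a unique-sequence set.

The unit of analysis is the "unique sequence": a contig consensus built from
>= 2 clustered ESTs, or a singleton EST that joined no cluster.
"""

from __future__ import annotations

from dataclasses import dataclass

from .formats import ClusterTable, SeqRecord, UNAMBIGUOUS


@dataclass(frozen=True)
class AssemblySummary:
    n_ests: int
    n_contigs: int
    n_singletons: int
    n_unique: int
    mean_per_contig: float
    max_per_contig: int
    contig_len_mean: float
    contig_len_max: int


def assembly_summary(
    clusters: ClusterTable, unique_seqs: list[SeqRecord]
) -> AssemblySummary:
    """Summarise an assembly: EST/contig/singleton counts, members per contig,
    contig length statistics.

    Every contig id in `clusters` must have a consensus sequence among
    `unique_seqs`; singletons may or may not (a bare cluster table with an
    id-only singleton list is still summarisable for counts).
    """
    by_id = {rec.id: rec for rec in unique_seqs}
    missing = [cid for cid in clusters.contig_members if cid not in by_id]
    if missing:
        raise ValueError(
            f"contigs without consensus sequence: {', '.join(sorted(missing)[:5])}"
            + ("..." if len(missing) > 5 else "")
        )

    n_contigs = clusters.n_contigs
    n_singletons = clusters.n_singletons
    member_counts = [len(v) for v in clusters.contig_members.values()]
    n_ests = n_singletons + sum(member_counts)
    mean_per_contig = (n_ests - n_singletons) / n_contigs if n_contigs else 0.0
    contig_lens = [len(by_id[cid]) for cid in clusters.contig_members]
    return AssemblySummary(
        n_ests=n_ests,
        n_contigs=n_contigs,
        n_singletons=n_singletons,
        n_unique=n_contigs + n_singletons,
        mean_per_contig=mean_per_contig,
        max_per_contig=max(member_counts, default=0),
        contig_len_mean=(sum(contig_lens) / len(contig_lens)) if contig_lens else 0.0,
        contig_len_max=max(contig_lens, default=0),
    )


def gc_content(seqs: list[SeqRecord]) -> float:
    """Pooled GC fraction over all sequences, ambiguous bases excluded.

    Computed as (#G + #C) / (#A + #C + #G + #T) with every sequence
    amalgamated into one pool; this is NOT the mean of per-sequence fractions.
    """
    gc = 0
    total = 0
    for rec in seqs:
        for ch in rec.sequence:
            if ch in UNAMBIGUOUS:
                total += 1
                if ch in ("G", "C"):
                    gc += 1
    if total == 0:
        raise ValueError("no unambiguous bases in input; GC content undefined")
    return gc / total


def length_stats(seqs: list[SeqRecord]) -> dict:
    """Arithmetic mean and maximum of sequence lengths."""
    if not seqs:
        raise ValueError("length_stats on empty input")
    lengths = [len(rec) for rec in seqs]
    return {"mean": sum(lengths) / len(lengths), "max": max(lengths), "n": len(lengths)}
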