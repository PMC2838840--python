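"""Best-hit selection, taxonomic tallies, cross-proteome presence screening and
redundancy-based unique-gene estimation.

A "best hit" is the single most significant match of a query that passes the
e-value cutoff; ties on e-value are broken by higher bitscore, then by
lexicographically smallest subject id, so output is deterministic across runs
and platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from .formats import HitRecord


@dataclass(frozen=True)
class BestHit:
    qseqid: str
    sseqid: str
    evalue: float
    bitscore: float
    source_db: str = ""


@dataclass
class TaxonTally:
    """Ordered category -> count map over best hits, plus the no-hit count.

    Category counts and `no_hits` always sum to the number of queries."""

    counts: dict[str, int]
    no_hits: int
    n_queries: int

    def subtotal(self, labels: Sequence[str]) -> int:
        """Sum of the counts of the given categories (e.g. every Hymenoptera
        category of a taxonomic tally)."""
        return sum(self.counts[lab] for lab in labels)

    @property
    def n_with_hits(self) -> int:
        return sum(self.counts.values())


@dataclass
class CrossProteomeMatrix:
    """Query x reference-proteome presence flags (True iff >= 1 hit passed
    the cutoff in that proteome's hit table)."""

    presence: pd.DataFrame  # bool, index=qseqid sorted, columns=db names

    @property
    def dbs(self) -> list[str]:
        return list(self.presence.columns)

    def db_counts(self) -> dict[str, int]:
        return {db: int(self.presence[db].sum()) for db in self.dbs}

    def candidates(self, missing_db: str) -> list[str]:
        """Queries present in every proteome except `missing_db` — candidates
        for gene loss / pseudogenization / missed annotation in that genome."""
        if missing_db not in self.presence.columns:
            raise KeyError(f"unknown proteome {missing_db!r}")
        others = [db for db in self.dbs if db != missing_db]
        mask = self.presence[others].all(axis=1) & ~self.presence[missing_db]
        return sorted(self.presence.index[mask])


def best_hits(
    hits: Iterable[HitRecord], cutoff: float, source_db: str = ""
) -> list[BestHit]:
    """Per query passing the e-value cutoff, the single hit with minimal
    e-value (ties: maximal bitscore, then smallest sseqid). Sorted by query."""
    best: dict[str, HitRecord] = {}
    for h in hits:
        if h.evalue > cutoff:
            continue
        cur = best.get(h.qseqid)
        if cur is None or (h.evalue, -h.bitscore, h.sseqid) < (
            cur.evalue, -cur.bitscore, cur.sseqid
        ):
            best[h.qseqid] = h
    return [
        BestHit(
            qseqid=q, sseqid=h.sseqid, evalue=h.evalue,
            bitscore=h.bitscore, source_db=source_db,
        )
        for q, h in sorted(best.items())
    ]


def taxon_tally(
    best: Sequence[BestHit],
    taxmap: dict[str, str],
    categories: Sequence[tuple[str, object]],
    n_queries: int,
) -> TaxonTally:
    """Assign each best hit to the FIRST matching category rule and tally.

    `categories` is an ordered list of (label, taxa) pairs, where taxa is a
    collection of taxon labels or the wildcard "*" (catch-all). Rules are
    ordered because taxonomic categories typically nest (a genus-level rule
    must precede the family-level rule that contains it).
    """
    unmapped = sorted({b.sseqid for b in best if b.sseqid not in taxmap})
    if unmapped:
        raise ValueError(
            "subjects missing from taxon map: " + ", ".join(unmapped[:10])
            + ("..." if len(unmapped) > 10 else "")
        )
    counts = {label: 0 for label, _ in categories}
    for b in best:
        taxon = taxmap[b.sseqid]
        for label, taxa in categories:
            if taxa == "*" or taxon in taxa:
                counts[label] += 1
                break
        else:
            raise ValueError(
                f"taxon {taxon!r} (subject {b.sseqid}) matches no category rule"
            )
    no_hits = n_queries - len(best)
    if no_hits < 0:
        raise ValueError("more best hits than queries")
    return TaxonTally(counts=counts, no_hits=no_hits, n_queries=n_queries)


def cross_proteome(
    hitfiles: dict[str, Iterable[HitRecord]], cutoff: float
) -> CrossProteomeMatrix:
    """Presence/absence of each query across >= 2 reference proteomes."""
    if len(hitfiles) < 2:
        raise ValueError("cross_proteome needs at least 2 proteomes")
    present: dict[str, set[str]] = {}
    for db, hits in hitfiles.items():
        present[db] = {h.qseqid for h in hits if h.evalue <= cutoff}
    queries = sorted(set().union(*present.values())) if present else []
    data = {db: [q in qs for q in queries] for db, qs in present.items()}
    df = pd.DataFrame(data, index=queries, columns=list(hitfiles))
    return CrossProteomeMatrix(presence=df)


def redundancy_estimate(best: Sequence[BestHit], n_unique_seqs: int) -> dict:
    """Unique-gene estimate from best-hit redundancy against one proteome.

    ratio = unique subjects / hit-bearing queries; est_genes = the ratio
    applied to the whole unique-sequence set. The percent is reported as a
    whole number, round-half-even.
    """
    if not best:
        raise ValueError("redundancy_estimate on empty best-hit list")
    n_hits = len({b.qseqid for b in best})
    n_subj = len({b.sseqid for b in best})
    ratio = n_subj / n_hits
    return {
        "n_hits": n_hits,
        "n_unique_subjects": n_subj,
        "ratio": ratio,
        "percent": round(ratio * 100),
        "est_genes": round(ratio * n_unique_seqs),
    }
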