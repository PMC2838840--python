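"""GO-slim profiling and pairwise organism comparison by Fisher's exact test.

Electronically inferred annotations (evidence code IEA by default) are removed
before tallying; a sequence reaching the same slim term through two different
GO ids counts once per distinct (sequence, slim term) pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from scipy.stats import fisher_exact as _scipy_fisher

from .formats import GoAnnotation, NAMESPACES

DEFAULT_EXCLUDED_EVIDENCE = frozenset({"IEA"})


@dataclass
class SlimTally:
    """Per-namespace counts of (sequence, slim term) assignments, with the
    percent each term contributes to the namespace total."""

    namespace: str
    counts: dict[str, int]
    n_unmapped: int = 0

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def percents(self) -> dict[str, float]:
        t = self.total
        return {term: (c / t * 100 if t else 0.0) for term, c in self.counts.items()}


@dataclass(frozen=True)
class SlimComparison:
    slim_term: str
    a_count: int
    a_total: int
    b_count: int
    b_total: int
    p_value: float
    flagged_raw: bool
    flagged: bool  # after multiplicity correction


def filter_annotations(
    annots: Iterable[GoAnnotation],
    excluded_codes: frozenset = DEFAULT_EXCLUDED_EVIDENCE,
) -> list[GoAnnotation]:
    """Drop annotations with an excluded evidence code (default: IEA, the
    electronically-inferred code)."""
    return [a for a in annots if a.evidence_code not in excluded_codes]


def slim_tally(
    annots: Iterable[GoAnnotation],
    slim_map: dict[str, tuple[str, str]],
) -> list[SlimTally]:
    """Map annotations to GO-slim terms and tally per namespace.

    One sequence may contribute to several slim terms, but a given
    (sequence, slim term) pair is counted once. GO ids absent from the slim
    map are counted per namespace and reported, not fatal. Returns one tally
    per namespace, in canonical namespace order.
    """
    pairs: dict[str, set[tuple[str, str]]] = {ns: set() for ns in NAMESPACES}
    unmapped: dict[str, int] = {ns: 0 for ns in NAMESPACES}
    for a in annots:
        entry = slim_map.get(a.go_id)
        if entry is None:
            unmapped[a.namespace] += 1
            continue
        slim, ns = entry
        pairs[ns].add((a.seq_id, slim))
    tallies = []
    for ns in NAMESPACES:
        counts: dict[str, int] = {}
        for _seq, slim in sorted(pairs[ns]):
            counts[slim] = counts.get(slim, 0) + 1
        tallies.append(
            SlimTally(namespace=ns, counts=dict(sorted(counts.items())),
                      n_unmapped=unmapped[ns])
        )
    return tallies


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]]:
    the sum of hypergeometric probabilities of all tables with the observed
    margins whose probability does not exceed that of the observed table.

    A zero margin makes the table degenerate; p = 1.0 by convention, with a
    warning.
    """
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise ValueError("table entries must be non-negative integers")
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        warnings.warn("degenerate 2x2 table (zero margin); p = 1.0 by convention")
        return 1.0
    p = float(_scipy_fisher([[a, b], [c, d]], alternative="two-sided")[1])
    return min(1.0, max(0.0, p))


def compare_distributions(
    tally_a: SlimTally,
    tally_b: SlimTally,
    alpha: float = 0.05,
    correction: str = "bonferroni",
) -> list[SlimComparison]:
    """One Fisher test per slim term of a shared vocabulary.

    For each term, the table is [[count_in_a, rest_of_a], [count_in_b,
    rest_of_b]]. `flagged_raw` marks p < alpha; `flagged` applies the chosen
    multiplicity correction within the namespace (Bonferroni by default).
    """
    if tally_a.namespace != tally_b.namespace:
        raise ValueError(
            f"namespace mismatch: {tally_a.namespace} vs {tally_b.namespace}"
        )
    if set(tally_a.counts) != set(tally_b.counts):
        raise ValueError("slim vocabularies differ between the two tallies")
    if correction not in ("bonferroni", "none"):
        raise ValueError(f"unknown correction {correction!r}")
    m = len(tally_a.counts)
    thresh = alpha / m if (correction == "bonferroni" and m) else alpha
    out = []
    ta, tb = tally_a.total, tally_b.total
    for term in tally_a.counts:
        ca, cb = tally_a.counts[term], tally_b.counts[term]
        p = fisher_exact_2x2(ca, ta - ca, cb, tb - cb)
        out.append(
            SlimComparison(
                slim_term=term, a_count=ca, a_total=ta, b_count=cb, b_total=tb,
                p_value=p, flagged_raw=p < alpha, flagged=p < thresh,
            )
        )
    return out
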