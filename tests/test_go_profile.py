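"""Evidence filtering, slim tallies and Fisher exact comparison."""

import math

import numpy as np
import pytest

from estkit.formats import GoAnnotation, read_go, read_slim_map
from estkit.go_profile import (
    SlimTally,
    compare_distributions,
    filter_annotations,
    fisher_exact_2x2,
    slim_tally,
)

from .oracles import fisher_oracle


def _ann(seq, go, ev="IDA", ns="molecular_function"):
    return GoAnnotation(seq, go, ev, ns)


class TestFilter:
    def test_iea_removed_by_default(self):
        annots = [_ann("g1", "GO:0005524", "IDA"), _ann("g2", "GO:0005524", "IEA")]
        assert [a.seq_id for a in filter_annotations(annots)] == ["g1"]

    def test_empty_exclusion_is_identity(self):
        annots = [_ann("g1", "GO:0005524", "IEA")]
        assert filter_annotations(annots, frozenset()) == annots

    def test_all_iea_gives_empty(self):
        assert filter_annotations([_ann("g", "GO:0005524", "IEA")] * 3) == []


class TestSlimTally:
    SLIM = {
        "GO:0005524": ("binding", "molecular_function"),
        "GO:0003677": ("binding", "molecular_function"),
        "GO:0016301": ("catalytic activity", "molecular_function"),
    }

    def test_single_annotation_is_100_percent(self):
        (mf, _bp, _cc) = slim_tally([_ann("g1", "GO:0005524")], self.SLIM)
        assert mf.counts == {"binding": 1}
        assert mf.percents["binding"] == 100.0

    def test_same_slim_via_two_go_ids_counts_once(self):
        annots = [_ann("g1", "GO:0005524"), _ann("g1", "GO:0003677")]
        (mf, _, _) = slim_tally(annots, self.SLIM)
        assert mf.counts == {"binding": 1}

    def test_unmapped_counted_not_fatal(self):
        annots = [_ann("g1", "GO:0005524"), _ann("g1", "GO:0099999")]
        (mf, _, _) = slim_tally(annots, self.SLIM)
        assert mf.n_unmapped == 1 and mf.total == 1

    def test_percents_sum_to_100(self):
        rng = np.random.default_rng(3)
        ids = list(self.SLIM)
        annots = [
            _ann(f"g{rng.integers(40)}", ids[int(rng.integers(len(ids)))])
            for _ in range(200)
        ]
        (mf, _, _) = slim_tally(annots, self.SLIM)
        assert sum(mf.percents.values()) == pytest.approx(100.0, abs=0.1)

    def test_removing_nothing_changes_nothing(self):
        annots = [_ann("g1", "GO:0005524"), _ann("g2", "GO:0016301")]
        assert slim_tally(filter_annotations(annots), self.SLIM) == slim_tally(
            annots, self.SLIM
        )

    def test_simulator_bookkeeping(self, sim_fixture):
        gt, d = sim_fixture
        annots = filter_annotations(read_go(d / "go_annotations.tsv"))
        tallies = slim_tally(annots, read_slim_map(d / "go_slim_map.tsv"))
        got = {t.namespace: t.counts for t in tallies if t.counts}
        assert got == gt.expected_go


class TestFisher:
    def test_identical_proportions_give_one(self):
        assert fisher_exact_2x2(10, 90, 10, 90) == 1.0

    def test_perfect_separation(self):
        # only the two extreme tables have probability <= observed
        assert fisher_exact_2x2(10, 0, 0, 10) == pytest.approx(
            2 / math.comb(20, 10), abs=1e-15
        )

    def test_zero_margin_convention(self):
        with pytest.warns(UserWarning, match="zero margin"):
            assert fisher_exact_2x2(0, 0, 3, 4) == 1.0

    def test_symmetry_row_and_column_swap(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            a, b, c, d = (int(x) for x in rng.integers(0, 25, size=4))
            if (a + b) * (c + d) * (a + c) * (b + d) == 0:
                continue
            p = fisher_exact_2x2(a, b, c, d)
            assert fisher_exact_2x2(c, d, a, b) == pytest.approx(p, abs=1e-12)
            assert fisher_exact_2x2(b, a, d, c) == pytest.approx(p, abs=1e-12)

    def test_matches_enumeration_oracle_sampled(self):
        rng = np.random.default_rng(5)
        for _ in range(300):
            n = int(rng.integers(4, 31))
            cuts = sorted(rng.integers(0, n + 1, size=3))
            a, b, c = cuts[0], cuts[1] - cuts[0], cuts[2] - cuts[1]
            d = n - a - b - c
            if (a + b) * (c + d) * (a + c) * (b + d) == 0:
                continue
            assert fisher_exact_2x2(a, b, c, d) == pytest.approx(
                fisher_oracle(a, b, c, d), abs=1e-12
            )

    def test_super_uniform_under_null(self):
        # fixed-margin null: p-values should be (conservatively) super-uniform
        rng = np.random.default_rng(19)
        n1, n2, k = 40, 40, 30
        pvals = []
        for _ in range(400):
            a = rng.hypergeometric(n1, n2, k)
            pvals.append(fisher_exact_2x2(a, n1 - a, k - a, n2 - (k - a)))
        pvals = np.asarray(pvals)
        for alpha in (0.05, 0.1, 0.25, 0.5):
            assert (pvals <= alpha).mean() <= alpha + 0.06


class TestCompare:
    def _tally(self, ns, counts):
        return SlimTally(namespace=ns, counts=counts)

    def test_identical_counts_not_flagged(self):
        t = self._tally("molecular_function", {"binding": 10, "catalytic": 20})
        for comp in compare_distributions(t, t):
            assert comp.p_value == 1.0 and not comp.flagged

    def test_extreme_imbalance_flagged(self):
        a = self._tally("molecular_function", {"x": 0, "y": 1000})
        b = self._tally("molecular_function", {"x": 500, "y": 500})
        by_term = {c.slim_term: c for c in compare_distributions(a, b)}
        assert by_term["x"].flagged and by_term["x"].flagged_raw

    def test_vocabulary_mismatch(self):
        a = self._tally("molecular_function", {"x": 1, "y": 2})
        b = self._tally("molecular_function", {"x": 1, "z": 2})
        with pytest.raises(ValueError, match="vocabularies"):
            compare_distributions(a, b)

    def test_planted_enrichment_recovered(self):
        # one term truly enriched; it alone should be flagged in >=95% of runs
        rng = np.random.default_rng(23)
        terms = ["t1", "t2", "t3", "t4"]
        base = np.array([0.25, 0.25, 0.25, 0.25])
        shifted = np.array([0.55, 0.15, 0.15, 0.15])  # t1 planted
        hits = 0
        reps = 200
        for _ in range(reps):
            ca = rng.multinomial(800, base)
            cb = rng.multinomial(800, shifted)
            ta = self._tally("biological_process", dict(zip(terms, map(int, ca))))
            tb = self._tally("biological_process", dict(zip(terms, map(int, cb))))
            comps = {c.slim_term: c for c in compare_distributions(ta, tb)}
            if comps["t1"].flagged:
                hits += 1
        assert hits / reps >= 0.95
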