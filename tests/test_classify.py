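"""ROC/AUC, odds-ratio enrichment, Venn counting, consensus peaks, level groups."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from markbins.classify import (
    bin_presence,
    combine_marks,
    consensus_peaks,
    group_by_level,
    merge_intervals,
    overlap_enrichment,
    roc_auc,
    venn_partition,
)


def mannwhitney_auc(scores, labels):
    """Tie-corrected pair-counting oracle: concordant + half ties over all pairs."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestROC:
    def test_perfect_separation(self):
        result = roc_auc(np.array([3.0, 2.0, 1.0, 0.5]), np.array([1, 1, 0, 0], bool))
        assert result.auc == 1.0
        assert result.tpr[0] == 0.0 and result.tpr[-1] == 1.0
        assert result.fpr[0] == 0.0 and result.fpr[-1] == 1.0

    def test_all_tied_scores_give_diagonal(self):
        result = roc_auc(np.full(10, 2.0), np.array([1, 0] * 5, bool))
        assert result.auc == pytest.approx(0.5)
        # origin plus a single interior/terminal point for the one tie block
        assert len(result.fpr) == 2

    def test_worked_example_three_of_four_pairs(self):
        scores = np.array([0.9, 0.8, 0.7, 0.6])
        labels = np.array([1, 0, 1, 0], bool)
        result = roc_auc(scores, labels)
        assert result.auc == pytest.approx(0.75)
        assert result.auc == pytest.approx(mannwhitney_auc(scores, labels))

    def test_rejects_single_class(self):
        with pytest.raises(ValueError):
            roc_auc(np.array([1.0, 2.0]), np.array([1, 1], bool))
        with pytest.raises(ValueError):
            roc_auc(np.array([1.0, 2.0]), np.array([0, 0], bool))

    @given(data=st.data())
    @settings(max_examples=250, deadline=None)
    def test_auc_equals_mannwhitney_statistic(self, data):
        n = data.draw(st.integers(2, 30))
        # coarse grid of score values forces plenty of ties
        scores = np.array(data.draw(
            st.lists(st.sampled_from([0.0, 0.25, 0.5, 0.75, 1.0]), min_size=n, max_size=n)
        ))
        labels = np.array(data.draw(
            st.lists(st.booleans(), min_size=n, max_size=n)
        ))
        if labels.all() or not labels.any():
            labels[0] = ~labels[0]
        result = roc_auc(scores, labels)
        assert result.auc == pytest.approx(mannwhitney_auc(scores, labels), abs=1e-12)
        # scipy cross-check via the U statistic
        u = stats.mannwhitneyu(scores[labels], scores[~labels]).statistic
        assert result.auc == pytest.approx(u / (labels.sum() * (~labels).sum()), abs=1e-9)

    @given(data=st.data())
    @settings(max_examples=100, deadline=None)
    def test_symmetry_and_monotone_invariance(self, data):
        n = data.draw(st.integers(2, 25))
        scores = np.array(data.draw(
            st.lists(st.integers(0, 6), min_size=n, max_size=n)
        ), dtype=float)
        labels = np.array(data.draw(st.lists(st.booleans(), min_size=n, max_size=n)))
        if labels.all() or not labels.any():
            labels[0] = ~labels[0]
        auc = roc_auc(scores, labels).auc
        assert auc + roc_auc(-scores, labels).auc == pytest.approx(1.0)
        assert roc_auc(np.exp(scores), labels).auc == pytest.approx(auc)
        tpr = roc_auc(scores, labels).tpr
        fpr = roc_auc(scores, labels).fpr
        assert np.all(np.diff(tpr) >= 0) and np.all(np.diff(fpr) >= 0)

    def test_combine_marks_mean(self):
        a = np.array([2.0, 2.0])
        b = np.array([0.0, 2.0])
        assert combine_marks(a, b).tolist() == [1.0, 2.0]
        with pytest.raises(ValueError):
            combine_marks(a, np.zeros(3))


def fisher_oracle(a, b, c, d):
    """Exhaustive two-sided Fisher probability over all tables with the margins."""
    row1, row2 = a + b, c + d
    col1 = a + c
    n = row1 + row2

    def p_table(x):
        return (
            math.comb(row1, x)
            * math.comb(row2, col1 - x)
            / math.comb(n, col1)
        )

    lo = max(0, col1 - row2)
    hi = min(col1, row1)
    p_obs = p_table(a)
    return sum(p_table(x) for x in range(lo, hi + 1) if p_table(x) <= p_obs * (1 + 1e-12))


class TestOverlapEnrichment:
    def test_worked_table_or_36(self):
        a_vec = np.repeat([True, True, False, False], [30, 10, 5, 60])
        b_vec = np.repeat([True, False, True, False], [30, 10, 5, 60])
        table = overlap_enrichment(a_vec, b_vec)
        assert (table.a, table.b, table.c, table.d) == (30, 10, 5, 60)
        assert table.odds_ratio == pytest.approx(36.0)
        assert table.p_value == pytest.approx(fisher_oracle(30, 10, 5, 60), abs=1e-12)

    @given(data=st.data())
    @settings(max_examples=150, deadline=None)
    def test_fisher_p_matches_exhaustive_oracle(self, data):
        a = data.draw(st.integers(0, 30))
        b = data.draw(st.integers(0, 30))
        c = data.draw(st.integers(0, 30))
        d = data.draw(st.integers(0, 30))
        if a + b + c + d == 0:
            a = 1
        vec_a = np.repeat([True, True, False, False], [a, b, c, d])
        vec_b = np.repeat([True, False, True, False], [a, b, c, d])
        table = overlap_enrichment(vec_a, vec_b)
        assert table.p_value == pytest.approx(fisher_oracle(a, b, c, d), abs=1e-12)

    def test_haldane_correction_on_zero_cell(self):
        vec_a = np.repeat([True, True, False, False], [5, 0, 3, 10])
        vec_b = np.repeat([True, False, True, False], [5, 0, 3, 10])
        table = overlap_enrichment(vec_a, vec_b)
        assert table.odds_ratio == pytest.approx((5.5 * 10.5) / (0.5 * 3.5))

    def test_independent_vectors_are_null(self):
        rng = np.random.default_rng(123)
        a_vec = rng.random(10_000) < 0.3
        b_vec = rng.random(10_000) < 0.4
        table = overlap_enrichment(a_vec, b_vec)
        assert 0.8 <= table.odds_ratio <= 1.25
        assert table.p_value > 0.01

    def test_stratified_tables_cover_universe(self):
        rng = np.random.default_rng(7)
        binding = rng.random(500) < 0.3
        strata = rng.choice(["both", "K9only", "K27only", "neither"], size=500)
        tables = overlap_enrichment(binding, binding, strata=strata)
        assert set(tables) == set(np.unique(strata))
        for label, t in tables.items():
            assert t.n == 500
            assert t.a + t.c == (strata == label).sum()

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            overlap_enrichment(np.array([], bool), np.array([], bool))


class TestConsensusPeaks:
    def peaks(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end"])

    def test_identical_peaks_two_of_two(self):
        reps = [self.peaks([("chr1", 100, 200)]), self.peaks([("chr1", 100, 200)])]
        out = consensus_peaks(reps, min_support=2)
        assert len(out) == 1 and out.loc[0, "support"] == 2

    def test_singleton_dropped_with_three_replicates(self):
        reps = [
            self.peaks([("chr1", 100, 200)]),
            self.peaks([]),
            self.peaks([]),
        ]
        out = consensus_peaks(reps, min_support=2)
        assert len(out) == 0

    def test_chained_overlap_merges_with_support_three(self):
        reps = [
            self.peaks([("chr1", 100, 200)]),
            self.peaks([("chr1", 150, 300)]),
            self.peaks([("chr1", 250, 400)]),
        ]
        out = consensus_peaks(reps, min_support=2)
        assert len(out) == 1
        assert (out.loc[0, "start"], out.loc[0, "end"]) == (100, 400)
        assert out.loc[0, "support"] == 3

    def test_single_replicate_keeps_everything(self):
        reps = [self.peaks([("chr1", 0, 10), ("chr1", 50, 60)])]
        out = consensus_peaks(reps, min_support=2)
        assert len(out) == 2

    def test_idempotent(self):
        reps = [
            self.peaks([("chr1", 100, 200), ("chr2", 0, 50)]),
            self.peaks([("chr1", 150, 260)]),
        ]
        once = consensus_peaks(reps, min_support=2)
        twice = consensus_peaks([once[["chrom", "start", "end"]]], min_support=2)
        assert once[["chrom", "start", "end"]].equals(twice[["chrom", "start", "end"]])

    def test_touching_intervals_not_merged(self):
        merged = merge_intervals(self.peaks([("chr1", 0, 100), ("chr1", 100, 200)]))
        assert len(merged) == 2


class TestBinPresence:
    def test_overlap_and_boundary_semantics(self, toy_bins):
        peaks = pd.DataFrame({"chrom": ["chr1"], "start": [500], "end": [600]})
        assert bin_presence(toy_bins, peaks).tolist() == [True, False]
        # peak ending exactly at bin start: half-open, no overlap
        peaks = pd.DataFrame({"chrom": ["chr1"], "start": [900], "end": [1000]})
        assert bin_presence(toy_bins, peaks).tolist() == [True, False]

    def test_empty_peaks(self, toy_bins):
        assert not bin_presence(toy_bins, pd.DataFrame(columns=["chrom", "start", "end"])).any()


class TestVennPartition:
    def test_disjoint_and_subset(self):
        a = np.array([1, 1, 0, 0], bool)
        b = np.array([0, 0, 1, 1], bool)
        counts = venn_partition({"A": a, "B": b})
        assert counts[("A", "B")] == 0
        sub = np.array([1, 0, 0, 0], bool)
        sup = np.array([1, 1, 0, 0], bool)
        counts = venn_partition({"A": sub, "B": sup})
        assert counts[("A",)] == 0

    @given(data=st.data())
    @settings(max_examples=100, deadline=None)
    def test_counts_match_per_bin_enumeration_and_sum(self, data):
        n = data.draw(st.integers(1, 60))
        k = data.draw(st.integers(1, 4))
        names = [f"s{i}" for i in range(k)]
        presence = {
            name: np.array(data.draw(st.lists(st.booleans(), min_size=n, max_size=n)))
            for name in names
        }
        counts = venn_partition(presence)
        assert sum(counts.values()) == n
        for region, count in counts.items():
            mask = np.ones(n, bool)
            for name in names:
                mask &= presence[name] if name in region else ~presence[name]
            assert count == int(mask.sum())


class TestGroupByLevel:
    def test_all_zero_single_group(self):
        with pytest.warns(UserWarning):
            out = group_by_level(np.zeros(5), 15)
        assert set(out.group) == {1}

    def test_distinct_levels_construction(self):
        out = group_by_level(np.arange(16, dtype=float), 15)  # one zero + 1..15
        assert len(out.definitions) == 14
        sizes = out.sizes
        assert sizes[1] == 1  # the zero bin
        # every non-zero bin lands in exactly one interval group; the top
        # (closed) interval holds the two highest levels
        assert sum(v for g, v in sizes.items() if g > 1) == 15
        assert sizes[max(sizes)] == 2
        assert all(sizes[g] == 1 for g in range(2, 15))

    def test_heavy_ties_fewer_groups_none_empty(self):
        rng = np.random.default_rng(2)
        levels = rng.choice([0.0, 1.0, 1.0, 2.0, 5.0], size=300)
        out = group_by_level(levels, 15)
        assert len(out.definitions) < 14
        sizes = out.sizes
        assert sum(sizes.values()) == 300
        interval_groups = set(range(2, len(out.definitions) + 2))
        assert set(g for g in sizes if g > 1) == interval_groups
        # direct enumeration: assignment respects the interval definitions
        for level, g in zip(levels, out.group):
            if level == 0:
                assert g == 1
            else:
                lo, hi = out.definitions[g - 2]
                top = g - 2 == len(out.definitions) - 1
                assert lo <= level < hi or (top and level <= hi)
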