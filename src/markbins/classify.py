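"""Combinatorial-mark classification and interval-overlap enrichment.

Implements the chromatin-state classifier used to ask whether histone-mark
signal predicts piRNA source loci: a tie-aware ROC/AUC built from cumulative
true/false positive counts with trapezoidal integration, mark combination by
mean, consensus peak calling across replicates, per-bin peak presence calls,
2x2 odds-ratio enrichment with Fisher's exact test, Venn region counting and
signal-level grouping for violin-style summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class ROCResult:
    thresholds: np.ndarray  # distinct score values, descending
    fpr: np.ndarray  # includes the (0, 0) origin
    tpr: np.ndarray
    auc: float
    n_positive: int
    n_negative: int


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> ROCResult:
    """ROC curve and trapezoidal AUC with tied scores grouped per threshold.

    Bins are ranked by score descending; each distinct score value yields one
    operating point (cumulative TP/FP counts), which makes the curve cross
    tie blocks diagonally rather than taking the optimistic per-item path.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must align")
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs at least one positive and one negative instance")

    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    sorted_labels = labels[order]
    # last index of each tie block
    block_end = np.nonzero(np.diff(sorted_scores))[0]
    block_end = np.concatenate([block_end, [scores.size - 1]])
    cum_tp = np.cumsum(sorted_labels)[block_end]
    cum_fp = np.cumsum(~sorted_labels)[block_end]
    tpr = np.concatenate([[0.0], cum_tp / n_pos])
    fpr = np.concatenate([[0.0], cum_fp / n_neg])
    auc = float(np.trapezoid(tpr, fpr))
    return ROCResult(
        thresholds=sorted_scores[block_end],
        fpr=fpr,
        tpr=tpr,
        auc=auc,
        n_positive=n_pos,
        n_negative=n_neg,
    )


def combine_marks(track_a: np.ndarray, track_b: np.ndarray) -> np.ndarray:
    """Element-wise mean of two per-bin tracks on comparable scales."""
    a = np.asarray(track_a, dtype=np.float64)
    b = np.asarray(track_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("tracks must cover the same bins")
    return (a + b) / 2.0


def merge_intervals(intervals: pd.DataFrame) -> pd.DataFrame:
    """Union-merge of overlapping (>= 1 bp) intervals; touching ones stay apart."""
    if intervals.empty:
        return intervals.loc[:, ["chrom", "start", "end"]].copy()
    merged: list[tuple[str, int, int]] = []
    ordered = intervals.sort_values(["chrom", "start", "end"], kind="stable")
    cur = None
    for chrom, start, end in zip(ordered["chrom"], ordered["start"], ordered["end"]):
        if cur is not None and chrom == cur[0] and start < cur[2]:
            cur = (chrom, cur[1], max(cur[2], end))
        else:
            if cur is not None:
                merged.append(cur)
            cur = (chrom, int(start), int(end))
    merged.append(cur)
    return pd.DataFrame(merged, columns=["chrom", "start", "end"])


def consensus_peaks(
    replicate_peaks: list[pd.DataFrame], min_support: int = 2
) -> pd.DataFrame:
    """Merge replicate peak sets and keep intervals backed by enough replicates.

    All peaks are pooled and union-merged; a merged interval is retained iff
    at least ``min_support`` distinct replicates contribute an overlapping
    original peak. With a single replicate every peak is retained as is.
    Adds a ``support`` column.
    """
    if not replicate_peaks:
        raise ValueError("need at least one replicate peak set")
    if len(replicate_peaks) == 1:
        out = replicate_peaks[0].loc[:, ["chrom", "start", "end"]].copy()
        out["support"] = 1
        return out.reset_index(drop=True)
    tagged = []
    for rep, peaks in enumerate(replicate_peaks):
        if peaks.empty:
            continue
        t = peaks.loc[:, ["chrom", "start", "end"]].copy()
        t["replicate"] = rep
        tagged.append(t)
    if not tagged:
        return pd.DataFrame(columns=["chrom", "start", "end", "support"])
    pooled = pd.concat(tagged, ignore_index=True)
    merged = merge_intervals(pooled)
    support = np.zeros(len(merged), dtype=np.int64)
    for i, (chrom, start, end) in enumerate(
        zip(merged["chrom"], merged["start"], merged["end"])
    ):
        on = pooled[
            (pooled["chrom"] == chrom)
            & (pooled["start"] < end)
            & (pooled["end"] > start)
        ]
        support[i] = on["replicate"].nunique()
    merged["support"] = support
    return merged[merged["support"] >= min_support].reset_index(drop=True)


def bin_presence(bins: pd.DataFrame, peaks: pd.DataFrame) -> np.ndarray:
    """True for every bin overlapping any peak by at least 1 bp (half-open)."""
    present = np.zeros(len(bins), dtype=bool)
    if peaks.empty:
        return present
    merged = merge_intervals(peaks)
    for chrom, idx in bins.groupby("chrom", sort=False).groups.items():
        p = merged[merged["chrom"] == chrom]
        if p.empty:
            continue
        pstarts = p["start"].to_numpy()
        pends = p["end"].to_numpy()
        bstarts = bins.loc[idx, "start"].to_numpy()
        bends = bins.loc[idx, "end"].to_numpy()
        # merged peaks are disjoint and sorted; a bin overlaps iff some peak
        # starts before the bin end and ends after the bin start
        j = np.searchsorted(pstarts, bends, side="left") - 1
        ok = (j >= 0) & (np.where(j >= 0, pends[np.clip(j, 0, None)], 0) > bstarts)
        present[bins.index.get_indexer(idx)] = ok
    return present


@dataclass
class OverlapTable:
    """2x2 presence table with its odds ratio and Fisher exact probability.

    Cells: a = both present, b = A only, c = B only, d = neither. The odds
    ratio is the sample estimate (a*d)/(b*c) with a Haldane correction of
    0.5 added to every cell when any cell is zero; the p value is the
    standard two-sided Fisher exact probability (sum of hypergeometric
    point probabilities <= that of the observed table).
    """

    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    p_value: float
    label: str = ""

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


def _table_from_counts(a: int, b: int, c: int, d: int, label: str = "") -> OverlapTable:
    if min(a, b, c, d) < 0:
        raise ValueError("cell counts must be non-negative")
    if a + b + c + d == 0:
        raise ValueError("empty universe")
    if min(a, b, c, d) == 0:
        odds = (a + 0.5) * (d + 0.5) / ((b + 0.5) * (c + 0.5))
    else:
        odds = a * d / (b * c)
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return OverlapTable(a=a, b=b, c=c, d=d, odds_ratio=float(odds), p_value=float(p), label=label)


def overlap_enrichment(
    presence_a: np.ndarray,
    presence_b: np.ndarray,
    strata: pd.Series | np.ndarray | None = None,
) -> OverlapTable | dict[str, OverlapTable]:
    """Association between two per-bin presence calls over the bin universe.

    Without ``strata`` a single 2x2 table of A vs B is returned. With
    ``strata`` (a categorical label per bin, e.g. the four-way mark
    combination), one 2x2 table per stratum is returned: presence of A vs
    membership in that stratum against all other bins.
    """
    a_vec = np.asarray(presence_a, dtype=bool)
    b_vec = np.asarray(presence_b, dtype=bool)
    if a_vec.shape != b_vec.shape:
        raise ValueError("presence vectors must have equal length")
    if a_vec.size == 0:
        raise ValueError("empty universe")
    if strata is None:
        return _table_from_counts(
            int((a_vec & b_vec).sum()),
            int((a_vec & ~b_vec).sum()),
            int((~a_vec & b_vec).sum()),
            int((~a_vec & ~b_vec).sum()),
        )
    strata = np.asarray(strata)
    tables: dict[str, OverlapTable] = {}
    for label in pd.unique(strata):
        member = strata == label
        tables[str(label)] = _table_from_counts(
            int((a_vec & member).sum()),
            int((a_vec & ~member).sum()),
            int((~a_vec & member).sum()),
            int((~a_vec & ~member).sum()),
            label=str(label),
        )
    return tables


def venn_partition(presence: dict[str, np.ndarray]) -> dict[tuple[str, ...], int]:
    """Exact counts of every membership region for up to four presence calls."""
    names = list(presence)
    if not 1 <= len(names) <= 4:
        raise ValueError("venn_partition supports 1 to 4 sets")
    mat = np.column_stack([np.asarray(presence[n], dtype=bool) for n in names])
    codes = mat @ (1 << np.arange(len(names)))
    counts = np.bincount(codes, minlength=1 << len(names))
    return {
        tuple(n for i, n in enumerate(names) if code >> i & 1): int(counts[code])
        for code in range(1 << len(names))
    }


@dataclass
class GroupAssignment:
    """Outcome of signal-level grouping: group 1 is always the zero-level group."""

    group: np.ndarray  # int per bin, 1-based
    breakpoints: np.ndarray
    definitions: list[tuple[float, float]]  # (low, high) per interval group

    @property
    def sizes(self) -> dict[int, int]:
        uniq, counts = np.unique(self.group, return_counts=True)
        return dict(zip(uniq.tolist(), counts.tolist()))


def group_by_level(levels: np.ndarray, n_breakpoints: int = 15) -> GroupAssignment:
    """Partition bins into a zero group plus signal-level interval groups.

    Non-zero levels are sorted ascending; ``n_breakpoints`` equidistant rank
    breakpoints (including the lowest and highest level) are extracted, and
    each pair of consecutive distinct breakpoint values defines a half-open
    interval (the last interval is closed at the top). Ties can collapse
    breakpoints, so at most ``n_breakpoints - 1`` interval groups result.
    """
    levels = np.asarray(levels, dtype=np.float64)
    if np.any(levels < 0):
        raise ValueError("levels must be non-negative")
    if n_breakpoints < 2:
        raise ValueError("need at least two breakpoints")
    group = np.ones(levels.size, dtype=np.int64)
    nonzero = levels[levels > 0]
    if nonzero.size == 0:
        warnings.warn("no non-zero levels; single zero group returned", stacklevel=2)
        return GroupAssignment(group=group, breakpoints=np.array([]), definitions=[])
    ordered = np.sort(nonzero)
    m = ordered.size
    ranks = np.round(np.arange(n_breakpoints) * (m - 1) / (n_breakpoints - 1)).astype(int)
    breakpoints = ordered[ranks]
    definitions: list[tuple[float, float]] = []
    for lo, hi in zip(breakpoints, breakpoints[1:]):
        if hi > lo:
            definitions.append((float(lo), float(hi)))
    if not definitions:
        # all non-zero levels identical: one interval group holding them all
        definitions.append((float(breakpoints[0]), float(breakpoints[0])))
    lows = np.array([d[0] for d in definitions])
    idx = np.clip(np.searchsorted(lows, levels, side="right") - 1, 0, len(definitions) - 1)
    group = np.where(levels > 0, idx + 2, 1)
    return GroupAssignment(group=group, breakpoints=breakpoints, definitions=definitions)
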