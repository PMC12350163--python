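"""Fragment counting, normalization and the transforms used downstream.

Counting follows the half-length rule: a fragment contributes to every bin
that covers at least ``min_overlap_fraction`` of the fragment's length (ties
included, so a fragment split exactly in half is counted in both bins).
Normalization is FPKM on the mappable effective bin length, or plain counts
per million; background (IgG/input) tracks are subtracted on a fine window
grid after signal-extraction scaling (SES), with negatives clamped to zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class FragmentSet:
    """Stranded intervals from one sequencing library.

    ``intervals`` has columns chrom, start, end, strand (``+``, ``-`` or
    ``.``), 0-based half-open.
    """

    sample: str
    condition: str
    replicate: int
    intervals: pd.DataFrame

    def __post_init__(self) -> None:
        missing = {"chrom", "start", "end", "strand"} - set(self.intervals.columns)
        if missing:
            raise ValueError(f"fragment table lacks columns {sorted(missing)}")
        if len(self.intervals) and not (
            self.intervals["start"] < self.intervals["end"]
        ).all():
            raise ValueError("fragments must satisfy start < end")

    @property
    def library_size(self) -> int:
        return len(self.intervals)


def count_fragments(
    bins: pd.DataFrame,
    fragments: FragmentSet | pd.DataFrame,
    min_overlap_fraction: float | None = 0.5,
    strand: str = "both",
) -> tuple[np.ndarray, int]:
    """Count fragments per bin under the >= overlap-fraction rule.

    ``min_overlap_fraction=None`` counts any overlap of at least 1 bp
    (coverage-style counting for fine window grids). Bins must be disjoint
    and sorted within each chromosome. Returns (counts, n_skipped) where
    skipped fragments lie on sequences absent from the bin set.
    """
    if min_overlap_fraction is not None and not 0 < min_overlap_fraction <= 1:
        raise ValueError("min_overlap_fraction must be in (0, 1]")
    if strand not in {"+", "-", "both"}:
        raise ValueError("strand must be '+', '-' or 'both'")
    frags = fragments.intervals if isinstance(fragments, FragmentSet) else fragments
    if strand != "both":
        frags = frags[frags["strand"] == strand]

    counts = np.zeros(len(bins), dtype=np.int64)
    n_skipped = 0
    bin_pos = {
        chrom: (
            bins.index.get_indexer(idx),
            bins.loc[idx, "start"].to_numpy(),
            bins.loc[idx, "end"].to_numpy(),
        )
        for chrom, idx in bins.groupby("chrom", sort=False).groups.items()
    }
    for chrom, group in frags.groupby("chrom", sort=False):
        if chrom not in bin_pos:
            n_skipped += len(group)
            continue
        rows, bstarts, bends = bin_pos[chrom]
        if np.any(np.diff(bstarts) < 0) or np.any(bstarts[1:] < bends[:-1]):
            raise ValueError(f"bins on {chrom} are not sorted and disjoint")
        fs = group["start"].to_numpy()
        fe = group["end"].to_numpy()
        flen = fe - fs
        first = np.searchsorted(bends, fs, side="right")
        last = np.searchsorted(bstarts, fe, side="left")
        span = last - first
        max_span = int(span.max(initial=0))
        for offset in range(max_span):
            hit = span > offset
            bidx = first[hit] + offset
            ovl = np.minimum(fe[hit], bends[bidx]) - np.maximum(fs[hit], bstarts[bidx])
            if min_overlap_fraction is None:
                keep = ovl >= 1
            else:
                keep = ovl >= min_overlap_fraction * flen[hit]
            np.add.at(counts, rows[bidx[keep]], 1)
    return counts, n_skipped


def normalize_fpkm(
    counts: np.ndarray,
    bin_lengths: np.ndarray,
    mappability: np.ndarray,
    library_size: int | float,
) -> np.ndarray:
    """Fragments per kilobase of mappable bin length per million mapped reads.

    value = count * 1e9 / (library_size * bin_length * mappability); the
    denominator uses the mappable effective length, so a half-mappable bin
    gets twice the per-count signal.
    """
    if library_size <= 0:
        raise ValueError("library size must be positive")
    mappability = np.asarray(mappability, dtype=np.float64)
    if np.any(mappability <= 0):
        raise ValueError("mappability must be positive for all retained bins")
    return (
        np.asarray(counts, dtype=np.float64)
        * 1e9
        / (library_size * np.asarray(bin_lengths, dtype=np.float64) * mappability)
    )


def normalize_cpm(counts: np.ndarray, library_size: int | float) -> np.ndarray:
    """Counts per million mapped reads."""
    if library_size <= 0:
        raise ValueError("library size must be positive")
    return np.asarray(counts, dtype=np.float64) * 1e6 / library_size


def ses_scale_factor(
    signal: np.ndarray,
    background: np.ndarray,
    lowest_fraction: float = 0.5,
    bounds: tuple[float, float] = (1e-3, 1e3),
) -> float:
    """Scale factor matching background to signal where enrichment is absent.

    Windows are ordered by signal; the lowest-signal ``lowest_fraction`` of
    them defines s = sum(signal)/sum(background) over that subset, capped to
    ``bounds``. An all-zero background yields 1 with a warning.
    """
    signal = np.asarray(signal, dtype=np.float64)
    background = np.asarray(background, dtype=np.float64)
    if signal.shape != background.shape:
        raise ValueError("signal and background must share the window grid")
    if not 0 < lowest_fraction <= 1:
        raise ValueError("lowest_fraction must be in (0, 1]")
    if background.sum() == 0:
        warnings.warn("background track is all zero; scale factor set to 1", stacklevel=2)
        return 1.0
    order = np.argsort(signal, kind="stable")
    take = max(1, int(np.floor(lowest_fraction * signal.size)))
    low = order[:take]
    denom = background[low].sum()
    if denom == 0:
        warnings.warn(
            "background is zero over the least-enriched windows; scale factor set to 1",
            stacklevel=2,
        )
        return 1.0
    return float(np.clip(signal[low].sum() / denom, *bounds))


def subtract_background(
    signal: np.ndarray,
    background: np.ndarray,
    scale: float | None = None,
    lowest_fraction: float = 0.5,
    pseudocount: float = 0.0,
) -> np.ndarray:
    """SES-scaled background subtraction with clamping at zero.

    Returns max(signal - scale * background, 0) + pseudocount per window;
    ``scale`` defaults to :func:`ses_scale_factor` on the same tracks.
    """
    signal = np.asarray(signal, dtype=np.float64)
    background = np.asarray(background, dtype=np.float64)
    if scale is None:
        scale = ses_scale_factor(signal, background, lowest_fraction)
    return np.maximum(signal - scale * background, 0.0) + pseudocount


def window_mean_per_bin(
    windows: pd.DataFrame, values: np.ndarray, bins: pd.DataFrame
) -> np.ndarray:
    """Arithmetic mean of window values over the windows fully inside each bin."""
    values = np.asarray(values, dtype=np.float64)
    out = np.zeros(len(bins), dtype=np.float64)
    win_pos = {
        chrom: (
            windows.index.get_indexer(idx),
            windows.loc[idx, "start"].to_numpy(),
            windows.loc[idx, "end"].to_numpy(),
        )
        for chrom, idx in windows.groupby("chrom", sort=False).groups.items()
    }
    for i, (chrom, bstart, bend) in enumerate(
        zip(bins["chrom"], bins["start"], bins["end"])
    ):
        if chrom not in win_pos:
            continue
        rows, wstarts, wends = win_pos[chrom]
        lo = np.searchsorted(wstarts, bstart, side="left")
        hi = np.searchsorted(wends, bend, side="right")
        if hi > lo:
            out[i] = values[rows[lo:hi]].mean()
    return out


def size_factors_median_of_ratios(matrix: pd.DataFrame) -> pd.Series:
    """Median-of-ratios library size factors.

    The reference for each bin is its geometric mean across samples (rows
    with any zero excluded); the factor of a sample is the median over bins
    of count/reference. A single-sample matrix yields factor 1.
    """
    counts = matrix.to_numpy(dtype=np.float64)
    positive = (counts > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no bin has positive counts in every sample")
    logs = np.log(counts[positive])
    ref = logs.mean(axis=1)
    factors = np.exp(np.median(logs - ref[:, None], axis=0))
    return pd.Series(factors, index=matrix.columns, name="size_factor")


def log2_fold_change(
    mean_treated: np.ndarray | float,
    mean_control: np.ndarray | float,
    pseudocount: float = 0.01,
) -> np.ndarray | float:
    """log2((treated + pc) / (control + pc)) on non-negative normalized means."""
    treated = np.asarray(mean_treated, dtype=np.float64)
    control = np.asarray(mean_control, dtype=np.float64)
    if np.any(treated < 0) or np.any(control < 0):
        raise ValueError("means must be non-negative")
    out = np.log2((treated + pseudocount) / (control + pseudocount))
    return float(out) if out.ndim == 0 else out


def cap_log10(
    values: np.ndarray, cap: float, pseudocount: float = 1.0
) -> np.ndarray:
    """log10(min(value, cap) + pseudocount) for display-scale signal."""
    values = np.asarray(values, dtype=np.float64)
    return np.log10(np.minimum(values, cap) + pseudocount)


def min_strand(forward: np.ndarray, reverse: np.ndarray) -> np.ndarray:
    """Element-wise minimum of the two strands (suppresses unistrand signal)."""
    forward = np.asarray(forward, dtype=np.float64)
    reverse = np.asarray(reverse, dtype=np.float64)
    if forward.shape != reverse.shape:
        raise ValueError("strand tracks must cover the same bins")
    return np.minimum(forward, reverse)
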