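"""Knockdown dependency calls for bins and peaks.

Bins producing piRNAs are classified by how strongly their output drops when
a factor is depleted: Rhino dependency is a mean fold loss above a 2-fold
threshold across depletion strategies; Rhino-dependent bins are then split
into E(z)-dependent, Kipferl-dependent, dependent on both, or neither, at a
4-fold threshold. Occupancy peaks are classified as Kipferl-dependent or
-independent from their persistence in the Kipferl knockdown. The delta-group
analysis ranks bins by the change of one mark after knockdown, cuts them
into equal-size groups and summarizes how responder tracks move per group.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classify import bin_presence, merge_intervals

DEFAULT_UNPLACED_PATTERN = r"Scaffold|rand|^(?!chr)"


def fold_loss(
    control: np.ndarray,
    depleted: np.ndarray,
    pseudocount: float = 0.01,
    mode: str = "mean_of_ratios",
) -> np.ndarray:
    """Per-bin fold loss (control over depleted) across replicate columns.

    Both inputs are bins x replicates matrices of normalized values.
    ``mean_of_ratios`` pairs replicates by index, takes (control + pc) /
    (depleted + pc) per pair and averages; ``ratio_of_means`` averages each
    side first.
    """
    control = np.atleast_2d(np.asarray(control, dtype=np.float64).T).T
    depleted = np.atleast_2d(np.asarray(depleted, dtype=np.float64).T).T
    if mode == "mean_of_ratios":
        if control.shape != depleted.shape:
            raise ValueError("mean_of_ratios pairs replicates by index; shapes differ")
        return ((control + pseudocount) / (depleted + pseudocount)).mean(axis=1)
    if mode == "ratio_of_means":
        return (control.mean(axis=1) + pseudocount) / (depleted.mean(axis=1) + pseudocount)
    raise ValueError(f"unknown fold-change mode {mode!r}")


def classify_rhi_dependent(
    strategies: dict[str, tuple[np.ndarray, np.ndarray]],
    threshold_fold: float = 2.0,
    pseudocount: float = 0.01,
    mode: str = "mean_of_ratios",
) -> pd.DataFrame:
    """Bins whose mean piRNA fold loss across depletion strategies exceeds a threshold.

    Each strategy supplies (control, depleted) per-bin normalized matrices on
    the same bin set. Replicates are averaged within a strategy before the
    fold losses are averaged across strategies; a bin is Rhino-dependent iff
    that mean exceeds ``threshold_fold`` (strict).
    """
    if not strategies:
        raise ValueError("need at least one depletion strategy")
    losses = {}
    n_bins = None
    for name, (control, depleted) in strategies.items():
        fc = fold_loss(control, depleted, pseudocount, mode)
        if n_bins is None:
            n_bins = fc.size
        elif fc.size != n_bins:
            raise ValueError("bin sets differ across strategies")
        losses[name] = fc
    table = pd.DataFrame(losses)
    table["mean_fold_loss"] = table.mean(axis=1)
    table["rhi_dependent"] = table["mean_fold_loss"] > threshold_fold
    return table


def classify_ez_kipf(
    rhi_dependent: np.ndarray,
    fold_losses: dict[str, np.ndarray],
    threshold_fold: float = 4.0,
) -> pd.DataFrame:
    """Split Rhino-dependent bins by which knockdowns abolish their piRNA output.

    ``fold_losses`` maps the perturbations (``EzKD``, ``kipfKD``) to per-bin
    mean fold losses. Categories (mutually exclusive, exhaustive over
    Rhino-dependent bins): ``Ez_dep``, ``Kipf_dep``, ``both`` or ``neither``
    at >= ``threshold_fold`` mean loss.
    """
    for key in ("EzKD", "kipfKD"):
        if key not in fold_losses:
            raise ValueError(f"fold losses for {key!r} are required")
    rhi_dependent = np.asarray(rhi_dependent, dtype=bool)
    ez = np.asarray(fold_losses["EzKD"], dtype=np.float64) >= threshold_fold
    kipf = np.asarray(fold_losses["kipfKD"], dtype=np.float64) >= threshold_fold
    category = np.full(rhi_dependent.size, "", dtype=object)
    category[rhi_dependent & ez & ~kipf] = "Ez_dep"
    category[rhi_dependent & ~ez & kipf] = "Kipf_dep"
    category[rhi_dependent & ez & kipf] = "both"
    category[rhi_dependent & ~ez & ~kipf] = "neither"
    out = pd.DataFrame(
        {
            "rhi_dependent": rhi_dependent,
            "fold_loss_EzKD": fold_losses["EzKD"],
            "fold_loss_kipfKD": fold_losses["kipfKD"],
            "category": category,
        }
    )
    out.attrs["threshold_fold"] = threshold_fold
    return out


@dataclass
class PeakDependencyResult:
    peaks: pd.DataFrame  # chrom, start, end, excluded, reason, kipf_class
    min_fold: float

    @property
    def n_dependent(self) -> int:
        return int((self.peaks["kipf_class"] == "dependent").sum())

    @property
    def n_independent(self) -> int:
        return int((self.peaks["kipf_class"] == "independent").sum())


def classify_peaks_kipf(
    control_replicate_peaks: list[pd.DataFrame],
    rhikd_peaks: pd.DataFrame,
    kipfkd_peaks: pd.DataFrame,
    min_fold: float = 3.0,
    unplaced_pattern: str = DEFAULT_UNPLACED_PATTERN,
) -> PeakDependencyResult:
    """High-confidence occupancy peaks split by Kipferl dependency.

    Per-replicate control peaks with fold enrichment >= ``min_fold`` are
    union-merged into a high-confidence set. Peaks on unplaced contigs
    (sequence name matching ``unplaced_pattern``) or overlapping any peak
    retained in the Rhino knockdown are excluded with a reason. Remaining
    peaks are ``independent`` iff they overlap a peak in the Kipferl
    knockdown (Rhino still binds there without Kipferl), else ``dependent``.
    """
    confident = []
    for peaks in control_replicate_peaks:
        if "fold_enrichment" not in peaks.columns:
            raise ValueError("control peaks must carry a fold_enrichment column")
        confident.append(peaks[peaks["fold_enrichment"] >= min_fold])
    pooled = (
        pd.concat(confident, ignore_index=True)
        if confident
        else pd.DataFrame(columns=["chrom", "start", "end"])
    )
    merged = merge_intervals(pooled)

    pattern = re.compile(unplaced_pattern)
    unplaced = merged["chrom"].map(lambda c: bool(pattern.search(c))).to_numpy(dtype=bool)
    in_rhikd = bin_presence(merged, rhikd_peaks)
    in_kipfkd = bin_presence(merged, kipfkd_peaks)

    excluded = unplaced | in_rhikd
    reason = np.full(len(merged), "", dtype=object)
    reason[in_rhikd] = "present_in_rhiKD"
    reason[unplaced] = "unplaced_contig"  # takes precedence
    kipf_class = np.full(len(merged), "", dtype=object)
    kipf_class[~excluded & in_kipfkd] = "independent"
    kipf_class[~excluded & ~in_kipfkd] = "dependent"

    out = merged.copy()
    out["excluded"] = excluded
    out["reason"] = reason
    out["kipf_class"] = kipf_class
    return PeakDependencyResult(peaks=out, min_fold=min_fold)


def delta_group_analysis(
    bins: pd.DataFrame,
    delta: np.ndarray,
    responders: dict[str, np.ndarray],
    n_groups: int = 6,
    secondary: np.ndarray | None = None,
    secondary_percentile: float = 90.0,
) -> tuple[pd.Series, pd.DataFrame]:
    """Equal-size groups by signal change, with per-group responder means.

    Bins are ranked by ``delta`` ascending (strongest loss first; ties broken
    deterministically by bin_id) and split into ``n_groups`` groups of equal
    size, any remainder going to the lowest-rank groups. When ``secondary``
    is given, the analysis is first restricted to bins whose secondary-mark
    signal is at or above the ``secondary_percentile`` of euchromatic bins
    (requires a ``compartment`` column).

    Returns (group per retained bin as a Series indexed by bin_id,
    per-group summary with mean delta and mean responder values).
    """
    if n_groups < 1:
        raise ValueError("n_groups must be >= 1")
    delta = np.asarray(delta, dtype=np.float64)
    if len(bins) != delta.size:
        raise ValueError("delta must align with bins")
    keep = np.ones(len(bins), dtype=bool)
    if secondary is not None:
        if "compartment" not in bins.columns:
            raise ValueError("restriction requires compartment labels on bins")
        secondary = np.asarray(secondary, dtype=np.float64)
        eu = bins["compartment"].to_numpy() == "euchromatin"
        if not eu.any():
            raise ValueError("no euchromatic bins to anchor the percentile")
        cutoff = np.percentile(secondary[eu], secondary_percentile)
        keep = secondary >= cutoff

    sub = bins.loc[keep, ["bin_id"]].copy()
    sub["delta"] = delta[keep]
    for name, values in responders.items():
        sub[name] = np.asarray(values, dtype=np.float64)[keep]
    sub = sub.sort_values(["delta", "bin_id"], kind="stable").reset_index(drop=True)

    n = len(sub)
    if n == 0:
        raise ValueError("no bins retained for grouping")
    base, extra = divmod(n, n_groups)
    sizes = [base + 1 if g < extra else base for g in range(n_groups)]
    group = np.repeat(np.arange(1, n_groups + 1), sizes)
    sub["group"] = group

    summary = sub.groupby("group").agg(
        n=("bin_id", "size"),
        mean_delta=("delta", "mean"),
        **{f"mean_{name}": (name, "mean") for name in responders},
    )
    return pd.Series(sub["group"].to_numpy(), index=sub["bin_id"], name="group"), summary
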