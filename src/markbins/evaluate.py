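"""Scoring pipeline output against the simulator's ground truth.

Only meaningful for synthetic cohorts: compares the dependency calls, peak
classification and cluster predictions with the truth table the generator
emitted.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def expected_dependency_labels(truth: pd.DataFrame) -> pd.DataFrame:
    """Per-bin expected calls: Rhino dependency flag and E(z)/Kipf category."""
    dual = (truth["cluster_label"] == "dual_strand").to_numpy()
    cls = truth["dependency_class"].to_numpy()
    category = np.select(
        [cls == "Ez_dep", cls == "Kipf_dep", cls == "both_dep"],
        ["Ez_dep", "Kipf_dep", "both"],
        default="neither",
    )
    return pd.DataFrame(
        {"rhi_dependent": dual, "category": np.where(dual, category, "")},
        index=truth["bin_id"],
    )


def dependency_recovery(
    truth: pd.DataFrame, dependency_table: pd.DataFrame
) -> dict[str, float]:
    """Sensitivity/specificity of the Rhino call and overall label recovery.

    ``dependency_table`` is indexed by bin_id (a subset of truth bins, e.g.
    after mappability filtering); metrics are computed on the intersection.
    """
    expected = expected_dependency_labels(truth)
    common = dependency_table.index.intersection(expected.index)
    exp = expected.loc[common]
    got = dependency_table.loc[common]
    dual = exp["rhi_dependent"].to_numpy()
    called = got["rhi_dependent"].to_numpy()
    correct = (called == dual) & (
        ~dual | (got["category"].to_numpy() == exp["category"].to_numpy())
    )
    return {
        "sensitivity": float(called[dual].mean()) if dual.any() else float("nan"),
        "specificity": float(1 - called[~dual].mean()) if (~dual).any() else float("nan"),
        "label_recovery": float(correct.mean()),
        "n_bins": int(common.size),
    }


def peak_split_accuracy(truth: pd.DataFrame, peak_table: pd.DataFrame) -> dict[str, float]:
    """Fraction of classified peaks whose Kipferl call matches the truth bins.

    A peak's expected class is ``independent`` iff it overlaps any bin the
    truth table marks as a Kipferl-independent site.
    """
    classified = peak_table[~peak_table["excluded"]]
    indep_bins = truth[truth["kipf_independent_site"]]
    by_chrom = {
        chrom: (grp["start"].to_numpy(), grp["end"].to_numpy())
        for chrom, grp in indep_bins.groupby("chrom")
    }
    correct = 0
    for row in classified.itertuples():
        starts_ends = by_chrom.get(row.chrom)
        overlaps = False
        if starts_ends is not None:
            starts, ends = starts_ends
            overlaps = bool(np.any((starts < row.end) & (ends > row.start)))
        expected = "independent" if overlaps else "dependent"
        correct += row.kipf_class == expected
    n = len(classified)
    return {"accuracy": correct / n if n else float("nan"), "n_peaks": n}
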