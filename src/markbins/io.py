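"""Readers and writers for the plain-text formats the pipeline exchanges.

BED is consumed and produced natively in 0-based half-open coordinates.
Fragment files are BED6 (strand meaningful for small-RNA sets); peak files
are BED6 plus fold-enrichment and q-value columns; bins are written as BED4
plus mappability and compartment.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]
PEAK_COLUMNS = BED6_COLUMNS + ["fold_enrichment", "q_value"]


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED file with 3 to 8 columns; extra columns are preserved.

    Columns beyond the third get the standard names (name, score, strand,
    fold_enrichment, q_value); missing ones are filled with defaults.
    """
    try:
        frame = pd.read_csv(
            str(path), sep="\t", header=None, comment="#", dtype={0: str}
        )
    except pd.errors.EmptyDataError:
        return pd.DataFrame(
            {col: pd.Series(dtype=t) for col, t in zip(
                PEAK_COLUMNS,
                [str, np.int64, np.int64, str, np.int64, str, float, float],
            )}
        )
    n_cols = frame.shape[1]
    if n_cols < 3:
        raise ValueError(f"{path}: BED needs at least 3 columns")
    frame.columns = PEAK_COLUMNS[:n_cols] + [
        f"extra_{i}" for i in range(n_cols - len(PEAK_COLUMNS))
    ]
    if "name" not in frame.columns:
        frame["name"] = "."
    if "score" not in frame.columns:
        frame["score"] = 0
    if "strand" not in frame.columns:
        frame["strand"] = "."
    frame["start"] = frame["start"].astype(np.int64)
    frame["end"] = frame["end"].astype(np.int64)
    if not (frame["start"] < frame["end"]).all():
        raise ValueError(f"{path}: intervals must satisfy start < end")
    return frame


def write_bed(frame: pd.DataFrame, path: str | Path, columns: list[str] | None = None) -> None:
    """Write selected columns as TAB-separated BED with stable float formatting."""
    if columns is None:
        columns = [c for c in PEAK_COLUMNS if c in frame.columns]
    frame.loc[:, columns].to_csv(
        str(path), sep="\t", header=False, index=False, float_format="%.6g"
    )


def write_table(frame: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    """TSV output with stable float formatting (deterministic re-runs)."""
    frame.to_csv(str(path), sep="\t", index=index, float_format="%.10g")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(str(path), sep="\t")
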