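"""Genome binning, n-mer mappability and compartment assignment.

The genome is tiled into fixed-size bins (trailing shorter bin kept) or cut
into sliding windows. Mappability of a position is the fraction of the n
read-length k-mers overlapping it that occur exactly once in the genome,
counting both strands; the per-bin value is the fraction of k-mer start
positions inside the bin that are unique. Bins are then filtered on
mappability, size and sequence name, and labelled with a chromatin
compartment (euchromatin / heterochromatin / other) by bin midpoint.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import GenomeAssembly

BIN_COLUMNS = ["chrom", "start", "end", "bin_id"]

_BASE_CODES = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODES[_b] = _i
    _BASE_CODES[ord(chr(_b).lower())] = _i


def _bin_ids(chroms: pd.Series, starts: pd.Series, ends: pd.Series) -> pd.Series:
    return chroms + ":" + starts.astype(str) + "-" + ends.astype(str)


def tile_genome(assembly: GenomeAssembly, bin_size: int) -> pd.DataFrame:
    """Tile every sequence left to right into non-overlapping bins.

    The final bin of each sequence is retained even if shorter than
    ``bin_size``. Returns a frame sorted by (chrom, start) with a
    ``bin_id`` of the form ``chrom:start-end``.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    if len(assembly) == 0:
        raise ValueError("cannot tile an empty assembly")
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    for name in assembly.names:
        length = assembly.lengths[name]
        edges = list(range(0, length, bin_size)) + [length]
        chroms.extend([name] * (len(edges) - 1))
        starts.extend(edges[:-1])
        ends.extend(edges[1:])
    bins = pd.DataFrame({"chrom": chroms, "start": starts, "end": ends})
    bins["bin_id"] = _bin_ids(bins["chrom"], bins["start"], bins["end"])
    return bins


def slide_genome(
    assembly: GenomeAssembly,
    window: int = 10_000,
    step: int = 5_000,
    min_size: int = 5_000,
) -> pd.DataFrame:
    """Cut every sequence into sliding windows of ``window`` bp every ``step`` bp.

    Windows are truncated at the sequence end. All raw windows are returned;
    windows shorter than ``min_size`` are flagged in the ``below_min_size``
    column and are meant to be dropped by :func:`filter_bins` (the raw count
    is still reported by callers that need it).
    """
    if step <= 0 or step > window:
        raise ValueError("require 0 < step <= window")
    if len(assembly) == 0:
        raise ValueError("cannot window an empty assembly")
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    for name in assembly.names:
        length = assembly.lengths[name]
        for start in range(0, length, step):
            chroms.extend([name])
            starts.append(start)
            ends.append(min(start + window, length))
    bins = pd.DataFrame({"chrom": chroms, "start": starts, "end": ends})
    bins["bin_id"] = _bin_ids(bins["chrom"], bins["start"], bins["end"])
    bins["below_min_size"] = (bins["end"] - bins["start"]) < min_size
    return bins


def _encode(seq: str) -> np.ndarray:
    return _BASE_CODES[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _kmer_ints(codes: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Integer encodings of all n-mers plus a validity mask (no non-ACGT base)."""
    valid_base = codes != 255
    windows = np.lib.stride_tricks.sliding_window_view(
        np.where(valid_base, codes, 0).astype(np.uint64), n
    )
    powers = (4 ** np.arange(n - 1, -1, -1, dtype=np.uint64))
    values = windows @ powers
    bad = np.convolve((~valid_base).astype(np.int64), np.ones(n, dtype=np.int64), "valid") > 0
    return values, ~bad


@dataclass
class MappabilityTrack:
    """Per-position and per-bin mappability for one read length ``n``.

    ``unique_starts[name]`` flags, for every k-mer start position, whether
    that k-mer occurs exactly once in the genome (both strands considered; a
    palindromic k-mer counts its two strand occurrences as one placement).
    """

    n: int
    unique_starts: dict[str, np.ndarray]
    lengths: dict[str, int]

    def position_values(self, name: str) -> np.ndarray:
        """Fraction of the n k-mers overlapping each position that are unique.

        The denominator is ``n`` everywhere, including near sequence ends
        where fewer than n k-mers overlap a position, so ends are slightly
        penalized; values are capped at 1.
        """
        length = self.lengths[name]
        u = self.unique_starts[name]
        out = np.zeros(length, dtype=np.float64)
        if u.size:
            csum = np.concatenate([[0], np.cumsum(u)])
            pos = np.arange(length)
            lo = np.clip(pos - self.n + 1, 0, u.size)
            hi = np.clip(pos + 1, 0, u.size)
            out = (csum[hi] - csum[lo]) / self.n
        return np.minimum(out, 1.0)

    def bin_values(self, bins: pd.DataFrame) -> np.ndarray:
        """Unique k-mer starts inside each bin divided by the bin length."""
        values = np.zeros(len(bins), dtype=np.float64)
        for chrom, idx in bins.groupby("chrom", sort=False).groups.items():
            u = self.unique_starts.get(chrom)
            if u is None or u.size == 0:
                continue
            csum = np.concatenate([[0], np.cumsum(u)])
            starts = bins.loc[idx, "start"].to_numpy()
            ends = bins.loc[idx, "end"].to_numpy()
            lo = np.clip(starts, 0, u.size)
            hi = np.clip(ends, 0, u.size)
            values[bins.index.get_indexer(idx)] = (csum[hi] - csum[lo]) / (ends - starts)
        return values


def compute_mappability(assembly: GenomeAssembly, n: int) -> MappabilityTrack:
    """Exact-match n-mer mappability over both strands.

    A k-mer is unique iff its sequence occurs exactly once in the whole
    genome considering both strands. Occurrences are counted as placements
    of the canonical (lexicographically smaller of forward and reverse
    complement) form, so a k-mer equal to its own reverse complement counts
    its two strand readings as a single placement. Any k-mer containing a
    non-ACGT symbol is treated as non-unique.
    """
    if not assembly.has_sequences:
        raise ValueError("mappability requires nucleotide sequences")
    if n < 2:
        raise ValueError("n must be >= 2")
    if n > 31:
        return _compute_mappability_strings(assembly, n)

    per_seq: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    all_canon: list[np.ndarray] = []
    for name in assembly.names:
        seq = assembly.sequences[name].upper()
        if len(seq) < n:
            warnings.warn(
                f"sequence {name!r} is shorter than n={n}; mappability set to 0",
                stacklevel=2,
            )
            per_seq[name] = (np.zeros(0, dtype=np.uint64), np.zeros(0, dtype=bool))
            continue
        codes = _encode(seq)
        fwd, valid = _kmer_ints(codes, n)
        # reverse complement read starting at i equals the k-mer of the
        # reverse-complemented sequence starting at L - n - i
        rc_codes = (3 - codes[::-1]).astype(np.uint8)
        rc_codes[codes[::-1] == 255] = 255
        rev, _ = _kmer_ints(rc_codes, n)
        rev = rev[::-1]
        canon = np.minimum(fwd, rev)
        per_seq[name] = (canon, valid)
        all_canon.append(canon[valid])

    if all_canon:
        pooled = np.concatenate(all_canon)
        uniq, counts = np.unique(pooled, return_counts=True)
        singletons = uniq[counts == 1]
    else:
        singletons = np.zeros(0, dtype=np.uint64)

    unique_starts: dict[str, np.ndarray] = {}
    for name in assembly.names:
        canon, valid = per_seq[name]
        if canon.size == 0:
            unique_starts[name] = np.zeros(0, dtype=bool)
            continue
        unique_starts[name] = valid & np.isin(canon, singletons)
    return MappabilityTrack(n=n, unique_starts=unique_starts, lengths=dict(assembly.lengths))


_RC = str.maketrans("ACGT", "TGCA")


def _compute_mappability_strings(assembly: GenomeAssembly, n: int) -> MappabilityTrack:
    """Dictionary-based fallback for read lengths beyond the integer encoder."""
    from collections import Counter

    counts: Counter[str] = Counter()
    canon_per_seq: dict[str, list[str | None]] = {}
    for name in assembly.names:
        seq = assembly.sequences[name].upper()
        if len(seq) < n:
            warnings.warn(
                f"sequence {name!r} is shorter than n={n}; mappability set to 0",
                stacklevel=2,
            )
            canon_per_seq[name] = []
            continue
        rc = seq.translate(_RC)[::-1]
        length = len(seq)
        canons: list[str | None] = []
        for i in range(length - n + 1):
            kmer = seq[i : i + n]
            if any(b not in "ACGT" for b in kmer):
                canons.append(None)
                continue
            canon = min(kmer, rc[length - n - i : length - i])
            canons.append(canon)
            counts[canon] += 1
        canon_per_seq[name] = canons

    unique_starts = {
        name: np.array(
            [c is not None and counts[c] == 1 for c in canons], dtype=bool
        )
        for name, canons in canon_per_seq.items()
    }
    return MappabilityTrack(n=n, unique_starts=unique_starts, lengths=dict(assembly.lengths))


def filter_bins(
    bins: pd.DataFrame,
    min_mappability: float = 0.2,
    min_size: int | None = None,
    excluded_sequences: tuple[str, ...] = (),
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Drop bins below the mappability/size thresholds or on excluded sequences.

    Criteria are applied in order (excluded sequence, size, mappability) and
    the number of bins removed at each step is reported, so that
    input = retained + sum(removed).
    """
    if not 0 <= min_mappability <= 1:
        raise ValueError("min_mappability must be in [0, 1]")
    report: dict[str, int] = {"input": len(bins)}
    kept = bins
    removed = kept["chrom"].isin(excluded_sequences)
    report["removed_excluded_sequence"] = int(removed.sum())
    kept = kept[~removed]
    if min_size is not None:
        removed = (kept["end"] - kept["start"]) < min_size
        report["removed_min_size"] = int(removed.sum())
        kept = kept[~removed]
    else:
        report["removed_min_size"] = 0
    if "mappability" in kept.columns:
        removed = kept["mappability"] < min_mappability
        report["removed_low_mappability"] = int(removed.sum())
        kept = kept[~removed]
    elif min_mappability > 0:
        raise ValueError("bins carry no mappability column")
    report["retained"] = len(kept)
    return kept.reset_index(drop=True), report


_INTERVAL_RE = re.compile(r"^\s*(\S+?)\s*:\s*([\d,]+)\s*[-–]\s*([\d,]+)\s*$")


def parse_printed_interval(text: str) -> tuple[str, int, int]:
    """Convert a printed ``chrom: start-end`` interval to 0-based half-open.

    Printed compartment coordinates are breakpoints shared with the adjacent
    compartment: a printed start of 1 means position 0, while any other
    printed start is itself the 0-based boundary (it equals the printed end
    of the neighbouring interval). The printed end is exclusive after
    conversion. Example: ``chr2R: 1-6460000`` -> ``('chr2R', 0, 6460000)``.
    """
    m = _INTERVAL_RE.match(text)
    if not m:
        raise ValueError(f"cannot parse interval {text!r}")
    chrom = m.group(1)
    start = int(m.group(2).replace(",", ""))
    end = int(m.group(3).replace(",", ""))
    start0 = 0 if start == 1 else start
    if start0 >= end:
        raise ValueError(f"malformed interval {text!r}: start >= end")
    return chrom, start0, end


def assign_compartment(
    bins: pd.DataFrame,
    compartment_intervals: list[tuple[str, int, int, str]],
) -> pd.DataFrame:
    """Label each bin with the compartment containing its midpoint.

    ``compartment_intervals`` holds ``(chrom, start, end, label)`` tuples in
    0-based half-open coordinates, non-overlapping within each label. Bins
    whose midpoint falls in no interval get the label ``other``.
    """
    by_label: dict[str, list[tuple[str, int, int]]] = {}
    for chrom, start, end, label in compartment_intervals:
        if start >= end:
            raise ValueError(f"malformed interval {chrom}:{start}-{end}")
        by_label.setdefault(label, []).append((chrom, start, end))
    for label, ivs in by_label.items():
        seen: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in ivs:
            seen.setdefault(chrom, []).append((start, end))
        for chrom, spans in seen.items():
            spans.sort()
            for (s1, e1), (s2, _) in zip(spans, spans[1:]):
                if s2 < e1:
                    raise ValueError(f"overlapping {label} intervals on {chrom}")

    mids = (bins["start"].to_numpy() + bins["end"].to_numpy()) // 2
    labels = np.full(len(bins), "other", dtype=object)
    for chrom, start, end, label in compartment_intervals:
        mask = (bins["chrom"].to_numpy() == chrom) & (mids >= start) & (mids < end)
        labels[mask] = label
    out = bins.copy()
    out["compartment"] = labels
    return out
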