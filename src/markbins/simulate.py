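"""Synthetic cohort generator with known ground truth.

Emulates the statistical structure the bin-level analysis assumes, without
any real sequencing data: a toy genome with exact-repeat blocks (so
mappability drops below 1 there), a mitochondrion-like sequence for
exclusion testing and an unplaced scaffold; per-bin histone-mark states
(none / K9 only / K27 only / both); dual-strand piRNA clusters placed
preferentially in dual-marked bins and unistrand clusters in unmarked
chromatin; negative-binomial fragment counts per mark track and stranded
piRNA read counts whose means respond to the knockdown conditions
(control, EzKD, kipfKD, doubleKD, rhiKD) according to each bin's
dependency class.

Every random draw comes from a named substream derived from the master
seed, so a fixed seed reproduces the fixture byte for byte and adding a
track does not perturb existing ones.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .binning import tile_genome
from .classify import merge_intervals
from .config import PIRNA_CONDITIONS, SimulationConfig, save_config
from .genome import GenomeAssembly, write_chrom_sizes, write_fasta
from .io import write_bed, write_table
from .quantify import FragmentSet

MARKS = ("H3K9me3", "H3K27me3", "Rhi")
MARK_STATES = ("none", "K9only", "K27only", "both")
DEPENDENCY_CLASSES = ("none", "Rhi_only", "Ez_dep", "Kipf_dep", "both_dep", "gain_on_EzKD")

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _rng(seed: int, *names: str) -> np.random.Generator:
    """Named, order-independent RNG substream keyed on the master seed."""
    key = tuple(zlib.crc32(name.encode()) for name in names)
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with variance mu + dispersion * mu^2 (Poisson at 0)."""
    mean = np.asarray(mean, dtype=np.float64)
    if dispersion == 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def _mark_included(mark: str, mark_state: np.ndarray) -> np.ndarray:
    if mark == "H3K9me3":
        return np.isin(mark_state, ("K9only", "both"))
    if mark == "H3K27me3":
        return np.isin(mark_state, ("K27only", "both"))
    raise ValueError(f"unknown histone mark {mark!r}")


def simulate_genome(
    config: SimulationConfig,
) -> tuple[GenomeAssembly, pd.DataFrame, list[tuple[str, int, int, str]]]:
    """Toy genome plus per-bin truth table and compartment intervals.

    Main sequences are named chr1..chrN; a terminal mitochondrion-like
    sequence (``mito``) and an unplaced scaffold (``Scaffold_1``) are
    appended. Duplication blocks are pasted as exact repeats at
    non-overlapping positions so that downstream mappability is < 1 there.
    """
    config.validate()

    names = [f"chr{i + 1}" for i in range(config.n_sequences)]
    lengths = {name: config.sequence_length for name in names}
    sequences: dict[str, str] = {}
    for name in names:
        rng = _rng(config.seed, "genome", name)
        codes = rng.integers(0, 4, size=config.sequence_length)
        sequences[name] = _BASES[codes].tobytes().decode("ascii")

    # exact-repeat blocks: each block sequence is pasted at `copies`
    # non-overlapping positions sampled across the main sequences
    rng_dup = _rng(config.seed, "duplications")
    used: dict[str, list[tuple[int, int]]] = {name: [] for name in names}
    placements: list[tuple[int, str, int, int]] = []  # (block, chrom, start, length)
    for block_idx, (length, copies) in enumerate(config.duplication_blocks):
        block = _BASES[rng_dup.integers(0, 4, size=length)].tobytes().decode("ascii")
        placed = 0
        attempts = 0
        while placed < copies:
            attempts += 1
            if attempts > 10_000:
                raise ValueError(
                    f"cannot place duplication block {block_idx} of {length} bp: "
                    "sequences too crowded"
                )
            name = names[int(rng_dup.integers(0, len(names)))]
            start = int(rng_dup.integers(0, config.sequence_length - length + 1))
            if any(start < e and start + length > s for s, e in used[name]):
                continue
            used[name].append((start, start + length))
            placements.append((block_idx, name, start, length))
            seq = sequences[name]
            sequences[name] = seq[:start] + block + seq[start + length :]
            placed += 1

    scaffold = "Scaffold_1"
    for extra, extra_len in ((scaffold, config.scaffold_length), ("mito", config.mito_length)):
        rng = _rng(config.seed, "genome", extra)
        codes = rng.integers(0, 4, size=extra_len)
        sequences[extra] = _BASES[codes].tobytes().decode("ascii")
        lengths[extra] = extra_len
    names = names + [scaffold, "mito"]  # mito emitted last

    assembly = GenomeAssembly(names=names, lengths=lengths, sequences=sequences)

    compartments: list[tuple[str, int, int, str]] = []
    for name in names[: config.n_sequences]:
        split = int(
            round(config.heterochromatin_fraction * lengths[name] / config.bin_size)
        ) * config.bin_size
        compartments.append((name, 0, split, "heterochromatin"))
        compartments.append((name, split, lengths[name], "euchromatin"))

    truth = _build_truth(config, assembly, compartments)
    truth.attrs["duplication_placements"] = placements
    return assembly, truth, compartments


def _build_truth(
    config: SimulationConfig,
    assembly: GenomeAssembly,
    compartments: list[tuple[str, int, int, str]],
) -> pd.DataFrame:
    from .binning import assign_compartment

    bins = tile_genome(assembly, config.bin_size)
    bins = assign_compartment(bins, compartments)
    n = len(bins)
    rng = _rng(config.seed, "truth")

    main = ~bins["chrom"].isin(["mito", "Scaffold_1"]).to_numpy()
    scaffold = (bins["chrom"] == "Scaffold_1").to_numpy()

    p_none = 1.0 - config.p_k9_only - config.p_k27_only - config.p_both
    draw = rng.choice(
        MARK_STATES, size=n, p=[p_none, config.p_k9_only, config.p_k27_only, config.p_both]
    )
    mark_state = np.where(main, draw, "none").astype(object)
    # the unplaced scaffold carries a few dual-marked (hence occupied) bins
    # so that peak exclusion on contig name is exercised
    mark_state[scaffold & (rng.random(n) < 0.3)] = "both"

    u = rng.random(n)
    cluster = np.full(n, "none", dtype=object)
    cluster[main & (mark_state == "both") & (u < config.p_dual_given_both)] = "dual_strand"
    cluster[main & (mark_state == "K9only") & (u < config.p_dual_given_k9)] = "dual_strand"
    cluster[main & (mark_state == "none") & (u < config.p_uni_given_none)] = "unistrand"

    dependency = np.full(n, "none", dtype=object)
    dual = cluster == "dual_strand"
    in_k9 = dual & (mark_state == "K9only")
    dependency[in_k9] = "Kipf_dep"  # Kipferl recruits the reader to K9-only loci
    in_both = np.flatnonzero(dual & (mark_state == "both"))
    dependency[in_both] = rng.choice(
        ["Ez_dep", "both_dep", "Rhi_only", "gain_on_EzKD"],
        size=in_both.size,
        p=[0.5, 0.2, 0.15, 0.15],
    )

    uni_strand = np.full(n, ".", dtype=object)
    uni = cluster == "unistrand"
    uni_strand[uni] = rng.choice(["+", "-"], size=int(uni.sum()))

    bound_p = np.select(
        [mark_state == "both", mark_state == "K9only", mark_state == "K27only"],
        [config.p_bound_given_both, config.p_bound_given_k9, config.p_bound_given_k27],
        default=config.p_bound_given_none,
    )
    rhi_bound = (rng.random(n) < bound_p) | dual
    rhi_bound &= bins["chrom"].to_numpy() != "mito"

    artifact = rhi_bound & ~dual & (rng.random(n) < 0.03)

    kipf_independent = np.where(
        dual,
        ~np.isin(dependency, ("Kipf_dep", "both_dep")),
        mark_state == "both",
    ) & rhi_bound

    has_k27 = np.isin(mark_state, ("K27only", "both"))
    k27_mult = np.ones(n, dtype=np.float64)
    k27_mult[has_k27] = np.power(2.0, rng.uniform(-3.0, 0.5, size=int(has_k27.sum())))
    rhi_mult = np.ones(n, dtype=np.float64)
    responsive = rhi_bound & kipf_independent & has_k27
    rhi_mult[responsive] = k27_mult[responsive]

    truth = bins.copy()
    truth["mark_state"] = mark_state
    truth["cluster_label"] = cluster
    truth["dependency_class"] = dependency
    truth["uni_strand"] = uni_strand
    truth["rhi_bound"] = rhi_bound
    truth["rhi_artifact"] = artifact
    truth["kipf_independent_site"] = kipf_independent
    truth["k27_ezkd_multiplier"] = k27_mult
    truth["rhi_ezkd_multiplier"] = rhi_mult
    return truth


def _place_fragments(
    rng: np.random.Generator,
    truth: pd.DataFrame,
    counts: np.ndarray,
    length: int,
    strand: str,
) -> pd.DataFrame:
    """Uniform fragment placement fully inside each bin (no boundary straddle)."""
    chroms: list[np.ndarray] = []
    starts: list[np.ndarray] = []
    flens: list[np.ndarray] = []
    bstart = truth["start"].to_numpy()
    bend = truth["end"].to_numpy()
    bchrom = truth["chrom"].to_numpy()
    for i in np.flatnonzero(counts):
        c = int(counts[i])
        fl = min(length, bend[i] - bstart[i])
        hi = bend[i] - fl
        pos = rng.integers(bstart[i], hi + 1, size=c)
        chroms.append(np.repeat(bchrom[i], c))
        starts.append(pos)
        flens.append(np.repeat(fl, c))
    if not chroms:
        return pd.DataFrame(columns=["chrom", "start", "end", "name", "score", "strand"])
    chrom_all = np.concatenate(chroms)
    start_all = np.concatenate(starts)
    flen_all = np.concatenate(flens)
    frame = pd.DataFrame(
        {
            "chrom": chrom_all,
            "start": start_all,
            "end": start_all + flen_all,
            "name": ".",
            "score": 0,
            "strand": strand,
        }
    )
    return frame


def simulate_mark_fragments(
    truth: pd.DataFrame,
    config: SimulationConfig,
    mark: str,
    condition: str = "control",
) -> tuple[list[FragmentSet], np.ndarray]:
    """Fragment sets for one occupancy track, one per replicate.

    Counts per bin are negative binomial around the background mean, times
    the enrichment fold where the bin carries the mark (for the reader
    protein track ``Rhi``: where the bin is occupied). Under ``EzKD``, bins
    respond according to their per-bin multipliers in the truth table.
    Returns (fragment sets, drawn counts as bins x replicates).
    """
    config.validate()
    if mark == "Rhi":
        marked = truth["rhi_bound"].to_numpy(dtype=bool)
        modifier = truth["rhi_ezkd_multiplier"].to_numpy()
    else:
        marked = _mark_included(mark, truth["mark_state"].to_numpy())
        modifier = (
            truth["k27_ezkd_multiplier"].to_numpy()
            if mark == "H3K27me3"
            else np.ones(len(truth))
        )
    mean = np.where(
        marked,
        config.mark_background_mean * config.enrichment_fold,
        config.mark_background_mean,
    ).astype(np.float64)
    if condition == "EzKD":
        mean = np.where(marked, mean * modifier, mean)
    elif condition != "control":
        raise ValueError(f"unsupported condition for mark tracks: {condition!r}")

    sets: list[FragmentSet] = []
    all_counts = np.zeros((len(truth), config.n_replicates), dtype=np.int64)
    for rep in range(config.n_replicates):
        rng = _rng(config.seed, "mark", mark, condition, f"rep{rep}")
        counts = _nb_draw(rng, mean, config.nb_dispersion)
        all_counts[:, rep] = counts
        frame = _place_fragments(rng, truth, counts, config.fragment_length, ".")
        sets.append(
            FragmentSet(sample=mark, condition=condition, replicate=rep, intervals=frame)
        )
    return sets, all_counts


def simulate_background_fragments(
    truth: pd.DataFrame, config: SimulationConfig
) -> FragmentSet:
    """IgG-like track: background-mean counts everywhere, one library."""
    rng = _rng(config.seed, "mark", "IgG", "control", "rep0")
    mean = np.full(len(truth), config.mark_background_mean, dtype=np.float64)
    counts = _nb_draw(rng, mean, config.nb_dispersion)
    frame = _place_fragments(rng, truth, counts, config.fragment_length, ".")
    return FragmentSet(sample="IgG", condition="control", replicate=0, intervals=frame)


def pirna_strand_means(
    truth: pd.DataFrame, config: SimulationConfig, condition: str
) -> dict[str, np.ndarray]:
    """Expected piRNA reads per bin and strand under one knockdown condition.

    Dual-strand cluster bins emit on both strands; their output is divided
    by the knockdown fold when a condition removes a factor they depend on
    (rhiKD hits every dual-strand bin; doubleKD applies the EzKD and kipfKD
    rules cumulatively) and multiplied by the gain fold for the
    anticorrelated class under EzKD. Unistrand bins emit on one strand and
    ignore all conditions; all other bins emit low-level background reads.
    """
    if condition not in PIRNA_CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}; expected one of {PIRNA_CONDITIONS}")
    n = len(truth)
    cluster = truth["cluster_label"].to_numpy()
    dep = truth["dependency_class"].to_numpy()
    uni_strand = truth["uni_strand"].to_numpy()

    dual = cluster == "dual_strand"
    factor = np.ones(n, dtype=np.float64)
    if condition in ("EzKD", "doubleKD"):
        factor[np.isin(dep, ("Ez_dep", "both_dep"))] /= config.knockdown_fold
        factor[dep == "gain_on_EzKD"] *= config.gain_fold
    if condition in ("kipfKD", "doubleKD"):
        factor[np.isin(dep, ("Kipf_dep", "both_dep"))] /= config.knockdown_fold
    if condition == "rhiKD":
        factor[dual] = 1.0 / config.knockdown_fold

    means = {}
    for strand in "+-":
        mean = np.zeros(n, dtype=np.float64)
        mean[dual] = config.pirna_mean * factor[dual]
        uni_here = (cluster == "unistrand") & (uni_strand == strand)
        mean[uni_here] = config.pirna_mean
        background = cluster == "none"
        mean[background] = config.pirna_background_mean
        means[strand] = mean
    return means


def simulate_pirna_reads(
    truth: pd.DataFrame, config: SimulationConfig, condition: str
) -> tuple[list[FragmentSet], dict[str, np.ndarray]]:
    """Stranded piRNA read sets per replicate for one knockdown condition.

    Returns (fragment sets, drawn counts per strand as bins x replicates).
    """
    config.validate()
    means = pirna_strand_means(truth, config, condition)
    sets: list[FragmentSet] = []
    drawn = {
        strand: np.zeros((len(truth), config.n_replicates), dtype=np.int64)
        for strand in "+-"
    }
    for rep in range(config.n_replicates):
        frames = []
        for strand in "+-":
            rng = _rng(config.seed, "pirna", condition, strand, f"rep{rep}")
            counts = _nb_draw(rng, means[strand], config.nb_dispersion)
            drawn[strand][:, rep] = counts
            frames.append(
                _place_fragments(rng, truth, counts, config.pirna_read_length, strand)
            )
        frame = pd.concat(frames, ignore_index=True)
        sets.append(
            FragmentSet(sample="piRNA", condition=condition, replicate=rep, intervals=frame)
        )
    return sets, drawn


def _peak_frame(truth: pd.DataFrame, mask: np.ndarray, fold: float) -> pd.DataFrame:
    """Merged runs of flagged bins as a peak table with fold and q-value."""
    flagged = truth.loc[mask, ["chrom", "start", "end"]]
    if flagged.empty:
        return pd.DataFrame(columns=["chrom", "start", "end", "name", "score", "strand",
                                     "fold_enrichment", "q_value"])
    # adjacent flagged bins form one peak
    runs: list[tuple[str, int, int]] = []
    cur = None
    for chrom, start, end in zip(flagged["chrom"], flagged["start"], flagged["end"]):
        if cur is not None and chrom == cur[0] and start == cur[2]:
            cur = (chrom, cur[1], end)
        else:
            if cur is not None:
                runs.append(cur)
            cur = (chrom, int(start), int(end))
    runs.append(cur)
    out = pd.DataFrame(runs, columns=["chrom", "start", "end"])
    out["name"] = [f"peak_{i}" for i in range(len(out))]
    out["score"] = 0
    out["strand"] = "."
    out["fold_enrichment"] = fold
    out["q_value"] = 1e-6
    return out


def simulate_peaks(
    truth: pd.DataFrame, config: SimulationConfig
) -> dict[tuple[str, str], list[pd.DataFrame]]:
    """Noise-free peak calls per (track, condition) and replicate.

    Peaks cover exactly the truly marked (or occupied) bins; replicates are
    identical by construction, so the consensus step retains them all. The
    reader-protein track also yields condition-specific sets: artifact peaks
    persist in the Rhino knockdown, and Kipferl-independent sites persist in
    the Kipferl knockdown.
    """
    state = truth["mark_state"].to_numpy()
    rhi_bound = truth["rhi_bound"].to_numpy(dtype=bool)
    artifact = truth["rhi_artifact"].to_numpy(dtype=bool)
    kipf_indep = truth["kipf_independent_site"].to_numpy(dtype=bool)
    masks = {
        ("H3K9me3", "control"): _mark_included("H3K9me3", state),
        ("H3K27me3", "control"): _mark_included("H3K27me3", state),
        ("Rhi", "control"): rhi_bound,
        ("Rhi", "rhiKD"): artifact,
        ("Rhi", "kipfKD"): rhi_bound & (kipf_indep | artifact),
    }
    peaks: dict[tuple[str, str], list[pd.DataFrame]] = {}
    for key, mask in masks.items():
        frame = _peak_frame(truth, mask, config.enrichment_fold)
        peaks[key] = [frame.copy() for _ in range(config.n_replicates)]
    return peaks


@dataclass
class Cohort:
    """Everything one simulated study produces, plus the drawn ground truth."""

    config: SimulationConfig
    assembly: GenomeAssembly
    truth: pd.DataFrame
    compartments: list[tuple[str, int, int, str]]
    mark_fragments: dict[tuple[str, str], list[FragmentSet]]
    mark_counts: dict[tuple[str, str], np.ndarray]
    background: FragmentSet
    pirna_fragments: dict[str, list[FragmentSet]]
    pirna_counts: dict[str, dict[str, np.ndarray]]
    peaks: dict[tuple[str, str], list[pd.DataFrame]]


MARK_TRACKS = (
    ("H3K9me3", "control"),
    ("H3K27me3", "control"),
    ("H3K27me3", "EzKD"),
    ("Rhi", "control"),
    ("Rhi", "EzKD"),
)


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """Run the full generator: genome, truth, fragments, peaks."""
    assembly, truth, compartments = simulate_genome(config)
    mark_fragments = {}
    mark_counts = {}
    for mark, condition in MARK_TRACKS:
        sets, counts = simulate_mark_fragments(truth, config, mark, condition)
        mark_fragments[(mark, condition)] = sets
        mark_counts[(mark, condition)] = counts
    background = simulate_background_fragments(truth, config)
    pirna_fragments = {}
    pirna_counts = {}
    for condition in PIRNA_CONDITIONS:
        sets, drawn = simulate_pirna_reads(truth, config, condition)
        pirna_fragments[condition] = sets
        pirna_counts[condition] = drawn
    peaks = simulate_peaks(truth, config)
    return Cohort(
        config=config,
        assembly=assembly,
        truth=truth,
        compartments=compartments,
        mark_fragments=mark_fragments,
        mark_counts=mark_counts,
        background=background,
        pirna_fragments=pirna_fragments,
        pirna_counts=pirna_counts,
        peaks=peaks,
    )


def cluster_annotation(truth: pd.DataFrame) -> pd.DataFrame:
    """Merged cluster intervals (dual_strand and unistrand) as a BED table."""
    frames = []
    for label in ("dual_strand", "unistrand"):
        sel = truth.loc[truth["cluster_label"] == label, ["chrom", "start", "end"]]
        if sel.empty:
            continue
        merged = merge_intervals(sel)
        # adjacent bins do not overlap, so merge touching runs explicitly
        merged = _coalesce_touching(merged)
        merged["name"] = label
        frames.append(merged)
    if not frames:
        return pd.DataFrame(columns=["chrom", "start", "end", "name"])
    return pd.concat(frames, ignore_index=True)


def _coalesce_touching(intervals: pd.DataFrame) -> pd.DataFrame:
    rows: list[tuple[str, int, int]] = []
    cur = None
    ordered = intervals.sort_values(["chrom", "start"], kind="stable")
    for chrom, start, end in zip(ordered["chrom"], ordered["start"], ordered["end"]):
        if cur is not None and chrom == cur[0] and start <= cur[2]:
            cur = (chrom, cur[1], max(cur[2], end))
        else:
            if cur is not None:
                rows.append(cur)
            cur = (chrom, int(start), int(end))
    if cur is not None:
        rows.append(cur)
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def write_fixture(cohort: Cohort, outdir: str | Path) -> Path:
    """Serialize a cohort to plain-text files readable by the pipeline.

    Layout: genome.fa, genome.chrom.sizes, config.yaml, truth.tsv,
    compartments.bed, clusters.bed, marks/ and pirna/ BED6 fragment files,
    peaks/ BED6+2 peak files. Re-reading the fragment files reproduces the
    drawn counts exactly (fragments never straddle bin boundaries).
    """
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "marks").mkdir(exist_ok=True)
        (outdir / "pirna").mkdir(exist_ok=True)
        (outdir / "peaks").mkdir(exist_ok=True)
    except OSError as err:
        raise ValueError(f"cannot create fixture directory {outdir}: {err}") from err

    write_fasta(cohort.assembly, outdir / "genome.fa")
    write_chrom_sizes(cohort.assembly, outdir / "genome.chrom.sizes")
    save_config(cohort.config, outdir / "config.yaml")
    write_table(cohort.truth, outdir / "truth.tsv")

    comp = pd.DataFrame(cohort.compartments, columns=["chrom", "start", "end", "name"])
    write_bed(comp, outdir / "compartments.bed", ["chrom", "start", "end", "name"])
    write_bed(
        cluster_annotation(cohort.truth),
        outdir / "clusters.bed",
        ["chrom", "start", "end", "name"],
    )

    for (mark, condition), sets in cohort.mark_fragments.items():
        for frag in sets:
            write_bed(frag.intervals, outdir / "marks" / f"{mark}_{condition}_rep{frag.replicate}.bed")
    write_bed(cohort.background.intervals, outdir / "marks" / "IgG_control_rep0.bed")
    for condition, sets in cohort.pirna_fragments.items():
        for frag in sets:
            write_bed(frag.intervals, outdir / "pirna" / f"{condition}_rep{frag.replicate}.bed")
    for (mark, condition), replicates in cohort.peaks.items():
        for rep, frame in enumerate(replicates):
            write_bed(frame, outdir / "peaks" / f"{mark}_{condition}_rep{rep}.bed")
    return outdir
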