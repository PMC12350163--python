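"""Configuration objects: simulation settings and analysis thresholds.

Every threshold the pipeline applies lives in :class:`AnalysisConfig`, whose
defaults are the published constants of the bin-level analysis (20%
mappability floor, half-length counting rule, 2-/4-fold dependency
thresholds, 3-fold high-confidence peaks, 2-replicate consensus support,
15 level breakpoints, 6 delta groups, 90th percentile restriction, caps of
300/200 for the log-scale displays). Unknown keys in a config file are
rejected outright.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

#: Euchromatin/heterochromatin compartments of the D. melanogaster dm6
#: assembly (Fabry et al. coordinates), converted to 0-based half-open with
#: shared breakpoints between adjacent compartments.
DM6_COMPARTMENTS: list[tuple[str, int, int, str]] = [
    ("chr2R", 6_460_000, 25_286_936, "euchromatin"),
    ("chr2L", 0, 22_160_000, "euchromatin"),
    ("chr3L", 0, 23_030_000, "euchromatin"),
    ("chr3R", 4_200_000, 32_079_331, "euchromatin"),
    ("chrX", 250_000, 21_500_000, "euchromatin"),
    ("chr2R", 0, 6_460_000, "heterochromatin"),
    ("chr2L", 22_160_000, 23_513_712, "heterochromatin"),
    ("chr3L", 23_030_000, 28_110_227, "heterochromatin"),
    ("chr3R", 0, 4_200_000, "heterochromatin"),
]

PIRNA_CONDITIONS = ("control", "EzKD", "kipfKD", "doubleKD", "rhiKD")


@dataclass
class SimulationConfig:
    """Settings for the synthetic cohort generator.

    The defaults are the study conditions the downstream analysis assumes:
    1 kb bins, negative-binomial counts with dispersion 0.1, a mean of 80
    piRNA reads per strand in an expressing bin, an 8-fold knockdown loss
    for dependent bins and a 2-fold gain for the anticorrelated class, and
    two replicates per track.
    """

    seed: int = 0
    n_sequences: int = 5
    sequence_length: int = 600_000
    bin_size: int = 1_000
    duplication_blocks: list[tuple[int, int]] = field(default_factory=lambda: [(2_000, 3)])
    mark_background_mean: float = 20.0
    enrichment_fold: float = 6.0
    nb_dispersion: float = 0.1
    n_replicates: int = 2
    pirna_mean: float = 80.0
    pirna_background_mean: float = 15.0
    knockdown_fold: float = 8.0
    gain_fold: float = 2.0
    fragment_length: int = 300
    pirna_read_length: int = 26
    mito_length: int = 15_000
    scaffold_length: int = 10_000
    mappability_read_length: int = 25
    # marginal probabilities of the per-bin mark state
    p_k9_only: float = 0.13
    p_k27_only: float = 0.12
    p_both: float = 0.05
    # cluster placement: dual-strand clusters preferentially occupy
    # dual-marked bins; unistrand clusters sit in unmarked chromatin
    p_dual_given_both: float = 0.6
    p_dual_given_k9: float = 0.06
    p_uni_given_none: float = 0.015
    # occupancy of the reader protein by mark state
    p_bound_given_both: float = 0.9
    p_bound_given_k9: float = 0.5
    p_bound_given_k27: float = 0.05
    p_bound_given_none: float = 0.02
    heterochromatin_fraction: float = 0.35

    def validate(self) -> None:
        if self.n_sequences < 1 or self.sequence_length < 1:
            raise ValueError("need at least one sequence of positive length")
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        for mean in (
            self.mark_background_mean,
            self.pirna_mean,
            self.pirna_background_mean,
        ):
            if mean <= 0:
                raise ValueError("all means must be positive")
        if self.enrichment_fold <= 1:
            raise ValueError("enrichment_fold must exceed 1")
        if self.knockdown_fold <= 1:
            raise ValueError("knockdown_fold must exceed 1")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be non-negative")
        if self.fragment_length <= 0 or self.fragment_length > self.bin_size:
            raise ValueError("fragment_length must be in (0, bin_size]")
        for length, copies in self.duplication_blocks:
            if length > self.sequence_length:
                raise ValueError(
                    f"duplication block of {length} bp exceeds the sequence "
                    f"length {self.sequence_length}"
                )
            if copies < 2:
                raise ValueError("a duplication block needs at least two copies")
        total = self.p_k9_only + self.p_k27_only + self.p_both
        if not 0 < total < 1:
            raise ValueError("mark-state probabilities must leave room for unmarked bins")


@dataclass
class AnalysisConfig:
    """All thresholds of the analysis pipeline, echoed into every result file."""

    bin_size: int = 1_000
    window: int = 10_000
    step: int = 5_000
    min_window_size: int = 5_000
    mappability_read_length: int = 100
    min_mappability: float = 0.2
    min_overlap_fraction: float = 0.5
    subtraction_window: int = 50
    ses_lowest_fraction: float = 0.5
    log2fc_pseudocount: float = 0.01
    cap_log10_pseudocount: float = 1.0
    cap_1kb: float = 300.0
    cap_10kb: float = 200.0
    rhi_threshold_fold: float = 2.0
    ez_kipf_threshold_fold: float = 4.0
    peak_min_fold: float = 3.0
    consensus_min_support: int = 2
    n_level_breakpoints: int = 15
    n_delta_groups: int = 6
    secondary_mark_percentile: float = 90.0
    excluded_sequences: list[str] = field(default_factory=lambda: ["mito"])
    unplaced_pattern: str = r"Scaffold|rand|^(?!chr)"
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.min_overlap_fraction <= 1:
            raise ValueError("min_overlap_fraction must be in (0, 1]")
        if not 0 <= self.min_mappability <= 1:
            raise ValueError("min_mappability must be in [0, 1]")
        if self.step <= 0 or self.step > self.window:
            raise ValueError("require 0 < step <= window")
        if self.rhi_threshold_fold <= 1 or self.ez_kipf_threshold_fold <= 1:
            raise ValueError("dependency thresholds must exceed 1")
        if not 0 <= self.secondary_mark_percentile <= 100:
            raise ValueError("secondary_mark_percentile must be a percentile")
        if self.n_level_breakpoints < 2 or self.n_delta_groups < 1:
            raise ValueError("grouping parameters out of range")


def _load_into(cls, path: str | Path):
    with open(path) as handle:
        raw = yaml.safe_load(handle) or {}
    known = {f for f in cls.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
    if "duplication_blocks" in raw and raw["duplication_blocks"] is not None:
        raw["duplication_blocks"] = [tuple(b) for b in raw["duplication_blocks"]]
    obj = cls(**raw)
    obj.validate()
    return obj


def load_simulation_config(path: str | Path) -> SimulationConfig:
    return _load_into(SimulationConfig, path)


def load_analysis_config(path: str | Path) -> AnalysisConfig:
    return _load_into(AnalysisConfig, path)


def save_config(config, path: str | Path) -> None:
    data = asdict(config)
    if "duplication_blocks" in data:
        data["duplication_blocks"] = [list(b) for b in data["duplication_blocks"]]
    with open(path, "w") as handle:
        yaml.safe_dump(data, handle, sort_keys=True, default_flow_style=False)
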