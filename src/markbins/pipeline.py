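"""End-to-end orchestration: fixture -> bins -> signal -> classification -> dependency.

Each stage is a plain function over in-memory tables so it can be tested in
isolation; :func:`run_pipeline` chains them, writes every result as TSV/JSON
and records a manifest with the configuration snapshot, input checksums and
per-stage row counts. Re-running on the same inputs and configuration
reproduces identical result bytes.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .binning import assign_compartment, compute_mappability, filter_bins, tile_genome
from .classify import (
    GroupAssignment,
    OverlapTable,
    ROCResult,
    bin_presence,
    combine_marks,
    consensus_peaks,
    group_by_level,
    overlap_enrichment,
    roc_auc,
    venn_partition,
)
from .config import AnalysisConfig, PIRNA_CONDITIONS, load_simulation_config
from .dependency import (
    classify_ez_kipf,
    classify_peaks_kipf,
    classify_rhi_dependent,
    delta_group_analysis,
    fold_loss,
)
from .genome import read_fasta
from .io import read_bed, write_table
from .quantify import (
    FragmentSet,
    count_fragments,
    min_strand,
    normalize_cpm,
    normalize_fpkm,
    subtract_background,
    window_mean_per_bin,
)

MARK_TRACK_FILES = (
    ("H3K9me3", "control"),
    ("H3K27me3", "control"),
    ("H3K27me3", "EzKD"),
    ("Rhi", "control"),
    ("Rhi", "EzKD"),
)


@dataclass
class Fixture:
    """Paths and parsed inputs of one analysis run."""

    root: Path
    assembly: object
    compartments: list[tuple[str, int, int, str]]
    clusters: pd.DataFrame
    sim_config: object | None = None

    @classmethod
    def load(cls, fixture_dir: str | Path) -> "Fixture":
        root = Path(fixture_dir)
        fasta = root / "genome.fa"
        if not fasta.exists():
            raise FileNotFoundError(f"missing input: {fasta}")
        assembly = read_fasta(fasta)
        comp_bed = read_bed(root / "compartments.bed")
        compartments = [
            (row.chrom, int(row.start), int(row.end), row.name_label)
            for row in comp_bed.rename(columns={"name": "name_label"}).itertuples()
        ]
        clusters = read_bed(root / "clusters.bed")
        sim_config = None
        cfg_path = root / "config.yaml"
        if cfg_path.exists():
            sim_config = load_simulation_config(cfg_path)
        return cls(
            root=root,
            assembly=assembly,
            compartments=compartments,
            clusters=clusters,
            sim_config=sim_config,
        )

    def fragment_set(self, relpath: str, sample: str, condition: str, replicate: int) -> FragmentSet:
        path = self.root / relpath
        if not path.exists():
            raise FileNotFoundError(f"missing input: {path}")
        return FragmentSet(
            sample=sample,
            condition=condition,
            replicate=replicate,
            intervals=read_bed(path),
        )

    def peak_replicates(self, mark: str, condition: str, n_replicates: int) -> list[pd.DataFrame]:
        return [
            read_bed(self.root / "peaks" / f"{mark}_{condition}_rep{r}.bed")
            for r in range(n_replicates)
        ]


def stage_bins(fixture: Fixture, config: AnalysisConfig) -> tuple[pd.DataFrame, dict]:
    """Tile, attach mappability, filter, and label compartments."""
    bins = tile_genome(fixture.assembly, config.bin_size)
    track = compute_mappability(fixture.assembly, config.mappability_read_length)
    bins["mappability"] = track.bin_values(bins)
    kept, report = filter_bins(
        bins,
        min_mappability=config.min_mappability,
        excluded_sequences=tuple(config.excluded_sequences),
    )
    kept = assign_compartment(kept, fixture.compartments)
    return kept, report


@dataclass
class QuantResult:
    mark_enrichment: pd.DataFrame  # bins x track columns "mark:condition"
    pirna_cpm: dict[str, dict[str, pd.DataFrame]]  # condition -> strand -> bins x reps
    pirna_fpkm_mean: dict[str, dict[str, np.ndarray]]  # condition -> strand -> per-bin mean
    library_sizes: dict[str, list[int]]


def stage_quantify(
    fixture: Fixture, bins: pd.DataFrame, config: AnalysisConfig, n_replicates: int
) -> QuantResult:
    """Window-level background subtraction for marks; stranded cpm/FPKM for piRNAs."""
    windows = tile_genome(fixture.assembly, config.subtraction_window)
    igg = fixture.fragment_set("marks/IgG_control_rep0.bed", "IgG", "control", 0)
    igg_win, _ = count_fragments(windows, igg, min_overlap_fraction=None)

    enrichment = pd.DataFrame(index=bins["bin_id"])
    for mark, condition in MARK_TRACK_FILES:
        per_rep = []
        for rep in range(n_replicates):
            frags = fixture.fragment_set(
                f"marks/{mark}_{condition}_rep{rep}.bed", mark, condition, rep
            )
            win_counts, _ = count_fragments(windows, frags, min_overlap_fraction=None)
            sub = subtract_background(
                win_counts.astype(float),
                igg_win.astype(float),
                lowest_fraction=config.ses_lowest_fraction,
            )
            per_rep.append(window_mean_per_bin(windows, sub, bins))
        enrichment[f"{mark}:{condition}"] = np.mean(per_rep, axis=0)

    lengths = (bins["end"] - bins["start"]).to_numpy()
    mapp = bins["mappability"].to_numpy()
    pirna_cpm: dict[str, dict[str, pd.DataFrame]] = {}
    pirna_fpkm_mean: dict[str, dict[str, np.ndarray]] = {}
    library_sizes: dict[str, list[int]] = {}
    for condition in PIRNA_CONDITIONS:
        cpm_by_strand = {s: {} for s in "+-"}
        fpkm_by_strand = {s: [] for s in "+-"}
        library_sizes[condition] = []
        for rep in range(n_replicates):
            frags = fixture.fragment_set(
                f"pirna/{condition}_rep{rep}.bed", "piRNA", condition, rep
            )
            lib = frags.library_size
            library_sizes[condition].append(lib)
            for strand in "+-":
                counts, _ = count_fragments(
                    bins, frags, min_overlap_fraction=config.min_overlap_fraction,
                    strand=strand,
                )
                cpm_by_strand[strand][f"rep{rep}"] = normalize_cpm(counts, lib)
                fpkm_by_strand[strand].append(normalize_fpkm(counts, lengths, mapp, lib))
        pirna_cpm[condition] = {
            s: pd.DataFrame(cpm_by_strand[s], index=bins["bin_id"]) for s in "+-"
        }
        pirna_fpkm_mean[condition] = {
            s: np.mean(fpkm_by_strand[s], axis=0) for s in "+-"
        }
    return QuantResult(
        mark_enrichment=enrichment,
        pirna_cpm=pirna_cpm,
        pirna_fpkm_mean=pirna_fpkm_mean,
        library_sizes=library_sizes,
    )


@dataclass
class ClassifyResult:
    auc_table: pd.DataFrame  # target region x predictor
    roc_curves: dict[tuple[str, str], ROCResult]
    presence: pd.DataFrame  # bins x track booleans
    or_tables: dict[str, OverlapTable]
    venn_counts: dict[tuple[str, ...], int]
    groups: GroupAssignment
    group_table: pd.DataFrame


def stage_classify(
    fixture: Fixture,
    bins: pd.DataFrame,
    quant: QuantResult,
    config: AnalysisConfig,
    n_replicates: int,
) -> ClassifyResult:
    """ROC/AUC of mark signal against cluster bins; peak presence, OR and groups."""
    targets = {}
    for label in ("dual_strand", "unistrand"):
        ivs = fixture.clusters[fixture.clusters["name"] == label]
        targets[label] = bin_presence(bins, ivs)

    k9 = quant.mark_enrichment["H3K9me3:control"].to_numpy()
    k27 = quant.mark_enrichment["H3K27me3:control"].to_numpy()
    predictors = {
        "H3K9me3": k9,
        "H3K27me3": k27,
        "combined_mean": combine_marks(k9, k27),
    }
    roc_curves: dict[tuple[str, str], ROCResult] = {}
    auc = pd.DataFrame(index=list(targets), columns=list(predictors), dtype=float)
    for tname, labels in targets.items():
        for pname, scores in predictors.items():
            result = roc_auc(scores, labels)
            roc_curves[(tname, pname)] = result
            auc.loc[tname, pname] = result.auc

    presence = pd.DataFrame(index=bins["bin_id"])
    for mark in ("Rhi", "H3K9me3", "H3K27me3"):
        reps = fixture.peak_replicates(mark, "control", n_replicates)
        consensus = consensus_peaks(reps, min_support=config.consensus_min_support)
        presence[mark] = bin_presence(bins, consensus)

    strata = np.select(
        [
            presence["H3K9me3"].to_numpy() & presence["H3K27me3"].to_numpy(),
            presence["H3K9me3"].to_numpy() & ~presence["H3K27me3"].to_numpy(),
            ~presence["H3K9me3"].to_numpy() & presence["H3K27me3"].to_numpy(),
        ],
        ["both", "K9only", "K27only"],
        default="neither",
    )
    or_tables = overlap_enrichment(
        presence["Rhi"].to_numpy(), presence["H3K9me3"].to_numpy(), strata=strata
    )
    venn_counts = venn_partition(
        {mark: presence[mark].to_numpy() for mark in ("Rhi", "H3K9me3", "H3K27me3")}
    )

    fwd = quant.pirna_fpkm_mean["control"]["+"]
    rev = quant.pirna_fpkm_mean["control"]["-"]
    level = min_strand(fwd, rev)
    groups = group_by_level(level, n_breakpoints=config.n_level_breakpoints)
    group_table = pd.DataFrame(
        {"bin_id": bins["bin_id"], "level": level, "group": groups.group}
    )
    return ClassifyResult(
        auc_table=auc,
        roc_curves=roc_curves,
        presence=presence,
        or_tables=or_tables,
        venn_counts=venn_counts,
        groups=groups,
        group_table=group_table,
    )


@dataclass
class DependencyResult:
    rhi_table: pd.DataFrame
    dependency_table: pd.DataFrame
    peak_result: object
    delta_groups: pd.Series
    delta_summary: pd.DataFrame


def _condition_cpm_total(quant: QuantResult, condition: str) -> np.ndarray:
    """Per-bin cpm summed over strands, as a bins x replicates matrix."""
    plus = quant.pirna_cpm[condition]["+"].to_numpy()
    minus = quant.pirna_cpm[condition]["-"].to_numpy()
    return plus + minus


def stage_dependency(
    fixture: Fixture,
    bins: pd.DataFrame,
    quant: QuantResult,
    config: AnalysisConfig,
    n_replicates: int,
) -> DependencyResult:
    """Knockdown dependency of bins and peaks plus the delta-group analysis."""
    control = _condition_cpm_total(quant, "control")
    rhi_table = classify_rhi_dependent(
        {"rhiKD": (control, _condition_cpm_total(quant, "rhiKD"))},
        threshold_fold=config.rhi_threshold_fold,
        pseudocount=config.log2fc_pseudocount,
    )
    rhi_table.index = bins["bin_id"]

    losses = {
        cond: fold_loss(
            control,
            _condition_cpm_total(quant, cond),
            pseudocount=config.log2fc_pseudocount,
        )
        for cond in ("EzKD", "kipfKD")
    }
    dependency_table = classify_ez_kipf(
        rhi_table["rhi_dependent"].to_numpy(),
        losses,
        threshold_fold=config.ez_kipf_threshold_fold,
    )
    dependency_table.index = bins["bin_id"]
    dependency_table["compartment"] = bins["compartment"].to_numpy()

    control_peaks = fixture.peak_replicates("Rhi", "control", n_replicates)
    rhikd_peaks = pd.concat(
        fixture.peak_replicates("Rhi", "rhiKD", n_replicates), ignore_index=True
    )
    kipfkd_peaks = pd.concat(
        fixture.peak_replicates("Rhi", "kipfKD", n_replicates), ignore_index=True
    )
    peak_result = classify_peaks_kipf(
        control_peaks,
        rhikd_peaks,
        kipfkd_peaks,
        min_fold=config.peak_min_fold,
        unplaced_pattern=config.unplaced_pattern,
    )

    delta = (
        quant.mark_enrichment["H3K27me3:EzKD"] - quant.mark_enrichment["H3K27me3:control"]
    ).to_numpy()
    responder = (
        quant.mark_enrichment["Rhi:EzKD"] - quant.mark_enrichment["Rhi:control"]
    ).to_numpy()
    delta_groups, delta_summary = delta_group_analysis(
        bins,
        delta,
        {"Rhi": responder},
        n_groups=config.n_delta_groups,
        secondary=quant.mark_enrichment["H3K9me3:control"].to_numpy(),
        secondary_percentile=config.secondary_mark_percentile,
    )
    return DependencyResult(
        rhi_table=rhi_table,
        dependency_table=dependency_table,
        peak_result=peak_result,
        delta_groups=delta_groups,
        delta_summary=delta_summary,
    )


@dataclass
class PipelineResult:
    bins: pd.DataFrame
    filter_report: dict
    quant: QuantResult
    classify: ClassifyResult
    dependency: DependencyResult
    outdir: Path | None = None


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()


def build_report(result: PipelineResult, config: AnalysisConfig) -> dict:
    """Summary tables: AUC matrix, OR table, dependency tallies, group means."""
    dep = result.dependency.dependency_table
    rhi_dep = dep[dep["rhi_dependent"]]
    category_counts = rhi_dep["category"].value_counts().to_dict()
    origin = (
        rhi_dep.groupby(["category", "compartment"]).size().unstack(fill_value=0)
    )
    peak = result.dependency.peak_result
    return {
        "config": {k: v for k, v in vars(config).items()},
        "auc": result.classify.auc_table.to_dict(),
        "odds_ratios": {
            label: {
                "a": t.a, "b": t.b, "c": t.c, "d": t.d,
                "odds_ratio": t.odds_ratio, "p_value": t.p_value,
            }
            for label, t in result.classify.or_tables.items()
        },
        "venn": {"+".join(k) if k else "none": v for k, v in result.classify.venn_counts.items()},
        "n_rhi_dependent": int(dep["rhi_dependent"].sum()),
        "dependency_categories": category_counts,
        "dependency_origin": {str(k): v for k, v in origin.to_dict(orient="index").items()},
        "peaks": {
            "n_high_confidence": int(len(peak.peaks)),
            "n_excluded": int(peak.peaks["excluded"].sum()),
            "n_kipf_dependent": peak.n_dependent,
            "n_kipf_independent": peak.n_independent,
        },
        "level_groups": result.classify.group_table.groupby("group")["level"]
        .agg(["size", "mean"])
        .to_dict(orient="index"),
    }


def write_results(
    result: PipelineResult, fixture: Fixture, config: AnalysisConfig, outdir: str | Path
) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    bins_out = result.bins.copy()
    write_table(bins_out, outdir / "bins.tsv")
    write_table(
        pd.DataFrame([result.filter_report]), outdir / "filter_report.tsv"
    )
    enr = result.quant.mark_enrichment.copy()
    write_table(enr.reset_index(), outdir / "mark_enrichment.tsv")
    for condition, by_strand in result.quant.pirna_cpm.items():
        merged = pd.concat(
            {s: frame for s, frame in by_strand.items()}, axis=1
        )
        merged.columns = [f"{s}_{c}" for s, c in merged.columns]
        write_table(merged.reset_index(), outdir / f"pirna_cpm_{condition}.tsv")
    write_table(
        result.classify.auc_table.reset_index(names="target"), outdir / "auc.tsv"
    )
    or_rows = [
        {
            "stratum": label, "a": t.a, "b": t.b, "c": t.c, "d": t.d,
            "odds_ratio": t.odds_ratio, "p_value": t.p_value,
        }
        for label, t in result.classify.or_tables.items()
    ]
    write_table(pd.DataFrame(or_rows), outdir / "or_table.tsv")
    venn_rows = [
        {"region": "+".join(k) if k else "none", "count": v}
        for k, v in result.classify.venn_counts.items()
    ]
    write_table(pd.DataFrame(venn_rows), outdir / "venn.tsv")
    write_table(result.classify.group_table, outdir / "level_groups.tsv")
    write_table(result.dependency.rhi_table.reset_index(), outdir / "rhi_dependency.tsv")
    write_table(
        result.dependency.dependency_table.reset_index(), outdir / "dependency.tsv"
    )
    write_table(result.dependency.peak_result.peaks, outdir / "peak_dependency.tsv")
    write_table(
        result.dependency.delta_summary.reset_index(), outdir / "delta_groups.tsv"
    )

    report = build_report(result, config)
    with open(outdir / "report.json", "w") as handle:
        json.dump(report, handle, indent=2, sort_keys=True, default=str)

    inputs = sorted(p for p in fixture.root.rglob("*") if p.is_file())
    manifest = {
        "version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "config": {k: v for k, v in vars(config).items()},
        "inputs": {str(p.relative_to(fixture.root)): _sha256(p) for p in inputs},
        "results": {
            p.name: _sha256(p)
            for p in sorted(outdir.glob("*.tsv")) + [outdir / "report.json"]
        },
        "rows": {
            "bins_retained": len(result.bins),
            "rhi_dependent": int(
                result.dependency.rhi_table["rhi_dependent"].sum()
            ),
            "high_confidence_peaks": int(len(result.dependency.peak_result.peaks)),
        },
    }
    with open(outdir / "manifest.json", "w") as handle:
        json.dump(manifest, handle, indent=2, sort_keys=True)
    return outdir


def run_pipeline(
    fixture_dir: str | Path,
    outdir: str | Path | None,
    config: AnalysisConfig | None = None,
) -> PipelineResult:
    """Execute every stage on a fixture directory; optionally write results."""
    config = config or AnalysisConfig()
    config.validate()
    fixture = Fixture.load(fixture_dir)
    n_replicates = fixture.sim_config.n_replicates if fixture.sim_config else 2
    if fixture.sim_config is not None:
        # fixtures carry their own (short) mappability read length
        config.mappability_read_length = fixture.sim_config.mappability_read_length

    bins, report = stage_bins(fixture, config)
    quant = stage_quantify(fixture, bins, config, n_replicates)
    classify = stage_classify(fixture, bins, quant, config, n_replicates)
    dependency = stage_dependency(fixture, bins, quant, config, n_replicates)
    result = PipelineResult(
        bins=bins,
        filter_report=report,
        quant=quant,
        classify=classify,
        dependency=dependency,
    )
    if outdir is not None:
        result.outdir = write_results(result, fixture, config, outdir)
    return result
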