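import pandas as pd
import pytest

from markbins.config import AnalysisConfig, SimulationConfig
from markbins.pipeline import run_pipeline
from markbins.simulate import simulate_cohort, write_fixture

#: canonical seed of the default synthetic study used across the suite
COHORT_SEED = 1


def small_config(seed: int = 7, **overrides) -> SimulationConfig:
    """A reduced cohort for fast determinism/round-trip checks."""
    defaults = dict(
        seed=seed,
        n_sequences=2,
        sequence_length=150_000,
        mito_length=6_000,
        scaffold_length=6_000,
        duplication_blocks=[(1_500, 2)],
        mappability_read_length=15,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def cohort():
    """The default synthetic study: 5 x 600 kb chromosomes, seed fixed."""
    return simulate_cohort(SimulationConfig(seed=COHORT_SEED))


@pytest.fixture(scope="session")
def fixture_dir(cohort, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("fixture")
    write_fixture(cohort, outdir)
    return outdir


@pytest.fixture(scope="session")
def pipeline_result(fixture_dir, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("results")
    return run_pipeline(fixture_dir, outdir, AnalysisConfig())


@pytest.fixture(scope="session")
def small_cohort():
    return simulate_cohort(small_config())


@pytest.fixture(scope="session")
def small_fixture_dir(small_cohort, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("small_fixture")
    write_fixture(small_cohort, outdir)
    return outdir


@pytest.fixture()
def toy_bins():
    """Two adjacent 1 kb bins on one chromosome."""
    return pd.DataFrame(
        {
            "chrom": ["chr1", "chr1"],
            "start": [0, 1000],
            "end": [1000, 2000],
            "bin_id": ["chr1:0-1000", "chr1:1000-2000"],
        }
    )


def make_fragments(rows):
    """Helper: fragment table from (chrom, start, end, strand) tuples."""
    frame = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand"])
    frame["name"] = "."
    frame["score"] = 0
    return frame[["chrom", "start", "end", "name", "score", "strand"]]
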