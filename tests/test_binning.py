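"""Genome tiling, sliding windows, mappability and compartment labels."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from markbins.binning import (
    assign_compartment,
    compute_mappability,
    filter_bins,
    parse_printed_interval,
    slide_genome,
    tile_genome,
)
from markbins.config import DM6_COMPARTMENTS
from markbins.genome import GenomeAssembly

_RC = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def assembly_from(seqs: dict[str, str]) -> GenomeAssembly:
    return GenomeAssembly(
        names=list(seqs),
        lengths={k: len(v) for k, v in seqs.items()},
        sequences=seqs,
    )


def lengths_only(lengths: dict[str, int]) -> GenomeAssembly:
    return GenomeAssembly(names=list(lengths), lengths=lengths)


class TestTiling:
    def test_single_exact_bin(self):
        bins = tile_genome(lengths_only({"chr1": 1000}), 1000)
        assert len(bins) == 1
        assert (bins.loc[0, "start"], bins.loc[0, "end"]) == (0, 1000)

    def test_trailing_short_bin_kept(self):
        bins = tile_genome(lengths_only({"chr1": 2500}), 1000)
        assert list(zip(bins["start"], bins["end"])) == [(0, 1000), (1000, 2000), (2000, 2500)]

    def test_rejects_empty_assembly(self):
        empty = GenomeAssembly(names=[], lengths={})
        with pytest.raises(ValueError, match="empty"):
            tile_genome(empty, 1000)
        with pytest.raises(ValueError, match="empty"):
            slide_genome(empty)

    @given(
        lengths=st.lists(st.integers(1, 5000), min_size=1, max_size=5),
        bin_size=st.integers(1, 1500),
    )
    @settings(max_examples=100, deadline=None)
    def test_tiling_is_a_partition(self, lengths, bin_size):
        assembly = lengths_only({f"chr{i}": n for i, n in enumerate(lengths)})
        bins = tile_genome(assembly, bin_size)
        assert (bins["end"] - bins["start"]).sum() == sum(lengths)
        expected = sum(-(-n // bin_size) for n in lengths)
        assert len(bins) == expected
        for _, group in bins.groupby("chrom"):
            starts, ends = group["start"].to_numpy(), group["end"].to_numpy()
            assert (starts[1:] == ends[:-1]).all()  # disjoint and exhaustive


class TestSliding:
    def test_hand_enumeration_12kb(self):
        wins = slide_genome(lengths_only({"chr1": 12_000}), 10_000, 5_000, 5_000)
        assert list(zip(wins["start"], wins["end"])) == [
            (0, 10_000),
            (5_000, 12_000),
            (10_000, 12_000),
        ]
        retained = wins[~wins["below_min_size"]]
        assert len(retained) == 2

    def test_short_sequence_fully_filtered(self):
        wins = slide_genome(lengths_only({"chr1": 4_000}), 10_000, 5_000, 5_000)
        assert len(wins) == 1
        assert wins["below_min_size"].all()

    @given(length=st.integers(1, 60), window=st.integers(2, 20), data=st.data())
    @settings(max_examples=150, deadline=None)
    def test_raw_window_count_is_ceil_length_over_step(self, length, window, data):
        step = data.draw(st.integers(1, window))
        wins = slide_genome(lengths_only({"chr1": length}), window, step, min_size=1)
        assert len(wins) == -(-length // step)
        # hand enumeration
        expected = [(s, min(s + window, length)) for s in range(0, length, step)]
        assert list(zip(wins["start"], wins["end"])) == expected


def oracle_unique_starts(seqs: dict[str, str], n: int) -> dict[str, list[bool]]:
    """Brute force: scan every (sequence, offset) for each k-mer or its twin."""
    out = {}
    for name, seq in seqs.items():
        flags = []
        for i in range(len(seq) - n + 1):
            kmer = seq[i : i + n]
            if any(b not in "ACGT" for b in kmer):
                flags.append(False)
                continue
            twin = revcomp(kmer)
            hits = 0
            for other in seqs.values():
                for j in range(len(other) - n + 1):
                    window = other[j : j + n]
                    if window == kmer or window == twin:
                        hits += 1
            flags.append(hits == 1)
        out[name] = flags
    return out


def random_seq(rng, length, alphabet="ACGT"):
    return "".join(rng.choice(list(alphabet), size=length))


class TestMappability:
    def test_distinct_kmers_give_interior_value_one(self):
        rng = np.random.default_rng(11)
        seq = random_seq(rng, 400)
        n = 20
        track = compute_mappability(assembly_from({"chr1": seq}), n)
        values = track.position_values("chr1")
        interior = values[n - 1 : len(seq) - n + 1]
        assert np.allclose(interior, 1.0)

    def test_duplicated_block_zeroes_inner_positions(self):
        rng = np.random.default_rng(5)
        n = 12
        block = random_seq(rng, 3 * n)
        left = random_seq(rng, 150)
        mid = random_seq(rng, 150)
        right = random_seq(rng, 150)
        seq = left + block + mid + block + right
        track = compute_mappability(assembly_from({"chr1": seq}), n)
        values = track.position_values("chr1")
        for start in (len(left), len(left) + len(block) + len(mid)):
            inner = values[start + n - 1 : start + len(block) - n + 1]
            assert np.allclose(inner, 0.0)

    def test_matches_bruteforce_oracle_on_toy_genome(self):
        rng = np.random.default_rng(3)
        seqs = {"chrA": random_seq(rng, 600), "chrB": random_seq(rng, 400)}
        n = 20
        track = compute_mappability(assembly_from(seqs), n)
        oracle = oracle_unique_starts(seqs, n)
        for name in seqs:
            assert track.unique_starts[name].tolist() == oracle[name]

    def test_bin_values_match_oracle_recount(self):
        rng = np.random.default_rng(9)
        # short tandem-ish genome with forced repeats and an ambiguous base
        seq = random_seq(rng, 200)
        seq = seq + seq[50:90] + random_seq(rng, 60)
        seq = seq[:120] + "N" + seq[121:]
        n = 8
        assembly = assembly_from({"chr1": seq})
        track = compute_mappability(assembly, n)
        bins = tile_genome(assembly, 37)
        values = track.bin_values(bins)
        oracle = oracle_unique_starts({"chr1": seq}, n)["chr1"]
        for (start, end), got in zip(zip(bins["start"], bins["end"]), values):
            expect = sum(oracle[start:min(end, len(oracle))]) / (end - start)
            assert got == pytest.approx(expect)

    @given(data=st.data())
    @settings(max_examples=100, deadline=None)
    def test_property_oracle_equivalence(self, data):
        n = data.draw(st.integers(2, 25))
        n_seqs = data.draw(st.integers(1, 2))
        seqs = {}
        for i in range(n_seqs):
            length = data.draw(st.integers(n, 160))
            seqs[f"chr{i}"] = data.draw(
                st.text(alphabet="ACGTN", min_size=length, max_size=length)
            )
        track = compute_mappability(assembly_from(seqs), n)
        oracle = oracle_unique_starts(seqs, n)
        for name in seqs:
            assert track.unique_starts[name].tolist() == oracle[name]

    def test_sequence_shorter_than_n_warns_and_zeroes(self):
        with pytest.warns(UserWarning, match="shorter than"):
            track = compute_mappability(assembly_from({"tiny": "ACGT"}), 10)
        assert np.all(track.position_values("tiny") == 0.0)


class TestFilterBins:
    def make_bins(self, mappabilities, chrom="chr1"):
        frame = pd.DataFrame(
            {
                "chrom": chrom,
                "start": np.arange(len(mappabilities)) * 1000,
                "end": (np.arange(len(mappabilities)) + 1) * 1000,
                "mappability": mappabilities,
            }
        )
        frame["bin_id"] = frame["chrom"] + ":" + frame["start"].astype(str)
        return frame

    def test_threshold_is_strict_less_removal(self):
        bins = self.make_bins([0.2, 0.199, 0.5])
        kept, report = filter_bins(bins, min_mappability=0.2)
        assert kept["mappability"].tolist() == [0.2, 0.5]
        assert report["removed_low_mappability"] == 1

    def test_excluded_sequence_removed_regardless(self):
        bins = pd.concat(
            [self.make_bins([1.0]), self.make_bins([1.0], chrom="mito")],
            ignore_index=True,
        )
        kept, report = filter_bins(bins, excluded_sequences=("mito",))
        assert kept["chrom"].tolist() == ["chr1"]
        assert report["removed_excluded_sequence"] == 1

    def test_idempotent(self):
        bins = self.make_bins([0.1, 0.3, 0.9, 0.15])
        once, _ = filter_bins(bins, min_mappability=0.2)
        twice, report = filter_bins(once, min_mappability=0.2)
        pd.testing.assert_frame_equal(once, twice)
        assert report["removed_low_mappability"] == 0

    def test_retained_matches_truth_of_duplication_layout(self, cohort):
        """Bins kept by the filter are exactly those with >=20% unique k-mer starts."""
        from markbins.binning import compute_mappability

        config = cohort.config
        track = compute_mappability(cohort.assembly, config.mappability_read_length)
        bins = tile_genome(cohort.assembly, config.bin_size)
        bins["mappability"] = track.bin_values(bins)
        kept, _ = filter_bins(bins, min_mappability=0.2, excluded_sequences=("mito",))
        # oracle from the simulator's duplication layout: a bin fails only if
        # enough of its k-mer starts fall inside pasted repeat copies
        expect = bins[(bins["chrom"] != "mito") & (bins["mappability"] >= 0.2)]
        assert kept["bin_id"].tolist() == expect["bin_id"].tolist()
        placements = cohort.truth.attrs["duplication_placements"]
        dup_bins = set()
        for _, chrom, start, length in placements:
            for b in range(start // config.bin_size, (start + length) // config.bin_size + 1):
                dup_bins.add((chrom, b * config.bin_size))
        dropped = bins[~bins["bin_id"].isin(kept["bin_id"])]
        dropped = dropped[dropped["chrom"] != "mito"]
        assert all(
            (row.chrom, row.start) in dup_bins for row in dropped.itertuples()
        )


class TestCompartments:
    def test_printed_interval_conversion(self):
        assert parse_printed_interval("chr2R: 1-6460000") == ("chr2R", 0, 6_460_000)
        assert parse_printed_interval("chr2L: 22160000-23513712") == (
            "chr2L",
            22_160_000,
            23_513_712,
        )

    def test_heterochromatin_total_span(self):
        intervals = [
            "chr2R: 1-6460000",
            "chr2L: 22160000-23513712",
            "chr3L: 23030000-28110227",
            "chr3R: 1-4200000",
        ]
        total = sum(e - s for _, s, e in map(parse_printed_interval, intervals))
        assert total == 17_093_939

    def test_bin_midpoint_in_heterochromatin(self):
        bins = pd.DataFrame(
            {
                "chrom": ["chr2R"],
                "start": [100],
                "end": [1100],
                "bin_id": ["chr2R:100-1100"],
            }
        )
        out = assign_compartment(bins, DM6_COMPARTMENTS)
        assert out["compartment"].tolist() == ["heterochromatin"]

    def test_unlisted_sequence_is_other(self):
        bins = pd.DataFrame(
            {"chrom": ["chrU"], "start": [0], "end": [1000], "bin_id": ["chrU:0-1000"]}
        )
        out = assign_compartment(bins, DM6_COMPARTMENTS)
        assert out["compartment"].tolist() == ["other"]

    def test_malformed_interval_rejected(self):
        bins = pd.DataFrame(
            {"chrom": ["chr1"], "start": [0], "end": [1000], "bin_id": ["chr1:0-1000"]}
        )
        with pytest.raises(ValueError):
            assign_compartment(bins, [("chr1", 500, 500, "euchromatin")])

    def test_compartments_are_disjoint_at_printed_boundaries(self):
        # the shared breakpoint (e.g. chr2R 6460000) belongs to exactly one label
        bins = pd.DataFrame(
            {
                "chrom": ["chr2R", "chr2R"],
                "start": [6_459_000, 6_460_000],
                "end": [6_460_000, 6_461_000],
                "bin_id": ["a", "b"],
            }
        )
        out = assign_compartment(bins, DM6_COMPARTMENTS)
        assert out["compartment"].tolist() == ["heterochromatin", "euchromatin"]
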