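"""Island-context derivation, sequence-proportion enrichment, LD-block
overlap and blood-brain summaries."""

import numpy as np
import pandas as pd
import pytest

from twinmeth.core import AnnotationTrack, ProbeManifest, Region
from twinmeth.enrichment import (
    _Coverage,
    bloodbrain_summarize,
    derive_island_context,
    elements_frame,
    ldblock_overlap,
    sequence_overlap_enrichment,
)
from twinmeth.regions import build_background_regions


def _islands(rows):
    return AnnotationTrack("islands", pd.DataFrame(rows))


class TestIslandContext:
    def test_flank_definitions(self):
        track = _islands([{"chrom": "chr1", "start": 10000, "end": 11000}])
        ctx = derive_island_context(track)
        by_state = {r.state: (r.start, r.end) for r in ctx.intervals.itertuples()}
        assert by_state["island"] == (10000, 11000)
        assert by_state["n_shore"] == (8000, 10000)
        assert by_state["n_shelf"] == (6000, 8000)
        assert by_state["s_shore"] == (11000, 13000)
        assert by_state["s_shelf"] == (13000, 15000)

    def test_truncation_at_chromosome_start(self):
        ctx = derive_island_context(_islands([{"chrom": "chr1", "start": 500, "end": 1000}]))
        shores = ctx.intervals[ctx.intervals["state"] == "n_shore"]
        assert (shores["start"].iloc[0], shores["end"].iloc[0]) == (0, 500)
        assert (ctx.intervals[ctx.intervals["state"] == "n_shelf"]).empty

    def test_adjacent_islands_split_at_midpoint(self):
        ctx = derive_island_context(
            _islands(
                [
                    {"chrom": "chr1", "start": 10000, "end": 11000},
                    {"chrom": "chr1", "start": 13000, "end": 14000},
                ]
            )
        )
        t = ctx.intervals
        first_s_shore = t[(t["state"] == "s_shore") & (t["start"] == 11000)]
        assert first_s_shore["end"].iloc[0] == 12000  # midpoint of the 2 kb gap
        second_n_shore = t[(t["state"] == "n_shore") & (t["end"] == 13000)]
        assert second_n_shore["start"].iloc[0] == 12000

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_partition_of_covered_span(self, seed):
        rng = np.random.default_rng(seed)
        starts = np.sort(rng.choice(np.arange(0, 300000, 100), size=8, replace=False))
        rows = [
            {"chrom": "chr1", "start": int(s), "end": int(s + rng.integers(200, 3000))}
            for s in starts
        ]
        merged = []
        for r in rows:  # drop overlapping draws
            if not merged or r["start"] >= merged[-1]["end"]:
                merged.append(r)
        ctx = derive_island_context(_islands(merged), chrom_sizes={"chr1": 400000})
        t = ctx.intervals.sort_values("start")
        assert t["start"].iloc[0] == 0 and t["end"].iloc[-1] == 400000
        assert (t["start"].to_numpy()[1:] == t["end"].to_numpy()[:-1]).all()  # tiles, no gaps


class TestCoverage:
    @pytest.mark.parametrize("trial", range(5))
    def test_matches_brute_force(self, trial):
        rng = np.random.default_rng(trial)
        starts = np.sort(rng.choice(10000, size=20, replace=False))
        ends = starts + rng.integers(1, 300, size=20)
        kept: list[tuple[int, int]] = []
        for s, e in zip(starts, ends):  # drop draws overlapping the last kept one
            if not kept or s >= kept[-1][1]:
                kept.append((int(s), int(e)))
        ivals = pd.DataFrame(
            {"chrom": "chr1", "start": [s for s, _ in kept], "end": [e for _, e in kept]}
        )
        cov = _Coverage(ivals)
        queries = pd.DataFrame(
            {"chrom": "chr1", "start": rng.integers(0, 9000, 30), "end": 0}
        )
        queries["end"] = queries["start"] + rng.integers(1, 2000, 30)
        got = cov.overlap_bp(queries)
        base = np.zeros(11000, dtype=bool)
        for r in ivals.itertuples():
            base[r.start : r.end] = True
        expected = [base[q.start : q.end].sum() for q in queries.itertuples()]
        np.testing.assert_allclose(got, expected)


def _simple_world():
    """A toy genome: 40 probe pairs, a two-state annotation, and LD blocks."""
    rows = []
    pos = 1000
    for i in range(40):
        rows.append({"probe_id": f"cgA{i}", "chrom": "chr1", "pos": pos})
        rows.append({"probe_id": f"cgB{i}", "chrom": "chr1", "pos": pos + 400})
        pos += 5000
    manifest = ProbeManifest(pd.DataFrame(rows))
    background = build_background_regions(manifest)
    return manifest, background


class TestSequenceEnrichment:
    def test_called_set_inside_one_state(self):
        manifest, background = _simple_world()
        # state "hot" covers the first 10 background regions exactly
        hot = background.head(10)
        cold_start = int(hot["end"].max()) + 1
        track = AnnotationTrack(
            "two_state",
            pd.DataFrame(
                [{"chrom": "chr1", "start": int(r.start) - 1, "end": int(r.end), "state": "hot"}
                 for r in hot.itertuples()]
                + [{"chrom": "chr1", "start": cold_start, "end": 10_000_000, "state": "cold"}]
            ),
        )
        called = pd.DataFrame(
            {
                "chrom": "chr1",
                "start": hot["start"].head(5) - 1,
                "end": hot["end"].head(5),
                "element_type": "region",
                "n_probes": 2,
            }
        )
        res = sequence_overlap_enrichment(
            called, background, track, manifest, n_resample=500, n_boot=200, seed=0
        ).set_index("state")
        assert res.loc["hot", "observed"] == pytest.approx(1.0)
        assert res.loc["hot", "p"] < 0.05
        assert res.loc["cold", "observed"] == 0.0

    def test_null_mean_matches_bp_share(self):
        manifest, background = _simple_world()
        # state covering ~half the background regions
        half = background.head(20)
        track = AnnotationTrack(
            "half",
            pd.DataFrame(
                [{"chrom": "chr1", "start": int(r.start) - 1, "end": int(r.end), "state": "s"}
                 for r in half.itertuples()]
            ),
        )
        called = pd.DataFrame(
            {
                "chrom": "chr1",
                "start": background["start"].iloc[5:15] - 1,
                "end": background["end"].iloc[5:15],
                "element_type": "region",
                "n_probes": 2,
            }
        )
        res = sequence_overlap_enrichment(
            called, background, track, manifest, n_resample=800, n_boot=100, seed=1
        )
        # null draws are region-matched, so the expected proportion is the
        # state's share of background-region bp (= 20/40 here)
        assert abs(res["null_mean"].iloc[0] - 0.5) < 0.06

    def test_called_equals_background_is_unenriched(self):
        manifest, background = _simple_world()
        track = AnnotationTrack(
            "s",
            pd.DataFrame([{"chrom": "chr1", "start": 0, "end": 60_000, "state": "s"}]),
        )
        called = pd.DataFrame(
            {
                "chrom": "chr1",
                "start": background["start"] - 1,
                "end": background["end"],
                "element_type": "region",
                "n_probes": background["n_probes"],
            }
        )
        res = sequence_overlap_enrichment(
            called, background, track, manifest, n_resample=300, n_boot=100, seed=2
        )
        assert res["p"].iloc[0] > 0.5

    def test_empty_called_rejected(self):
        manifest, background = _simple_world()
        track = AnnotationTrack("s", pd.DataFrame([{"chrom": "chr1", "start": 0, "end": 10}]))
        with pytest.raises(ValueError, match="empty"):
            sequence_overlap_enrichment(pd.DataFrame(), background, track, manifest)


class TestLdBlocks:
    def _blocks(self):
        return AnnotationTrack(
            "ld", pd.DataFrame([{"chrom": "chr1", "start": 900, "end": 2000}])
        )

    def test_containment_counts(self):
        manifest, background = _simple_world()
        called = elements_frame(
            [Region("chr1", 1000, 1400, ["cgA0", "cgB0"], "DMR", "hyper", auc=1.0)]
        )
        res = ldblock_overlap(called, self._blocks(), background, manifest, 100, 100, seed=0)
        assert res.observed == 1
        assert res.per_block["n_overlapping"].iloc[0] == 1

    def test_adjacency_is_not_overlap(self):
        manifest, background = _simple_world()
        # half-open element ending exactly at the block start: zero shared bp
        called = pd.DataFrame(
            [{"chrom": "chr1", "start": 500, "end": 900, "element_type": "region", "n_probes": 2}]
        )
        res = ldblock_overlap(called, self._blocks(), background, manifest, 100, 100, seed=0)
        assert res.observed == 0

    def test_null_mean_matches_block_fraction(self):
        manifest, background = _simple_world()
        # blocks covering the spans of half of all background regions
        half = background.iloc[::2]
        blocks = AnnotationTrack(
            "ld",
            pd.DataFrame(
                [{"chrom": "chr1", "start": int(r.start) - 1, "end": int(r.end)}
                 for r in half.itertuples()]
            ),
        )
        called = pd.DataFrame(
            {
                "chrom": "chr1",
                "start": background["start"].head(10) - 1,
                "end": background["end"].head(10),
                "element_type": "region",
                "n_probes": 2,
            }
        )
        res = ldblock_overlap(called, blocks, background, manifest, 800, 100, seed=3)
        assert abs(res.null_mean - 5.0) < 0.8


class TestBloodBrain:
    def _region(self, probes):
        return Region("chr1", 100, 1000, probes, "DMR", "hyper", auc=1.0)

    def test_order_statistics(self):
        rho = pd.Series({"a": -0.44, "b": -0.21, "c": -0.18})
        out = bloodbrain_summarize([self._region(["a", "b", "c"])], rho)
        row = out.iloc[0]
        assert (row["median_rho"], row["min_rho"], row["max_rho"]) == (-0.21, -0.44, -0.18)
        assert row["n_missing"] == 0

    def test_single_probe_match(self):
        rho = pd.Series({"a": 0.3})
        row = bloodbrain_summarize([self._region(["a", "zz"])], rho).iloc[0]
        assert row["median_rho"] == row["min_rho"] == row["max_rho"] == 0.3
        assert row["n_missing"] == 1

    def test_no_match_flagged(self):
        rho = pd.Series({"other": 0.1})
        row = bloodbrain_summarize([self._region(["x", "y"])], rho).iloc[0]
        assert row["no_match"] and np.isnan(row["median_rho"]) and row["n_missing"] == 2
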