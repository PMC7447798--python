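"""Region selection, contiguity construction, trapezoidal scoring, background."""

import itertools

import numpy as np
import pandas as pd
import pytest

from twinmeth.core import ProbeManifest
from twinmeth.regions import (
    build_background_regions,
    build_candidate_regions,
    region_auc,
    score_regions,
    select_region_probes,
)
from twinmeth.simulate import SimulationConfig, simulate_manifest


def _manifest(positions, chrom="chr1"):
    if isinstance(positions, dict):
        rows = [
            {"probe_id": f"cg{c}_{i}", "chrom": c, "pos": p}
            for c, pos_list in positions.items()
            for i, p in enumerate(pos_list)
        ]
    else:
        rows = [{"probe_id": f"cg{i}", "chrom": chrom, "pos": p} for i, p in enumerate(positions)]
    return ProbeManifest(pd.DataFrame(rows))


def _retained(manifest, stats):
    return pd.DataFrame(
        {"probe_id": manifest.table["probe_id"], "region_stat": np.asarray(stats, dtype=float)}
    )


def brute_force_regions(positions, stats, max_gap=1000, min_probes=2):
    """Oracle: enumerate all maximal runs that satisfy the gap and sign rules."""
    n = len(positions)
    valid = []
    for i, j in itertools.combinations(range(n), 2):
        idx = list(range(i, j + 1))
        gaps_ok = all(positions[k + 1] - positions[k] <= max_gap for k in idx[:-1])
        signs = [1 if stats[k] >= 0 else -1 for k in idx]
        if gaps_ok and len(set(signs)) == 1 and len(idx) >= min_probes:
            valid.append(tuple(idx))
    maximal = [
        run for run in valid
        if not any(set(run) < set(other) for other in valid if other != run)
    ]
    return sorted(maximal)


class TestSelect:
    def _stats_frame(self, interest, nuisance=None, kind_col="stat_mean"):
        n = len(interest)
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"probe_id": [f"cg{i}" for i in range(n)], kind_col: interest})
        if kind_col != "stat_mean":
            df["stat_mean"] = rng.normal(size=n)
        if kind_col != "stat_var":
            df["stat_var"] = np.exp(rng.normal(size=n) * 0.1)
        for k in (2, 3, 4, 5):
            df[f"stat_c{k}"] = nuisance[k] if nuisance and k in nuisance else rng.normal(size=n)
        df["degenerate"] = False
        return df

    def test_median_probe_not_retained(self):
        interest = np.concatenate([np.linspace(-3, 3, 99), [0.0]])
        df = self._stats_frame(interest)
        out = select_region_probes(df, "DMR")
        assert "cg99" not in set(out["probe_id"])

    def test_extreme_nuisance_overrides_extreme_interest(self):
        rng = np.random.default_rng(1)
        interest = rng.normal(size=1000)
        interest[0] = 10.0  # far in the interest tail
        nuis = rng.normal(size=1000)
        nuis[0] = 8.0  # and far in a nuisance tail
        df = self._stats_frame(interest, nuisance={2: nuis})
        out = select_region_probes(df, "DMR")
        assert "cg0" not in set(out["probe_id"])

    def test_degenerate_distribution_empty(self):
        df = self._stats_frame(np.ones(50))
        out = select_region_probes(df, "DMR")
        assert out.empty

    def test_null_retention_fraction_matches_expectation(self):
        """Retention = 2 x tail mass x P(escaping all four nuisance tails)."""
        rng = np.random.default_rng(5)
        n = 40000
        df = self._stats_frame(rng.normal(size=n))
        out = select_region_probes(df, "DMR")
        expected = 0.10 * (1 - 0.02) ** 4
        assert abs(len(out) / n - expected) < 0.01

    def test_vmr_uses_log_f_sign(self):
        rng = np.random.default_rng(2)
        logf = rng.normal(size=200) * 0.3
        logf[0], logf[1] = 2.0, -2.0  # strongly more / less variable in cases
        df = self._stats_frame(np.exp(logf), kind_col="stat_var")
        out = select_region_probes(df, "VMR")
        stats_by_probe = out.set_index("probe_id")["region_stat"]
        assert stats_by_probe["cg0"] == pytest.approx(2.0)
        assert stats_by_probe["cg1"] == pytest.approx(-2.0)


class TestBuild:
    def test_gap_rule(self):
        man = _manifest([100, 600, 2100])
        out = build_candidate_regions(_retained(man, [2, 2, 2]), man, "DMR")
        assert len(out) == 1
        assert out[0].probe_ids == ["cg0", "cg1"]

    def test_same_sign_rule(self):
        man = _manifest([100, 500, 900])
        out = build_candidate_regions(_retained(man, [2, 2, -2]), man, "DMR")
        assert len(out) == 1 and out[0].n_probes == 2 and out[0].direction == "hyper"

    def test_chromosomes_never_joined(self):
        man = _manifest({"chr1": [100, 300], "chr2": [350, 500]})
        out = build_candidate_regions(_retained(man, [1, 1, 1, 1]), man, "DMR")
        assert len(out) == 2

    @pytest.mark.parametrize("trial", range(20))
    def test_matches_brute_force_enumerator(self, trial):
        rng = np.random.default_rng(100 + trial)
        n = int(rng.integers(5, 50))
        positions = np.sort(rng.choice(np.arange(1, 20000), size=n, replace=False))
        stats = rng.normal(size=n) * 3
        man = _manifest(positions.tolist())
        out = build_candidate_regions(_retained(man, stats), man, "DMR")
        got = sorted(
            tuple(int(pid[2:]) for pid in r.probe_ids) for r in out
        )
        expected = brute_force_regions(positions, stats)
        assert got == expected

    def test_order_independence(self):
        rng = np.random.default_rng(7)
        positions = np.sort(rng.choice(20000, size=30, replace=False)) + 1
        stats = rng.normal(size=30)
        man = _manifest(positions.tolist())
        retained = _retained(man, stats)
        shuffled = retained.sample(frac=1.0, random_state=1).reset_index(drop=True)
        a = build_candidate_regions(retained, man, "DMR")
        b = build_candidate_regions(shuffled, man, "DMR")
        assert [(r.chrom, r.start, r.end) for r in a] == [(r.chrom, r.start, r.end) for r in b]


class TestAuc:
    def test_single_trapezoid(self):
        assert region_auc([100, 200], [2, 4]) == pytest.approx(300.0)

    def test_rectangle_limit(self):
        assert region_auc([0, 100, 300], [3, 3, 3]) == pytest.approx(900.0)

    def test_quadrature_oracle(self):
        rng = np.random.default_rng(11)
        pos = np.sort(rng.choice(10000, size=8, replace=False)).astype(float)
        stats = np.abs(rng.normal(size=8)) + 0.1
        # piecewise-linear integrand evaluated on a grid containing the knots
        grid = np.unique(np.concatenate([pos, np.linspace(pos[0], pos[-1], 5001)]))
        dense = np.interp(grid, pos, stats)
        expected = np.trapezoid(dense, grid)
        assert abs(region_auc(pos, stats) - expected) < 1e-9

    def test_mixed_signs_rejected(self):
        with pytest.raises(ValueError, match="sign"):
            region_auc([0, 100], [1, -1])

    def test_translation_invariance_and_homogeneity(self):
        pos = np.array([50, 400, 900], dtype=float)
        stats = np.array([1.5, 2.5, 0.5])
        base = region_auc(pos, stats)
        assert region_auc(pos + 123456, stats) == pytest.approx(base)
        assert region_auc(pos, 2 * stats) == pytest.approx(2 * base)


class TestScore:
    def test_empty(self, small_manifest):
        assert score_regions([], pd.DataFrame(columns=["probe_id", "region_stat"]), small_manifest) == []

    def test_sorted_by_auc_descending(self):
        man = _manifest([100, 400, 2000, 2600])
        retained = _retained(man, [1, 1, 5, 5])
        cands = build_candidate_regions(retained, man, "DMR")
        scored = score_regions(cands, retained, man)
        aucs = [r.auc for r in scored]
        assert aucs == sorted(aucs, reverse=True)
        assert scored[0].auc == pytest.approx(600 * 5)

    def test_auc_recomputable_from_members(self, small_manifest):
        rng = np.random.default_rng(3)
        stats = rng.normal(size=len(small_manifest)) * 2
        retained = _retained(small_manifest, stats)
        retained = retained[np.abs(retained["region_stat"]) > 0.5]
        cands = build_candidate_regions(retained, small_manifest, "DMR")
        scored = score_regions(cands, retained, small_manifest)
        pos = small_manifest.table.set_index("probe_id")["pos"]
        st = retained.set_index("probe_id")["region_stat"]
        for r in scored:
            manual = region_auc(pos[r.probe_ids].to_numpy(), st[r.probe_ids].to_numpy())
            assert r.auc == pytest.approx(manual)


class TestBackground:
    def test_small_example(self):
        man = _manifest([100, 900, 1700, 5100])
        bg = build_background_regions(man)
        assert len(bg) == 1
        assert (bg.loc[0, "start"], bg.loc[0, "end"], bg.loc[0, "n_probes"]) == (100, 1700, 3)
        assert bg.attrs["total_bp"] == 1601

    def test_called_regions_nest_in_background(self, small_manifest):
        rng = np.random.default_rng(9)
        stats = rng.normal(size=len(small_manifest)) * 2
        retained = _retained(small_manifest, stats)
        cands = build_candidate_regions(retained, small_manifest, "DMR")
        bg = build_background_regions(small_manifest)
        for r in cands:
            host = bg[(bg["chrom"] == r.chrom) & (bg["start"] <= r.start) & (bg["end"] >= r.end)]
            assert len(host) == 1

    def test_count_scales_with_probes(self):
        small = build_background_regions(simulate_manifest(SimulationConfig(n_probes=2000, seed=2)))
        large = build_background_regions(simulate_manifest(SimulationConfig(n_probes=8000, seed=2)))
        ratio = len(large) / len(small)
        assert 3.0 < ratio < 5.0
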