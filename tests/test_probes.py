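"""Per-probe mean model, negative-control contrasts, variance F test, calling."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from twinmeth.core import SampleSheet
from twinmeth.probes import (
    ProbeModelEngine,
    call_probes,
    compute_contrasts,
    compute_probe_stats,
    fit_probe_model,
    variance_test,
)
from twinmeth.simulate import SimulationConfig, simulate_cohort, simulate_manifest, simulate_methylation

from conftest import discordant_sheet


def _engine_stats(sheet: SampleSheet, Y: np.ndarray) -> pd.DataFrame:
    eng = ProbeModelEngine(sheet)
    Ys, Yd = eng.transform(Y)
    return eng.fit_mean(Ys, Yd)


class TestMeanModel:
    def test_paired_t_equivalence_exact(self):
        """On a discordant-only design with constant NK, the mixed-model
        statistic is the classical paired t statistic."""
        sheet = discordant_sheet(20, seed=4, nk_constant=0.05)
        rng = np.random.default_rng(8)
        Y = rng.normal(0, 1, size=(60, 40)) + 0.3 * sheet.table["md_status"].to_numpy()
        fit = _engine_stats(sheet, Y)
        md = sheet.table["md_status"].to_numpy()
        diffs = Y[:, md == 1] - Y[:, md == 0]  # row order pairs cases/controls per pair
        # per pair: columns alternate twins; recompute case-minus-control
        t_ref = np.empty(Y.shape[0])
        n = sheet.n_pairs
        d = np.empty((Y.shape[0], n))
        for j in range(n):
            block = Y[:, 2 * j : 2 * j + 2]
            sign = 1.0 if md[2 * j] == 1 else -1.0
            d[:, j] = sign * (block[:, 0] - block[:, 1])
        t_ref = d.mean(axis=1) / (d.std(axis=1, ddof=1) / np.sqrt(n))
        np.testing.assert_allclose(fit["stat_mean"].to_numpy(), t_ref, atol=1e-6)

    def test_matches_statsmodels_mixedlm(self, small_sheet, small_sim):
        """Independent oracle: REML mixed model fit probe by probe."""
        import statsmodels.formula.api as smf

        eng = ProbeModelEngine(small_sheet)
        Y = eng.align(small_sim.m_matrix)
        fit = _engine_stats(small_sheet, Y[:6])
        for i in range(6):
            df = small_sheet.table.copy()
            df["y"] = Y[i]
            ml = smf.mixedlm("y ~ md_status + nk_prop", df, groups=df["pair_id"]).fit(reml=True)
            assert abs(fit["beta_md"][i] - ml.params["md_status"]) < 0.02
            assert abs(fit["stat_mean"][i] - ml.tvalues["md_status"]) < 0.15

    def test_degenerate_probe_flagged(self, small_sheet):
        y = np.full(len(small_sheet.table), 1.234)
        res = fit_probe_model(y, small_sheet)
        assert res["beta_md"] == 0.0 and res["p_mean"] == 1.0 and res["degenerate"]

    def test_parameter_recovery(self):
        """Mean of the MD-effect estimate over replicate probes recovers the
        simulated shift within Monte-Carlo error."""
        cfg = SimulationConfig(n_pairs_discordant=27, n_pairs_concneg=42, n_pairs_concpos=6,
                               n_probes=10, seed=21)
        sheet = simulate_cohort(cfg)
        rng = np.random.default_rng(3)
        n_rep, delta = 300, 0.5
        md = sheet.table["md_status"].to_numpy()
        pair_idx = pd.factorize(sheet.table["pair_id"])[0]
        u = rng.normal(0, 0.25, size=(n_rep, sheet.n_pairs))
        Y = u[:, pair_idx] + rng.normal(0, 0.25, size=(n_rep, 150)) + delta * md
        fit = _engine_stats(sheet, Y)
        se_mean = fit["se_md"].mean() / np.sqrt(n_rep)
        assert abs(fit["beta_md"].mean() - delta) < 4 * se_mean

    def test_r2_maps_delta_to_paper_band(self):
        """A shift of ~0.22 M units in this cohort gives per-probe R^2 near
        0.06, the middle of the published effect-size band."""
        cfg = SimulationConfig(n_probes=10, seed=22)
        sheet = simulate_cohort(cfg)
        rng = np.random.default_rng(5)
        md = sheet.table["md_status"].to_numpy()
        pair_idx = pd.factorize(sheet.table["pair_id"])[0]
        u = rng.normal(0, 0.25, size=(400, sheet.n_pairs))
        Y = u[:, pair_idx] + rng.normal(0, 0.25, size=(400, 150)) + 0.22 * md
        fit = _engine_stats(sheet, Y)
        assert 0.03 < fit["r2_md"].median() < 0.10


class TestContrasts:
    def test_null_contrast_pvalues_uniform(self):
        cfg = SimulationConfig(n_probes=3000, seed=31)
        man = simulate_manifest(cfg)
        sheet = simulate_cohort(cfg)
        res = simulate_methylation(cfg, man, sheet)
        contr = compute_contrasts(res.m_matrix, sheet)
        for col in ("p_c2", "p_c3", "p_c4", "p_c5"):
            assert sps.kstest(contr[col], "uniform").pvalue > 0.01, col

    def test_contrasts_blind_to_true_md_effect(self):
        """A genuine case effect (present in every affected twin) must not
        light up the negative-control contrasts."""
        cfg = SimulationConfig(n_probes=2000, seed=32)
        man = simulate_manifest(cfg)
        sheet = simulate_cohort(cfg)
        res = simulate_methylation(cfg, man, sheet)
        Y = res.m_matrix.values.to_numpy() + 0.5 * sheet.table["md_status"].to_numpy()
        mat = res.m_matrix.__class__(
            pd.DataFrame(Y, index=res.m_matrix.probe_ids, columns=res.m_matrix.sample_ids), "M"
        )
        contr = compute_contrasts(mat, sheet)
        for col in ("p_c2", "p_c3", "p_c4", "p_c5"):
            assert (contr[col] < 0.05).mean() < 0.10, col

    def test_missing_concordant_positive_degenerate(self):
        sheet = discordant_sheet(10, seed=2)
        rng = np.random.default_rng(0)
        Y = rng.normal(size=(20, 20))
        eng = ProbeModelEngine(sheet)
        out = eng.contrast_stats(*eng.transform(Y))
        assert (out["p_c2"] == 1.0).all() and (out["p_c5"] == 1.0).all()


class TestVarianceTest:
    def _sheet(self):
        return simulate_cohort(SimulationConfig(seed=41))

    def test_equal_variances_give_f_near_one(self):
        sheet = self._sheet()
        rng = np.random.default_rng(0)
        F, p = variance_test(rng.normal(size=(2000, 150)), sheet)
        assert abs(np.median(F) - 1.0) < 0.15
        assert sps.kstest(p, "uniform").pvalue > 0.01

    def test_label_swap_reciprocity(self):
        sheet = self._sheet()
        rng = np.random.default_rng(2)
        Y = rng.normal(size=(50, 150))
        F, p = variance_test(Y, sheet)
        flipped = sheet.table.copy()
        flipped["md_status"] = 1 - flipped["md_status"]
        # class counts flip, so rebuild without the pair-class validation
        swapped = SampleSheet(flipped)
        F2, p2 = variance_test(Y, swapped)
        np.testing.assert_allclose(F2, 1.0 / F, rtol=1e-10)
        np.testing.assert_allclose(p2, p, rtol=1e-8)

    def test_zero_control_variance(self):
        sheet = self._sheet()
        md = sheet.table["md_status"].to_numpy()
        Y = np.zeros((1, 150))
        Y[0, md == 1] = np.random.default_rng(3).normal(size=(md == 1).sum())
        F, p = variance_test(Y, sheet)
        assert np.isinf(F[0]) and p[0] == 0.0

    def test_power_matches_analytic(self):
        """Empirical power of the F test at a 4x variance ratio matches the
        closed-form power from the F distribution."""
        sheet = self._sheet()
        md = sheet.table["md_status"].to_numpy()
        rng = np.random.default_rng(4)
        n_rep = 2000
        Y = rng.normal(size=(n_rep, 150))
        Y[:, md == 1] *= 2.0
        F, p = variance_test(Y, sheet)
        alpha = 0.05
        dfn, dfd = 38, 110
        # two-sided rejection: F/4 beyond the alpha/2 quantiles
        lo, hi = sps.f.ppf(alpha / 2, dfn, dfd), sps.f.isf(alpha / 2, dfn, dfd)
        analytic = sps.f.sf(hi / 4.0, dfn, dfd) + sps.f.cdf(lo / 4.0, dfn, dfd)
        empirical = (p < alpha).mean()
        assert abs(empirical - analytic) < 3 * np.sqrt(analytic * (1 - analytic) / n_rep) + 0.01


class TestCallProbes:
    def _stats(self, n=200, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {
                "probe_id": [f"cg{i}" for i in range(n)],
                "stat_mean": rng.normal(size=n),
                "p_mean": rng.uniform(size=n),
                "stat_var": np.exp(rng.normal(size=n) * 0.2),
                "p_var": rng.uniform(size=n),
                "degenerate": False,
                **{f"stat_c{k}": rng.normal(size=n) for k in (2, 3, 4, 5)},
                **{f"p_c{k}": rng.uniform(size=n) for k in (2, 3, 4, 5)},
            }
        )

    def test_nuisance_filter_overrides_interest(self):
        stats = self._stats()
        stats.loc[0, "p_mean"] = 1e-12
        stats.loc[0, "p_c4"] = 0.01
        calls = call_probes(stats, "DMP")
        assert "cg0" not in set(calls.table["probe_id"])

    def test_empty_survivors(self):
        stats = self._stats(n=5)
        for k in (2, 3, 4, 5):
            stats[f"p_c{k}"] = 0.001
        calls = call_probes(stats, "DMP")
        assert calls.table.empty and calls.n_after_nuisance == 0

    def test_directions(self):
        stats = self._stats()
        stats[[f"p_c{k}" for k in (2, 3, 4, 5)]] = 0.5
        stats.loc[1, "p_mean"] = 1e-9
        stats.loc[1, "stat_mean"] = -7.0
        calls = call_probes(stats, "DMP", fdr_thresh=0.05)
        row = calls.table.set_index("probe_id").loc["cg1"]
        assert row["direction"] == "hypo"
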