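"""Per-probe univariate tests for the twin design.

Mean model
----------
For each probe the M-value is regressed on depression (MD) status and NK-cell
proportion with a random intercept per twin pair.  Because every pair has
exactly two members, the mixed model factors exactly into two independent
strata under the orthogonal pair transform

    s_j = (y_j1 + y_j2) / sqrt(2)   (between-pair; variance sigma_e^2 + 2 sigma_pair^2)
    d_j = (y_j1 - y_j2) / sqrt(2)   (within-pair;  variance sigma_e^2)

so generalized least squares with stratum-specific variances (estimated from
the stratum residuals) reproduces the mixed-model fit in closed form.  On a
discordant-only design with a constant covariate the MD statistic collapses
to the classical paired t statistic, which the tests pin down exactly.
Everything is vectorized across probes, which is what makes a
1000-permutation study affordable.

Variance model
--------------
The variably-methylated-probe statistic is the plain two-sample F value,
case variance over control variance, with a two-sided parametric p-value;
the permutation null, not the F distribution, is authoritative for calling.

Contrasts
---------
Contrast 1 (interest) is the MD fixed effect.  Contrasts 2-5 are negative
controls: groups between which no depression-specific difference is expected
even when a genuine MD effect exists, so they flag pair-type and twin-order
artifacts without tagging real signal.  Contrast 2 compares
concordant-positive twins (all affected) with the affected twins of
discordant pairs; contrast 3 compares concordant-negative twins (all
unaffected) with the unaffected twins of discordant pairs; contrasts 4 and 5
are the twin-order differences within concordant-negative and
concordant-positive pairs.  2 and 3 are Welch tests on pair-level values
(pair means vs single twins), 4 and 5 one-sample tests on pair differences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import (
    CONCORDANT_NEG,
    CONCORDANT_POS,
    DISCORDANT,
    ContrastSpec,
    MethylationMatrix,
    SampleSheet,
    default_contrasts,
    validate_contrasts,
)

__all__ = [
    "ProbeModelEngine",
    "fit_probe_model",
    "compute_contrasts",
    "variance_test",
    "compute_probe_stats",
    "call_probes",
]

log = logging.getLogger(__name__)

_VAR_FLOOR = 1e-12

NUISANCE_STAT_COLS = ["stat_c2", "stat_c3", "stat_c4", "stat_c5"]
NUISANCE_P_COLS = ["p_c2", "p_c3", "p_c4", "p_c5"]


class ProbeModelEngine:
    """Vectorized between/within-pair GLS for one sample sheet.

    The engine precomputes the pair transform and design matrices; ``fit``
    then handles an arbitrary probe x sample matrix in a few BLAS calls.
    Sample columns must be ordered as ``sheet.table`` (pair_id, twin_index).
    """

    def __init__(self, sheet: SampleSheet, df_mode: str = "normal") -> None:
        if df_mode not in ("normal", "bw"):
            raise ValueError("df_mode must be 'normal' or 'bw'")
        self.sheet = sheet
        self.df_mode = df_mode
        t = sheet.table
        self.n_samples = len(t)
        self.n_pairs = sheet.n_pairs
        if self.n_pairs < 4:
            raise ValueError("need at least 4 twin pairs for stratum variance estimation")
        # rows are sorted (pair_id, twin_index): even rows twin 1, odd rows twin 2
        self.idx1 = np.arange(0, self.n_samples, 2)
        self.idx2 = np.arange(1, self.n_samples, 2)
        md = t["md_status"].to_numpy(dtype=float)
        nk = t["nk_prop"].to_numpy(dtype=float)
        X = np.column_stack([np.ones(self.n_samples), md, nk])
        self._col_names = ["const", "md", "nk"]
        self.Xb = (X[self.idx1] + X[self.idx2]) / np.sqrt(2.0)
        self.Xw = (X[self.idx1] - X[self.idx2]) / np.sqrt(2.0)
        stacked = np.vstack([self.Xb, self.Xw])
        kept: list[int] = []
        basis = np.empty((stacked.shape[0], 0))
        for j in range(stacked.shape[1]):
            col = stacked[:, j]
            resid = col - basis @ np.linalg.lstsq(basis, col, rcond=None)[0] if basis.size else col
            if np.linalg.norm(resid) > 1e-8 * max(np.linalg.norm(col), 1.0):
                kept.append(j)
                basis = np.column_stack([basis, col])
        self.kept = kept
        self.md_estimable = 1 in kept
        self.j_md = kept.index(1) if self.md_estimable else -1
        Xbk, Xwk = self.Xb[:, kept], self.Xw[:, kept]
        self.Xbk, self.Xwk = Xbk, Xwk
        self.Gb = Xbk.T @ Xbk
        self.Gw = Xwk.T @ Xwk
        # stratum designs for residual variance: only columns active in the stratum
        w_active = [i for i in range(len(kept)) if np.linalg.norm(Xwk[:, i]) > 1e-10]
        b_active = [i for i in range(len(kept)) if np.linalg.norm(Xbk[:, i]) > 1e-10]
        self.Xw_used = Xwk[:, w_active]
        self.Xb_used = Xbk[:, b_active]
        self.rank_w = np.linalg.matrix_rank(self.Xw_used) if self.Xw_used.size else 0
        self.rank_b = np.linalg.matrix_rank(self.Xb_used) if self.Xb_used.size else 0
        self.df_w = self.n_pairs - self.rank_w
        self.df_b = self.n_pairs - self.rank_b
        self._pinv_w = np.linalg.pinv(self.Xw_used) if self.Xw_used.size else None
        self._pinv_b = np.linalg.pinv(self.Xb_used) if self.Xb_used.size else None
        # pair class masks, aligned with the transform's pair order
        pair_order = t["pair_id"].to_numpy()[self.idx1]
        cls = sheet.pairs.set_index("pair_id")["concordance"].reindex(pair_order).to_numpy()
        self.disc = cls == DISCORDANT
        self.cneg = cls == CONCORDANT_NEG
        self.cpos = cls == CONCORDANT_POS
        self.md = md
        # +1 where twin 1 of a discordant pair is the affected one, -1 otherwise
        self.disc_aff_sign = np.where(md[self.idx1] == 1, 1.0, -1.0)[self.disc]

    # -- transforms ---------------------------------------------------------
    def transform(self, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Pair sums and differences (each probes x n_pairs), scaled by 1/sqrt(2)."""
        return (
            (Y[:, self.idx1] + Y[:, self.idx2]) / np.sqrt(2.0),
            (Y[:, self.idx1] - Y[:, self.idx2]) / np.sqrt(2.0),
        )

    def align(self, matrix: MethylationMatrix) -> np.ndarray:
        """Matrix values as an array with columns in the engine's sample order."""
        missing = set(self.sheet.sample_ids) - set(matrix.sample_ids)
        if missing:
            raise ValueError(f"matrix lacks samples {sorted(missing)[:3]}...")
        return matrix.values[self.sheet.sample_ids].to_numpy(dtype=float)

    # -- mean model ---------------------------------------------------------
    def fit_mean(self, Ys: np.ndarray, Yd: np.ndarray) -> pd.DataFrame:
        n = Ys.shape[0]
        if not self.md_estimable:
            log.warning("MD status has no variation; mean model degenerate for all probes")
            return pd.DataFrame(
                {
                    "beta_md": np.zeros(n),
                    "se_md": np.full(n, np.nan),
                    "stat_mean": np.zeros(n),
                    "p_mean": np.ones(n),
                    "r2_md": np.zeros(n),
                    "degenerate": np.ones(n, dtype=bool),
                }
            )
        # stratum residual variances
        if self._pinv_w is not None and self.df_w > 0:
            resid_w = Yd - (Yd @ self._pinv_w.T) @ self.Xw_used.T
            var_w = (resid_w**2).sum(axis=1) / self.df_w
        else:
            var_w = Yd.var(axis=1, ddof=1)
        resid_b = Ys - (Ys @ self._pinv_b.T) @ self.Xb_used.T
        var_b = (resid_b**2).sum(axis=1) / max(self.df_b, 1)
        degenerate = (var_w <= _VAR_FLOOR) & (var_b <= _VAR_FLOOR)
        ww = 1.0 / np.maximum(var_w, _VAR_FLOOR)
        wb = 1.0 / np.maximum(var_b, _VAR_FLOOR)
        U = Yd @ self.Xwk
        V = Ys @ self.Xbk
        A = ww[:, None, None] * self.Gw[None] + wb[:, None, None] * self.Gb[None]
        rhs = ww[:, None] * U + wb[:, None] * V
        beta = np.linalg.solve(A, rhs[..., None])[..., 0]
        cov = np.linalg.inv(A)
        j = self.j_md
        beta_md = beta[:, j]
        se_md = np.sqrt(np.maximum(cov[:, j, j], 0.0))
        with np.errstate(divide="ignore", invalid="ignore"):
            stat = np.where(se_md > 0, beta_md / se_md, 0.0)
        if self.df_mode == "bw":
            p = 2.0 * sps.t.sf(np.abs(stat), df=max(self.df_w, 1))
        else:
            p = 2.0 * sps.norm.sf(np.abs(stat))
        beta_md = np.where(degenerate, 0.0, beta_md)
        stat = np.where(degenerate, 0.0, stat)
        p = np.where(degenerate, 1.0, p)
        # variance in M explained by MD status across samples
        var_md = self.md.var()
        # the pair transform is orthonormal: sum(y^2) = sum(s^2) + sum(d^2)
        ss = (Ys**2).sum(axis=1) + (Yd**2).sum(axis=1)
        ybar = np.sqrt(2.0) * Ys.sum(axis=1) / self.n_samples
        var_y = (ss - self.n_samples * ybar**2) / max(self.n_samples - 1, 1)
        r2 = np.clip(
            np.where(var_y > _VAR_FLOOR, beta_md**2 * var_md / np.maximum(var_y, _VAR_FLOOR), 0.0),
            0.0,
            1.0,
        )
        return pd.DataFrame(
            {
                "beta_md": beta_md,
                "se_md": se_md,
                "stat_mean": stat,
                "p_mean": p,
                "r2_md": r2,
                "degenerate": degenerate,
            }
        )

    # -- negative-control contrasts ----------------------------------------
    @staticmethod
    def _one_sample_t(D: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        n = D.shape[1]
        if n < 2:
            m = D.shape[0]
            return np.zeros(m), np.ones(m)
        se = np.sqrt(np.maximum(D.var(axis=1, ddof=1), _VAR_FLOOR) / n)
        t = D.mean(axis=1) / se
        p = 2.0 * sps.t.sf(np.abs(t), df=n - 1)
        return t, p

    @staticmethod
    def _welch_t(A: np.ndarray, B: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        n1, n2 = A.shape[1], B.shape[1]
        if n1 < 2 or n2 < 2:
            n = A.shape[0]
            return np.zeros(n), np.ones(n)
        v1 = np.maximum(A.var(axis=1, ddof=1), _VAR_FLOOR)
        v2 = np.maximum(B.var(axis=1, ddof=1), _VAR_FLOOR)
        se2 = v1 / n1 + v2 / n2
        t = (A.mean(axis=1) - B.mean(axis=1)) / np.sqrt(se2)
        df = se2**2 / (v1**2 / (n1**2 * (n1 - 1)) + v2**2 / (n2**2 * (n2 - 1)))
        p = 2.0 * sps.t.sf(np.abs(t), df=df)
        return t, p

    def contrast_stats(self, Ys: np.ndarray, Yd: np.ndarray) -> pd.DataFrame:
        # pair means and the affected/unaffected twin of each discordant pair,
        # reconstructed from the orthonormal pair transform
        pair_mean = Ys / np.sqrt(2.0)
        sgn = self.disc_aff_sign
        disc_aff = (Ys[:, self.disc] + sgn * Yd[:, self.disc]) / np.sqrt(2.0)
        disc_unaff = (Ys[:, self.disc] - sgn * Yd[:, self.disc]) / np.sqrt(2.0)
        out: dict[str, np.ndarray] = {}
        pairs = [
            ("c2", lambda: self._welch_t(pair_mean[:, self.cpos], disc_aff)),
            ("c3", lambda: self._welch_t(pair_mean[:, self.cneg], disc_unaff)),
            ("c4", lambda: self._one_sample_t(Yd[:, self.cneg])),
            ("c5", lambda: self._one_sample_t(Yd[:, self.cpos])),
        ]
        for name, fn in pairs:
            stat, p = fn()
            out[f"stat_{name}"] = stat
            out[f"p_{name}"] = p
        if self.cpos.sum() < 2:
            log.warning("fewer than 2 concordant-positive pairs: contrasts 2 and 5 degenerate (p = 1)")
        return pd.DataFrame(out)


def fit_probe_model(m_values: np.ndarray | pd.Series, sheet: SampleSheet) -> pd.Series:
    """Fit the mean model for a single probe; values follow sheet.table order."""
    engine = ProbeModelEngine(sheet)
    y = np.asarray(m_values, dtype=float)[None, :]
    Ys, Yd = engine.transform(y)
    return engine.fit_mean(Ys, Yd).iloc[0]


def compute_contrasts(
    matrix: MethylationMatrix, sheet: SampleSheet, specs: list[ContrastSpec] | None = None
) -> pd.DataFrame:
    """Negative-control contrast statistics and p-values for every probe."""
    specs = specs if specs is not None else default_contrasts()
    validate_contrasts(specs)
    engine = ProbeModelEngine(sheet)
    Y = engine.align(matrix)
    Ys, Yd = engine.transform(Y)
    out = engine.contrast_stats(Ys, Yd)
    out.insert(0, "probe_id", matrix.probe_ids.to_numpy())
    return out


def variance_test(
    matrix: MethylationMatrix | np.ndarray, sheet: SampleSheet
) -> tuple[np.ndarray, np.ndarray]:
    """Two-sample F test of case vs control variance, per probe.

    Returns (F, p) with F = var(cases) / var(controls) and a two-sided p-value
    from F(n_cases - 1, n_controls - 1).  Zero control variance gives
    F = inf, p = 0.
    """
    if isinstance(matrix, MethylationMatrix):
        order = sheet.table["sample_id"]
        Y = matrix.values[order].to_numpy(dtype=float)
    else:
        Y = np.atleast_2d(np.asarray(matrix, dtype=float))
    md = sheet.table["md_status"].to_numpy()
    cases, controls = Y[:, md == 1], Y[:, md == 0]
    if cases.shape[1] < 2 or controls.shape[1] < 2:
        raise ValueError("variance test needs >= 2 cases and >= 2 controls")
    v1 = cases.var(axis=1, ddof=1)
    v0 = controls.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = np.where(v0 > 0, v1 / np.where(v0 > 0, v0, 1.0), np.inf)
        F = np.where((v0 <= 0) & (v1 <= 0), 1.0, F)
    dfn, dfd = cases.shape[1] - 1, controls.shape[1] - 1
    with np.errstate(invalid="ignore"):
        p = 2.0 * np.minimum(sps.f.sf(F, dfn, dfd), sps.f.cdf(F, dfn, dfd))
    p = np.where(np.isinf(F), 0.0, np.clip(p, 0.0, 1.0))
    return F, p


def compute_probe_stats(
    matrix: MethylationMatrix,
    sheet: SampleSheet,
    specs: list[ContrastSpec] | None = None,
    df_mode: str = "normal",
) -> pd.DataFrame:
    """Full per-probe statistics table: mean model, contrasts 2-5 and the F test."""
    specs = specs if specs is not None else default_contrasts()
    validate_contrasts(specs)
    engine = ProbeModelEngine(sheet, df_mode=df_mode)
    Y = engine.align(matrix)
    Ys, Yd = engine.transform(Y)
    mean_fit = engine.fit_mean(Ys, Yd)
    contr = engine.contrast_stats(Ys, Yd)
    F, p_var = variance_test(Y, sheet)
    out = pd.concat([mean_fit, contr], axis=1)
    out.insert(0, "probe_id", matrix.probe_ids.to_numpy())
    out["stat_var"] = F
    out["p_var"] = p_var
    return out


@dataclass
class ProbeCalls:
    """Called probes of one kind with the funnel counts that produced them."""

    kind: str  # "DMP" | "VMP"
    table: pd.DataFrame  # probe_id, stat, p, q, direction
    n_input: int
    n_after_nuisance: int


def call_probes(
    stats: pd.DataFrame,
    kind: str,
    nuisance_alpha: float = 0.05,
    fdr_thresh: float = 0.01,
    perm_null: np.ndarray | None = None,
) -> ProbeCalls:
    """Call differentially (DMP) or variably (VMP) methylated probes.

    Probes with any negative-control contrast p-value below ``nuisance_alpha``
    are removed first.  The remaining probes get an empirical p-value against
    the permutation null when one is supplied (two-sided on the magnitude of
    the statistic; log scale for F values), otherwise the model p-value is
    used.  The null is pooled across probes — t-like and log-F statistics
    share one scale, and pooling provides the p-value resolution that FDR
    control at 1% needs.  Benjamini-Hochberg adjustment is applied and probes
    with q below ``fdr_thresh`` are called.
    """
    from .permutation import empirical_pvalue_pooled, fdr_bh

    if kind not in ("DMP", "VMP"):
        raise ValueError("kind must be DMP or VMP")
    n_input = len(stats)
    nuis = stats[NUISANCE_P_COLS].to_numpy()
    keep = ~(nuis < nuisance_alpha).any(axis=1)
    if kind == "DMP":
        keep &= ~stats["degenerate"].to_numpy(dtype=bool)
        obs = stats["stat_mean"].to_numpy()
    else:
        obs = np.log(stats["stat_var"].to_numpy())
        keep &= np.isfinite(obs)
    survivors = stats.loc[keep].reset_index(drop=True)
    if len(survivors) == 0:
        log.info("call_probes(%s): no probes survive the nuisance filter", kind)
        empty = pd.DataFrame(columns=["probe_id", "stat", "p", "q", "direction"])
        return ProbeCalls(kind, empty, n_input, 0)
    obs_kept = obs[keep]
    if perm_null is not None:
        null_all = perm_null
        if kind == "VMP":
            null_all = np.log(np.maximum(null_all, _VAR_FLOOR))
        p = empirical_pvalue_pooled(obs_kept, null_all, sided="two")
    else:
        p = survivors["p_mean" if kind == "DMP" else "p_var"].to_numpy()
    q = fdr_bh(p)
    if kind == "DMP":
        direction = np.where(obs_kept > 0, "hyper", "hypo")
        stat_col = survivors["stat_mean"].to_numpy()
    else:
        direction = np.where(obs_kept > 0, "more_variable", "less_variable")
        stat_col = survivors["stat_var"].to_numpy()
    called = q < fdr_thresh
    table = pd.DataFrame(
        {
            "probe_id": survivors["probe_id"].to_numpy()[called],
            "stat": stat_col[called],
            "p": p[called],
            "q": q[called],
            "direction": direction[called],
        }
    )
    order = np.lexsort((table["probe_id"].to_numpy(), table["p"].to_numpy()))
    table = table.iloc[order].reset_index(drop=True)
    return ProbeCalls(kind, table, n_input, int(keep.sum()))
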