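"""Structure-preserving permutation engine and false-discovery control.

The permutation scheme resamples the outcome while preserving the twin
cohort's concordance composition: pair concordance classes are reassigned
across pairs without replacement (so the counts of discordant /
concordant-negative / concordant-positive pairs never change), and within a
newly discordant pair the affected twin is chosen uniformly.  Covariates and
slide assignments travel with the samples, untouched.

Probe-level inference uses empirical p-values, p = (1 + #{null >= obs}) /
(k + 1), followed by Benjamini-Hochberg adjustment.  Region-level inference
uses a rank-based scheme in the SAM lineage: observed order statistics of the
AUC are compared with the mean permuted order statistic at the same rank; for
a grid of thresholds the called set, the median count of permuted regions
exceeding the smallest called AUC ("falsely called"), and their ratio (the
FDR) are tabulated.  Extreme permuted statistics are winsorized at a high
pooled quantile before rank averaging so single wild permutations cannot
inflate the null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .core import (
    CONCORDANT_NEG,
    CONCORDANT_POS,
    DISCORDANT,
    MethylationMatrix,
    ProbeManifest,
    SampleSheet,
)

__all__ = [
    "permute_labels",
    "empirical_pvalue",
    "empirical_pvalue_matrix",
    "fdr_bh",
    "sam_region_fdr",
    "SamResult",
    "PermutationNull",
    "run_permutation_study",
]

log = logging.getLogger(__name__)


def permute_labels(sheet: SampleSheet, seed: int | np.random.Generator) -> SampleSheet:
    """Reassign pair concordance classes at random, preserving class counts.

    Within each pair that becomes discordant the affected twin is uniform.
    All covariates (NK proportion, slide) stay with their samples.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    classes = sheet.pairs["concordance"].to_numpy().copy()
    rng.shuffle(classes)
    new_status: dict[str, dict[int, int]] = {}
    for pair_id, cls in zip(sheet.pairs["pair_id"], classes):
        if cls == DISCORDANT:
            affected = int(rng.integers(1, 3))
            new_status[pair_id] = {affected: 1, 3 - affected: 0}
        elif cls == CONCORDANT_POS:
            new_status[pair_id] = {1: 1, 2: 1}
        else:
            new_status[pair_id] = {1: 0, 2: 0}
    t = sheet.table.copy()
    t["md_status"] = [
        new_status[p][i] for p, i in zip(t["pair_id"], t["twin_index"])
    ]
    return SampleSheet(t)


def empirical_pvalue(observed: float, null: np.ndarray, sided: str = "two") -> float:
    """Permutation p-value with the +1 correction: (1 + exceedances) / (k + 1).

    ``sided="upper"`` counts null values >= observed; ``"two"`` compares
    magnitudes.  Ties count as exceedances.
    """
    null = np.asarray(null, dtype=float)
    k = null.size
    if k < 1:
        raise ValueError("need at least one permutation value")
    if sided == "upper":
        n_ge = int(np.sum(null >= observed))
    elif sided == "two":
        n_ge = int(np.sum(np.abs(null) >= abs(observed)))
    else:
        raise ValueError("sided must be 'two' or 'upper'")
    return (1 + n_ge) / (k + 1)


def empirical_pvalue_matrix(
    observed: np.ndarray, null: np.ndarray, sided: str = "two"
) -> np.ndarray:
    """Row-wise empirical p-values: observed (n,), null (n, k)."""
    observed = np.asarray(observed, dtype=float)
    null = np.asarray(null, dtype=float)
    if sided == "two":
        n_ge = (np.abs(null) >= np.abs(observed)[:, None]).sum(axis=1)
    elif sided == "upper":
        n_ge = (null >= observed[:, None]).sum(axis=1)
    else:
        raise ValueError("sided must be 'two' or 'upper'")
    return (1 + n_ge) / (null.shape[1] + 1)


def empirical_pvalue_pooled(
    observed: np.ndarray, null: np.ndarray, sided: str = "two"
) -> np.ndarray:
    """Empirical p-values against the null pooled over all probes.

    Valid when the statistic is on one common scale across probes (t-like
    statistics, log variance ratios).  Pooling gives p-value resolution
    1 / (n_probes * k + 1) instead of 1 / (k + 1), which probe-level FDR
    control at stringent thresholds requires.
    """
    observed = np.asarray(observed, dtype=float)
    flat = np.asarray(null, dtype=float).ravel()
    if sided == "two":
        flat = np.abs(flat)
        obs = np.abs(observed)
    elif sided == "upper":
        obs = observed
    else:
        raise ValueError("sided must be 'two' or 'upper'")
    flat = np.sort(flat)
    n_lt = np.searchsorted(flat, obs, side="left")
    n_ge = flat.size - n_lt
    return (1 + n_ge) / (flat.size + 1)


def fdr_bh(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class SamResult:
    """Per-threshold FDR table for the rank-based region procedure."""

    table: pd.DataFrame  # delta, n_called, falsely_called, fdr, min_auc_called
    observed_sorted: np.ndarray
    rank_null_mean: np.ndarray

    def called_at(self, fdr_target: float) -> tuple[np.ndarray, float]:
        """Indices (into the descending observed order) of the largest called
        set with estimated FDR <= target, and that set's FDR."""
        ok = self.table[self.table["fdr"] <= fdr_target]
        if ok.empty or ok["n_called"].max() == 0:
            return np.array([], dtype=int), np.nan
        best = ok.loc[ok["n_called"].idxmax()]
        d = self.observed_sorted - self.rank_null_mean
        idx = np.flatnonzero(d >= best["delta"])
        return idx, float(best["fdr"])


def sam_region_fdr(
    observed_aucs: np.ndarray,
    permuted_aucs: list[np.ndarray],
    delta_grid: np.ndarray | None = None,
    trim_quantile: float = 0.001,
) -> SamResult:
    """Rank-based permutation FDR for region AUC scores.

    Observed AUCs are sorted descending and compared, rank by rank, with the
    mean permuted AUC at the same rank (permuted lists are sorted, padded
    with zeros or truncated to the observed length).  For each threshold
    delta the called set is every rank whose observed-minus-expected excess
    is at least delta; the falsely-called count is the median, across
    permutations, of permuted AUCs exceeding the smallest called AUC; the
    FDR is their ratio, capped at 1.
    """
    obs = np.sort(np.asarray(observed_aucs, dtype=float))[::-1]
    n = obs.size
    k = len(permuted_aucs)
    if k < 1:
        raise ValueError("need at least one permutation")
    pooled = np.concatenate([np.asarray(a, dtype=float) for a in permuted_aucs]) if any(
        len(a) for a in permuted_aucs
    ) else np.array([0.0])
    cap = np.quantile(pooled, 1 - trim_quantile) if pooled.size else np.inf
    trimmed: list[np.ndarray] = []
    lengths = set()
    for a in permuted_aucs:
        a = np.minimum(np.asarray(a, dtype=float), cap)
        lengths.add(a.size)
        trimmed.append(np.sort(a)[::-1])
    if len(lengths) > 1:
        log.info("permuted region lists differ in length; rank-aligning with zero padding")
    ranks = np.zeros((k, n))
    for i, a in enumerate(trimmed):
        m = min(n, a.size)
        ranks[i, :m] = a[:m]
    rank_mean = ranks.mean(axis=0)
    d = obs - rank_mean
    if delta_grid is None:
        pos = np.unique(d[d > 0])
        delta_grid = np.concatenate([[0.0], pos]) if pos.size else np.array([0.0])
    rows = []
    for delta in np.asarray(delta_grid, dtype=float):
        called = d >= delta
        n_called = int(called.sum())
        if n_called == 0:
            rows.append(
                {"delta": delta, "n_called": 0, "falsely_called": 0.0, "fdr": 0.0,
                 "min_auc_called": np.nan}
            )
            continue
        cutoff = obs[called].min()
        false_counts = [float(np.sum(a > cutoff)) for a in trimmed]
        falsely = float(np.median(false_counts))
        rows.append(
            {
                "delta": delta,
                "n_called": n_called,
                "falsely_called": falsely,
                "fdr": min(falsely / n_called, 1.0),
                "min_auc_called": cutoff,
            }
        )
    table = pd.DataFrame(rows, columns=["delta", "n_called", "falsely_called", "fdr", "min_auc_called"])
    return SamResult(table, obs, rank_mean)


@dataclass
class PermutationNull:
    """Null archives from one permutation study."""

    k: int
    seed: int
    stat_mean_null: np.ndarray | None = None  # probes x k
    stat_var_null: np.ndarray | None = None  # probes x k
    dmr_auc_nulls: list[np.ndarray] = field(default_factory=list)
    vmr_auc_nulls: list[np.ndarray] = field(default_factory=list)

    def save(self, path: str | Path) -> None:
        def pack(lists: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
            flat = np.concatenate(lists) if lists else np.array([], dtype=float)
            lens = np.array([len(a) for a in lists], dtype=np.int64)
            return flat, lens

        dmr_flat, dmr_lens = pack(self.dmr_auc_nulls)
        vmr_flat, vmr_lens = pack(self.vmr_auc_nulls)
        np.savez_compressed(
            path,
            k=self.k,
            seed=self.seed,
            stat_mean_null=self.stat_mean_null if self.stat_mean_null is not None else np.array([]),
            stat_var_null=self.stat_var_null if self.stat_var_null is not None else np.array([]),
            dmr_flat=dmr_flat,
            dmr_lens=dmr_lens,
            vmr_flat=vmr_flat,
            vmr_lens=vmr_lens,
        )

    @classmethod
    def load(cls, path: str | Path) -> "PermutationNull":
        with np.load(path) as z:
            def unpack(flat: np.ndarray, lens: np.ndarray) -> list[np.ndarray]:
                out, off = [], 0
                for ln in lens:
                    out.append(flat[off : off + ln].copy())
                    off += ln
                return out

            sm = z["stat_mean_null"]
            sv = z["stat_var_null"]
            return cls(
                k=int(z["k"]),
                seed=int(z["seed"]),
                stat_mean_null=sm if sm.size else None,
                stat_var_null=sv if sv.size else None,
                dmr_auc_nulls=unpack(z["dmr_flat"], z["dmr_lens"]),
                vmr_auc_nulls=unpack(z["vmr_flat"], z["vmr_lens"]),
            )


def run_permutation_study(
    matrix: MethylationMatrix,
    sheet: SampleSheet,
    manifest: ProbeManifest,
    k: int = 1000,
    seed: int = 0,
    dmr_quantiles: tuple[float, float] | None = None,
    vmr_quantiles: tuple[float, float] | None = None,
    nuisance_quantiles: tuple[float, float] = (0.01, 0.99),
    max_gap: int = 1000,
    min_probes: int = 2,
    checkpoint_path: str | Path | None = None,
    checkpoint_every: int = 100,
) -> PermutationNull:
    """Recompute the whole probe-and-region pipeline under k relabelings.

    Each permutation draws its own sub-seed deterministically from the master
    seed, relabels the cohort, refits the mean and variance statistics,
    recomputes all negative-control contrasts, recomputes the selection
    quantiles within the permutation, and rebuilds and rescores candidate
    regions for both the mean (DMR) and variance (VMR) paths.  Per-probe null
    statistics and per-permutation sorted region AUC lists are archived.
    A checkpoint file makes interrupted runs resumable.
    """
    from .probes import ProbeModelEngine, variance_test
    from .regions import build_candidate_regions, score_regions, select_region_probes

    if k == 0:
        log.warning("k = 0 permutations: downstream calling will fall back to parametric p-values")
        return PermutationNull(k=0, seed=seed)
    n_probes = len(matrix.probe_ids)
    null = PermutationNull(
        k=k,
        seed=seed,
        stat_mean_null=np.zeros((n_probes, k)),
        stat_var_null=np.zeros((n_probes, k)),
    )
    start = 0
    if checkpoint_path is not None and Path(checkpoint_path).exists():
        prev = PermutationNull.load(checkpoint_path)
        done = len(prev.dmr_auc_nulls)
        if prev.seed == seed and prev.stat_mean_null is not None and prev.stat_mean_null.shape[0] == n_probes:
            m = min(done, k)
            null.stat_mean_null[:, :m] = prev.stat_mean_null[:, :m]
            null.stat_var_null[:, :m] = prev.stat_var_null[:, :m]
            null.dmr_auc_nulls = prev.dmr_auc_nulls[:m]
            null.vmr_auc_nulls = prev.vmr_auc_nulls[:m]
            start = m
            log.info("resuming permutation study at %d/%d", start, k)

    base_engine = ProbeModelEngine(sheet)
    Y = base_engine.align(matrix)
    Ys, Yd = base_engine.transform(Y)  # pair structure is fixed under relabeling
    probe_frame = pd.DataFrame({"probe_id": matrix.probe_ids.to_numpy()})

    for i in range(start, k):
        rng = np.random.default_rng((seed, 1000 + i))
        perm_sheet = permute_labels(sheet, rng)
        engine = ProbeModelEngine(perm_sheet)
        mean_fit = engine.fit_mean(Ys, Yd)
        contr = engine.contrast_stats(Ys, Yd)
        F, p_var = variance_test(Y, perm_sheet)
        null.stat_mean_null[:, i] = mean_fit["stat_mean"].to_numpy()
        null.stat_var_null[:, i] = F
        stats = pd.concat([probe_frame, mean_fit, contr], axis=1)
        stats["stat_var"] = F
        stats["p_var"] = p_var
        for kind, iq, store in (
            ("DMR", dmr_quantiles, null.dmr_auc_nulls),
            ("VMR", vmr_quantiles, null.vmr_auc_nulls),
        ):
            retained = select_region_probes(stats, kind, iq, nuisance_quantiles)
            cands = build_candidate_regions(retained, manifest, kind, max_gap, min_probes)
            scored = score_regions(cands, retained, manifest)
            store.append(np.array([r.auc for r in scored], dtype=float))
        if checkpoint_path is not None and (i + 1) % checkpoint_every == 0 and i + 1 < k:
            partial = PermutationNull(
                k=i + 1,
                seed=seed,
                stat_mean_null=null.stat_mean_null[:, : i + 1].copy(),
                stat_var_null=null.stat_var_null[:, : i + 1].copy(),
                dmr_auc_nulls=null.dmr_auc_nulls[: i + 1],
                vmr_auc_nulls=null.vmr_auc_nulls[: i + 1],
            )
            partial.save(checkpoint_path)
    if checkpoint_path is not None:
        null.save(checkpoint_path)
    return null
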