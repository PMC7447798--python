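"""Regional calling: quantile selection, contiguity runs, trapezoidal AUC.

A candidate region is a maximal run of selected probes on one chromosome in
which every consecutive gap is at most 1 kb and every member statistic shares
one sign.  Its score is the trapezoidal area of influence: for consecutive
probes with statistics a, b at distance h bp the trapezoid contributes
h * (|a| + |b|) / 2, summed along the run.  The sign is held as the region
direction, so the score is nonnegative and rankable.

Selection uses genome-wide quantiles of the statistic of interest (outer
5/95 tails for mean differences, 10/90 for variance ratios) after dropping
probes whose negative-control statistics land in the outer 1/99 tails.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .core import ProbeManifest, Region, chrom_sort_key
from .probes import NUISANCE_STAT_COLS

__all__ = [
    "select_region_probes",
    "build_candidate_regions",
    "region_auc",
    "score_regions",
    "build_background_regions",
]

log = logging.getLogger(__name__)

DMR_INTEREST_QUANTILES = (0.05, 0.95)
VMR_INTEREST_QUANTILES = (0.10, 0.90)


def select_region_probes(
    stats: pd.DataFrame,
    kind: str,
    interest_quantiles: tuple[float, float] | None = None,
    nuisance_quantiles: tuple[float, float] = (0.01, 0.99),
) -> pd.DataFrame:
    """Retain probes whose statistic of interest is tail-extreme and whose
    negative-control statistics are not.

    For DMRs the statistic of interest is the signed mean-model statistic;
    for VMRs it is log F (positive = more variable in cases).  Quantiles are
    computed across all analyzed probes.  Returns the retained rows with a
    ``region_stat`` column carrying the signed statistic.
    """
    if kind == "DMR":
        interest = stats["stat_mean"].to_numpy(dtype=float)
        iq = interest_quantiles or DMR_INTEREST_QUANTILES
    elif kind == "VMR":
        with np.errstate(divide="ignore"):
            interest = np.log(stats["stat_var"].to_numpy(dtype=float))
        iq = interest_quantiles or VMR_INTEREST_QUANTILES
    else:
        raise ValueError("kind must be DMR or VMR")
    finite = np.isfinite(interest)
    if "degenerate" in stats.columns:
        finite &= ~stats["degenerate"].to_numpy(dtype=bool)
    vals = interest[finite]
    if len(vals) == 0:
        return stats.iloc[0:0].assign(region_stat=pd.Series(dtype=float))
    qlo, qhi = np.quantile(vals, iq[0]), np.quantile(vals, iq[1])
    if qhi <= qlo:
        log.warning("degenerate %s statistic distribution; empty retention", kind)
        return stats.iloc[0:0].assign(region_stat=pd.Series(dtype=float))
    retain = finite & ((interest <= qlo) | (interest >= qhi))
    for col in NUISANCE_STAT_COLS:
        s = stats[col].to_numpy(dtype=float)
        nlo, nhi = np.quantile(s, nuisance_quantiles[0]), np.quantile(s, nuisance_quantiles[1])
        retain &= ~((s <= nlo) | (s >= nhi))
    out = stats.loc[retain].copy()
    out["region_stat"] = interest[retain]
    return out.reset_index(drop=True)


def build_candidate_regions(
    retained: pd.DataFrame,
    manifest: ProbeManifest,
    kind: str,
    max_gap: int = 1000,
    min_probes: int = 2,
) -> list[Region]:
    """Maximal same-sign runs of retained probes with consecutive gaps <= max_gap.

    ``retained`` needs columns probe_id and region_stat.  Output order is
    genomic (chrom natural order, then start).
    """
    if kind == "DMR":
        directions = {1: "hyper", -1: "hypo"}
    elif kind == "VMR":
        directions = {1: "more_variable", -1: "less_variable"}
    else:
        raise ValueError("kind must be DMR or VMR")
    if retained.empty:
        return []
    located = manifest.table.merge(
        retained[["probe_id", "region_stat"]], on="probe_id", how="inner"
    )
    regions: list[Region] = []
    for chrom, sub in located.groupby("chrom", sort=False):
        sub = sub.sort_values("pos", kind="stable")
        pos = sub["pos"].to_numpy()
        stat = sub["region_stat"].to_numpy()
        sign = np.where(stat >= 0, 1, -1)
        new_run = np.ones(len(sub), dtype=bool)
        new_run[1:] = (np.diff(pos) > max_gap) | (sign[1:] != sign[:-1])
        run_id = np.cumsum(new_run)
        for _, run in sub.groupby(run_id, sort=False):
            if len(run) < min_probes:
                continue
            s = 1 if run["region_stat"].iloc[0] >= 0 else -1
            regions.append(
                Region(
                    chrom=str(chrom),
                    start=int(run["pos"].iloc[0]),
                    end=int(run["pos"].iloc[-1]),
                    probe_ids=run["probe_id"].tolist(),
                    kind=kind,
                    direction=directions[s],
                )
            )
    regions.sort(key=lambda r: (chrom_sort_key(r.chrom), r.start))
    return regions


def region_auc(positions: np.ndarray, stats: np.ndarray) -> float:
    """Trapezoidal area of influence of one region.

    Positions must be strictly increasing and the statistics must share one
    sign (the same-sign restriction makes the absolute-value area equal the
    signed area up to orientation).
    """
    positions = np.asarray(positions, dtype=float)
    stats = np.asarray(stats, dtype=float)
    if len(positions) < 2:
        raise ValueError("a region needs at least 2 probes")
    if not np.all(np.diff(positions) > 0):
        raise ValueError("positions must be strictly increasing")
    if stats.max() > 0 and stats.min() < 0:
        raise ValueError("mixed-sign statistics violate the region contract")
    a = np.abs(stats)
    h = np.diff(positions)
    return float(np.sum(h * (a[:-1] + a[1:]) / 2.0))


def score_regions(
    candidates: list[Region], retained: pd.DataFrame, manifest: ProbeManifest
) -> list[Region]:
    """Fill in the AUC of every candidate and rank by score.

    Returns the regions sorted by AUC descending, ties broken by genomic
    position for determinism.
    """
    stat_by_probe = retained.set_index("probe_id")["region_stat"]
    pos_by_probe = manifest.table.set_index("probe_id")["pos"]
    for r in candidates:
        pos = pos_by_probe[r.probe_ids].to_numpy()
        st = stat_by_probe[r.probe_ids].to_numpy()
        r.auc = region_auc(pos, st)
    return sorted(candidates, key=lambda r: (-r.auc, chrom_sort_key(r.chrom), r.start))


def build_background_regions(
    manifest: ProbeManifest, max_gap: int = 1000, min_probes: int = 2
) -> pd.DataFrame:
    """All maximal <=1 kb-gap probe runs with >= min_probes members.

    This is the region universe before any statistic filtering; enrichment
    null draws sample from it.  The returned frame has columns chrom, start,
    end, n_probes, probe_ids and carries total bp coverage in
    ``.attrs["total_bp"]``.
    """
    rows = []
    for chrom, sub in manifest.table.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        new_run = np.ones(len(sub), dtype=bool)
        new_run[1:] = np.diff(pos) > max_gap
        run_id = np.cumsum(new_run)
        for _, run in sub.groupby(run_id, sort=False):
            if len(run) < min_probes:
                continue
            rows.append(
                {
                    "chrom": str(chrom),
                    "start": int(run["pos"].iloc[0]),
                    "end": int(run["pos"].iloc[-1]),
                    "n_probes": len(run),
                    "probe_ids": ",".join(run["probe_id"]),
                }
            )
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "n_probes", "probe_ids"])
    df = df.sort_values(
        ["chrom", "start"], key=lambda c: c.map(chrom_sort_key) if c.name == "chrom" else c
    ).reset_index(drop=True)
    df.attrs["total_bp"] = int((df["end"] - df["start"] + 1).sum()) if len(df) else 0
    return df
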