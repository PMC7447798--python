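"""Annotation enrichment by genomic resampling, and blood-brain lookups.

Observed statistic: the fraction of called base pairs falling inside each
annotation state (single probes contribute the 2 bp of their CpG
dinucleotide).  The null is the same statistic over random draws from the
background universe matched on element count, element type and (for regions)
probe count within +-1; confidence intervals come from bootstrapping the
called elements; empirical p-values from the permutation tail counts with the
(1 + exceedances) / (k + 1) correction, two-sided by doubling the smaller
tail.

GWAS LD-block overlap is a count statistic: a called element overlaps a block
only with >= 1 bp of direct intersection — adjacency is not enough.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import AnnotationTrack, ProbeManifest, Region

__all__ = [
    "derive_island_context",
    "elements_frame",
    "sequence_overlap_enrichment",
    "ldblock_overlap",
    "bloodbrain_summarize",
]

log = logging.getLogger(__name__)

ISLAND_STATES = ["island", "n_shore", "s_shore", "n_shelf", "s_shelf", "open_sea"]


def derive_island_context(
    islands: AnnotationTrack, chrom_sizes: dict[str, int] | None = None
) -> AnnotationTrack:
    """Expand CpG islands into island / shore / shelf / open-sea states.

    Shores are the 2 kb flanks of an island, shelves the next 2 kb; the
    "north" side is the lower-coordinate side.  Where features of adjacent
    islands would collide, the gap is split at its midpoint so every base is
    assigned to the nearer island.  Flanks are truncated at position 0 and at
    ``chrom_sizes`` when given; open sea fills whatever remains of the
    chromosome span.
    """
    rows = []
    for chrom, grp in islands.intervals.groupby("chrom", sort=False):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        chrom_end = None if chrom_sizes is None else int(chrom_sizes.get(str(chrom), ends[-1] + 4000))
        span_end = chrom_end if chrom_end is not None else int(ends[-1]) + 4000
        feats = []
        for i in range(len(grp)):
            left_lim = 0 if i == 0 else (ends[i - 1] + starts[i]) // 2
            right_lim = span_end if i == len(grp) - 1 else (ends[i] + starts[i + 1]) // 2
            s, e = int(starts[i]), int(ends[i])
            pieces = [
                ("island", s, e),
                ("n_shore", max(s - 2000, left_lim), s),
                ("n_shelf", max(s - 4000, left_lim), max(s - 2000, left_lim)),
                ("s_shore", e, min(e + 2000, right_lim)),
                ("s_shelf", min(e + 2000, right_lim), min(e + 4000, right_lim)),
            ]
            for state, a, b in pieces:
                if b > a:
                    feats.append((a, b, state))
        feats.sort()
        pos = 0
        for a, b, state in feats:
            if a > pos:
                rows.append({"chrom": chrom, "start": pos, "end": a, "state": "open_sea"})
            rows.append({"chrom": chrom, "start": a, "end": b, "state": state})
            pos = b
        if pos < span_end:
            rows.append({"chrom": chrom, "start": pos, "end": span_end, "state": "open_sea"})
    return AnnotationTrack("island_context", pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# coverage arithmetic on non-overlapping interval sets
# ---------------------------------------------------------------------------


class _Coverage:
    """Exact bp-overlap queries against one set of non-overlapping intervals."""

    def __init__(self, intervals: pd.DataFrame) -> None:
        self.by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, grp in intervals.groupby("chrom", sort=False):
            s = np.sort(grp["start"].to_numpy())
            e = grp.sort_values("start")["end"].to_numpy()
            cum = np.concatenate([[0], np.cumsum(e - s)])
            self.by_chrom[str(chrom)] = (s, e, cum)

    def _cum_at(self, chrom: str, x: np.ndarray) -> np.ndarray:
        """Covered bp strictly below each coordinate in x."""
        if chrom not in self.by_chrom:
            return np.zeros(len(x), dtype=float)
        s, e, cum = self.by_chrom[chrom]
        i = np.searchsorted(s, x, side="right")
        j = np.maximum(i - 1, 0)
        partial = np.clip(x - s[j], 0, e[j] - s[j])
        return np.where(i > 0, cum[j] + partial, 0.0)

    def overlap_bp(self, elements: pd.DataFrame) -> np.ndarray:
        out = np.zeros(len(elements))
        for chrom, grp in elements.groupby("chrom", sort=False):
            a = self._cum_at(str(chrom), grp["start"].to_numpy())
            b = self._cum_at(str(chrom), grp["end"].to_numpy())
            out[grp.index.to_numpy()] = b - a
        return out


def _state_overlap_matrix(elements: pd.DataFrame, track: AnnotationTrack) -> pd.DataFrame:
    """bp overlap of each element (rows) with each state (columns)."""
    elements = elements.reset_index(drop=True)
    cols = {}
    for state in track.states:
        cov = _Coverage(track.intervals[track.intervals["state"] == state])
        cols[state] = cov.overlap_bp(elements)
    return pd.DataFrame(cols, index=elements.index)


# ---------------------------------------------------------------------------
# element construction and matched null draws
# ---------------------------------------------------------------------------


def elements_frame(
    regions: list[Region] | None = None,
    probe_ids: list[str] | None = None,
    manifest: ProbeManifest | None = None,
) -> pd.DataFrame:
    """Called regions and probes as 0-based half-open intervals.

    Probes are widened to the 2 bp of their CpG dinucleotide; regions span
    first to last member probe.  Columns: chrom, start, end, element_type,
    n_probes.
    """
    rows = []
    for r in regions or []:
        rows.append(
            {"chrom": r.chrom, "start": r.start - 1, "end": r.end, "element_type": "region",
             "n_probes": r.n_probes}
        )
    if probe_ids:
        if manifest is None:
            raise ValueError("manifest required to locate probes")
        loc = manifest.table.set_index("probe_id").loc[list(probe_ids)]
        for pid, row in loc.iterrows():
            rows.append(
                {"chrom": row["chrom"], "start": int(row["pos"]) - 1, "end": int(row["pos"]) + 1,
                 "element_type": "probe", "n_probes": 1}
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "element_type", "n_probes"])


def _background_elements(background: pd.DataFrame, manifest: ProbeManifest) -> pd.DataFrame:
    """Background universe in element form: all background regions + all probes."""
    reg = pd.DataFrame(
        {
            "chrom": background["chrom"],
            "start": background["start"] - 1,
            "end": background["end"],
            "element_type": "region",
            "n_probes": background["n_probes"],
        }
    )
    prb = pd.DataFrame(
        {
            "chrom": manifest.table["chrom"],
            "start": manifest.table["pos"] - 1,
            "end": manifest.table["pos"] + 1,
            "element_type": "probe",
            "n_probes": 1,
        }
    )
    return pd.concat([reg, prb], ignore_index=True)


def _matched_draw(
    called: pd.DataFrame, bg: pd.DataFrame, rng: np.random.Generator
) -> np.ndarray:
    """Indices into bg: one size/structure-matched draw, without replacement."""
    used: set[int] = set()
    idx = []
    bg_regions = bg.index[bg["element_type"] == "region"]
    bg_probes = bg.index[bg["element_type"] == "probe"].to_numpy()
    np_by_idx = bg["n_probes"]
    for row in called.itertuples(index=False):
        if row.element_type == "probe":
            pool = bg_probes
        else:
            mask = (np_by_idx[bg_regions] - row.n_probes).abs() <= 1
            pool = bg_regions[mask].to_numpy()
            widen = 2
            while pool.size == 0 or len(used.intersection(pool)) == pool.size:
                mask = (np_by_idx[bg_regions] - row.n_probes).abs() <= widen
                pool = bg_regions[mask].to_numpy()
                widen += 1
                if widen > int(np_by_idx.max()) + 2:
                    pool = bg_regions.to_numpy()
                    break
        for _ in range(50):
            pick = int(pool[rng.integers(pool.size)])
            if pick not in used:
                break
        used.add(pick)
        idx.append(pick)
    return np.array(idx, dtype=int)


def _two_sided_empirical(observed: float, null: np.ndarray) -> float:
    k = null.size
    upper = (1 + np.sum(null >= observed)) / (k + 1)
    lower = (1 + np.sum(null <= observed)) / (k + 1)
    return float(min(1.0, 2.0 * min(upper, lower)))


def sequence_overlap_enrichment(
    called: pd.DataFrame,
    background: pd.DataFrame,
    track: AnnotationTrack,
    manifest: ProbeManifest,
    n_resample: int = 1000,
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-state sequence-proportion enrichment of the called set.

    ``called`` is an element frame (see :func:`elements_frame`);
    ``background`` the background-region universe.  Returns one row per state
    with the observed bp proportion, bootstrap 95% CI, the null mean and the
    two-sided empirical p-value.
    """
    if called.empty:
        raise ValueError("called set is empty")
    rng = np.random.default_rng((seed, 21))
    called = called.reset_index(drop=True)
    bg = _background_elements(background, manifest)
    states = track.states
    ov_called = _state_overlap_matrix(called, track)
    ov_bg = _state_overlap_matrix(bg, track)
    len_called = (called["end"] - called["start"]).to_numpy(dtype=float)
    len_bg = (bg["end"] - bg["start"]).to_numpy(dtype=float)
    obs = ov_called.sum(axis=0).to_numpy() / len_called.sum()

    null = np.zeros((n_resample, len(states)))
    for r in range(n_resample):
        idx = _matched_draw(called, bg, rng)
        null[r] = ov_bg.to_numpy()[idx].sum(axis=0) / len_bg[idx].sum()

    boot = np.zeros((n_boot, len(states)))
    n = len(called)
    for b in range(n_boot):
        idx = rng.integers(n, size=n)
        boot[b] = ov_called.to_numpy()[idx].sum(axis=0) / len_called[idx].sum()
    ci_lo, ci_hi = np.percentile(boot, [2.5, 97.5], axis=0)

    rows = []
    for j, state in enumerate(states):
        rows.append(
            {
                "state": state,
                "observed": obs[j],
                "ci_lo": ci_lo[j],
                "ci_hi": ci_hi[j],
                "null_mean": null[:, j].mean(),
                "p": _two_sided_empirical(obs[j], null[:, j]),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class LdOverlapResult:
    observed: int
    ci_lo: float
    ci_hi: float
    p: float
    null_mean: float
    per_block: pd.DataFrame  # chrom, start, end, n_overlapping


def ldblock_overlap(
    called: pd.DataFrame,
    blocks: AnnotationTrack,
    background: pd.DataFrame,
    manifest: ProbeManifest,
    n_resample: int = 1000,
    n_boot: int = 1000,
    seed: int = 0,
) -> LdOverlapResult:
    """Count called elements directly overlapping any GWAS LD block.

    An element counts if it shares >= 1 bp with a block; proximity to a
    boundary does not count.  The null distribution comes from matched
    background draws; the CI from bootstrapping the called elements.
    """
    if called.empty:
        raise ValueError("called set is empty")
    rng = np.random.default_rng((seed, 22))
    called = called.reset_index(drop=True)
    bg = _background_elements(background, manifest)
    cov = _Coverage(blocks.intervals)
    hit_called = cov.overlap_bp(called) > 0
    hit_bg = cov.overlap_bp(bg) > 0
    observed = int(hit_called.sum())

    null = np.zeros(n_resample)
    for r in range(n_resample):
        idx = _matched_draw(called, bg, rng)
        null[r] = hit_bg[idx].sum()

    n = len(called)
    boot = np.zeros(n_boot)
    for b in range(n_boot):
        boot[b] = hit_called[rng.integers(n, size=n)].sum()
    ci_lo, ci_hi = np.percentile(boot, [2.5, 97.5])

    tallies = []
    for row in blocks.intervals.itertuples(index=False):
        one = _Coverage(pd.DataFrame([{"chrom": row.chrom, "start": row.start, "end": row.end}]))
        tallies.append(
            {"chrom": row.chrom, "start": row.start, "end": row.end,
             "n_overlapping": int((one.overlap_bp(called) > 0).sum())}
        )
    return LdOverlapResult(
        observed=observed,
        ci_lo=float(ci_lo),
        ci_hi=float(ci_hi),
        p=_two_sided_empirical(float(observed), null),
        null_mean=float(null.mean()),
        per_block=pd.DataFrame(tallies),
    )


def bloodbrain_summarize(regions: list[Region], rho: pd.Series) -> pd.DataFrame:
    """Median / min / max blood-brain correlation over each region's probes.

    Probes absent from the correlation table are counted in ``n_missing`` and
    excluded from the summaries; a region with no matched probe gets NaN
    summaries and a flag.
    """
    rows = []
    for r in regions:
        vals = rho.reindex(r.probe_ids)
        present = vals.dropna()
        rows.append(
            {
                "chrom": r.chrom,
                "start": r.start,
                "end": r.end,
                "kind": r.kind,
                "n_probes": r.n_probes,
                "median_rho": present.median() if len(present) else np.nan,
                "min_rho": present.min() if len(present) else np.nan,
                "max_rho": present.max() if len(present) else np.nan,
                "n_missing": int(vals.isna().sum()),
                "no_match": len(present) == 0,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "kind", "n_probes", "median_rho", "min_rho",
                 "max_rho", "n_missing", "no_match"],
    )
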