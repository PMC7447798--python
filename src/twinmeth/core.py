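"""Core data types for the twin-pair methylome analysis.

The analysis operates on four kinds of objects: a probe manifest (the genomic
address book of the array), a sample sheet describing the monozygotic twin
pairs and their depression status, a probe x sample methylation matrix (beta
or M scale), and interval annotation tracks.  All containers are thin,
validated wrappers around :class:`pandas.DataFrame`.

Coordinate conventions: probe positions and region bounds are 1-based
inclusive internally; annotation intervals (BED provenance) are 0-based
half-open.  Conversion happens only at the I/O boundary.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "chrom_sort_key",
    "ProbeManifest",
    "SampleSheet",
    "MethylationMatrix",
    "ContrastSpec",
    "default_contrasts",
    "Region",
    "AnnotationTrack",
    "DISCORDANT",
    "CONCORDANT_NEG",
    "CONCORDANT_POS",
]

DISCORDANT = "discordant"
CONCORDANT_NEG = "concordant_negative"
CONCORDANT_POS = "concordant_positive"

_CHROM_RE = re.compile(r"^(chr)?(\d+|[XYM]T?)$", re.IGNORECASE)


def chrom_sort_key(chrom: str) -> tuple:
    """Natural chromosome order: chr1 < chr2 < ... < chr10 < ... < chrX < chrY.

    Unrecognized labels sort after the canonical ones, lexicographically.
    """
    m = _CHROM_RE.match(str(chrom))
    if m:
        body = m.group(2).upper()
        if body.isdigit():
            return (0, int(body), "")
        order = {"X": 23, "Y": 24, "M": 25, "MT": 25}
        return (0, order[body], "")
    return (1, 0, str(chrom))


def _natural_chrom_order(chroms: Iterable[str]) -> pd.Categorical:
    levels = sorted(set(map(str, chroms)), key=chrom_sort_key)
    return pd.Categorical([str(c) for c in chroms], categories=levels, ordered=True)


@dataclass
class ProbeManifest:
    """Array probe coordinates: one row per probe, sorted by (chrom, pos).

    Columns: ``probe_id`` (unique), ``chrom``, ``pos`` (1-based bp of the
    interrogated CpG).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        required = {"probe_id", "chrom", "pos"}
        missing = required - set(t.columns)
        if missing:
            raise ValueError(f"manifest missing columns: {sorted(missing)}")
        dup = t["probe_id"][t["probe_id"].duplicated()]
        if len(dup):
            raise ValueError(f"duplicate probe_id in manifest: {dup.iloc[0]!r}")
        if (t["pos"] < 1).any():
            bad = t.loc[t["pos"] < 1, "probe_id"].iloc[0]
            raise ValueError(f"probe {bad!r} has position < 1")
        t = t.copy()
        t["pos"] = t["pos"].astype(np.int64)
        t["chrom"] = t["chrom"].astype(str)
        key = t["chrom"].map(chrom_sort_key)
        t = t.loc[sorted(t.index, key=lambda i: (key[i], t["pos"][i]))]
        self.table = t.reset_index(drop=True)

    @property
    def probe_ids(self) -> pd.Index:
        return pd.Index(self.table["probe_id"])

    def __len__(self) -> int:
        return len(self.table)

    def positions_for(self, probe_ids: Iterable[str]) -> pd.DataFrame:
        """Subset rows for the given probes, keeping genomic order."""
        sub = self.table[self.table["probe_id"].isin(set(probe_ids))]
        return sub.reset_index(drop=True)


@dataclass
class SampleSheet:
    """Twin cohort description, one row per sample.

    Columns: ``sample_id``, ``pair_id``, ``twin_index`` in {1, 2},
    ``md_status`` in {0, 1} (1 = affected by major depression), ``nk_prop``
    (natural-killer-cell proportion in [0, 1]) and ``slide`` (batch label).
    Each pair must appear exactly twice, once per twin index.  The pair
    concordance class (discordant / concordant-negative / concordant-positive)
    is derived on construction and cached in :attr:`pairs`.
    """

    table: pd.DataFrame
    pairs: pd.DataFrame = field(init=False)

    def __post_init__(self) -> None:
        t = self.table
        required = {"sample_id", "pair_id", "twin_index", "md_status", "nk_prop", "slide"}
        missing = required - set(t.columns)
        if missing:
            raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
        t = t.copy()
        t["twin_index"] = t["twin_index"].astype(int)
        t["md_status"] = t["md_status"].astype(int)
        if t["sample_id"].duplicated().any():
            raise ValueError("duplicate sample_id in sample sheet")
        if not t["twin_index"].isin([1, 2]).all():
            raise ValueError("twin_index must be 1 or 2")
        if not t["md_status"].isin([0, 1]).all():
            raise ValueError("md_status must be 0 or 1")
        if ((t["nk_prop"] < 0) | (t["nk_prop"] > 1)).any():
            bad = t.loc[(t["nk_prop"] < 0) | (t["nk_prop"] > 1), "sample_id"].iloc[0]
            raise ValueError(f"nk_prop outside [0, 1] for sample {bad!r}")
        for pid, grp in t.groupby("pair_id", sort=False):
            if len(grp) != 2:
                raise ValueError(f"pair {pid!r} has {len(grp)} members; expected 2")
            if set(grp["twin_index"]) != {1, 2}:
                raise ValueError(f"pair {pid!r} twin_index values are not {{1, 2}}")
        t = t.sort_values(["pair_id", "twin_index"], kind="stable").reset_index(drop=True)
        self.table = t
        n_aff = t.groupby("pair_id", sort=False)["md_status"].sum()
        cls = n_aff.map({0: CONCORDANT_NEG, 1: DISCORDANT, 2: CONCORDANT_POS})
        self.pairs = pd.DataFrame({"pair_id": n_aff.index, "concordance": cls.values})

    @property
    def sample_ids(self) -> pd.Index:
        return pd.Index(self.table["sample_id"])

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def class_counts(self) -> dict[str, int]:
        c = self.pairs["concordance"].value_counts()
        return {
            DISCORDANT: int(c.get(DISCORDANT, 0)),
            CONCORDANT_NEG: int(c.get(CONCORDANT_NEG, 0)),
            CONCORDANT_POS: int(c.get(CONCORDANT_POS, 0)),
        }


@dataclass
class MethylationMatrix:
    """Probe x sample methylation values with a transform provenance log.

    ``scale`` is ``"beta"`` (values in [0, 1]) or ``"M"`` (logit scale).
    """

    values: pd.DataFrame
    scale: str
    transform_log: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.scale not in ("beta", "M"):
            raise ValueError(f"scale must be 'beta' or 'M', got {self.scale!r}")
        if self.scale == "beta":
            v = self.values.to_numpy()
            if np.nanmin(v) < 0 or np.nanmax(v) > 1:
                raise ValueError("beta values must lie in [0, 1]")

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def logged(self, step: str) -> "MethylationMatrix":
        return MethylationMatrix(self.values, self.scale, [*self.transform_log, step])


@dataclass(frozen=True)
class ContrastSpec:
    """One of the five statistical contrasts fit per probe."""

    contrast_id: int
    description: str
    is_interest: bool = False


def default_contrasts() -> list[ContrastSpec]:
    """The default contrast set for the three-class twin design.

    Contrast 1 (the effect of interest) compares affected with unaffected
    twins using all pairs.  Contrasts 2-5 are negative controls: they compare
    groups between which no depression-specific methylation difference is
    expected, and probes reacting to them are filtered out.
    """
    return [
        ContrastSpec(1, "MD affected vs unaffected (all pairs)", True),
        ContrastSpec(2, "concordant-positive twins vs affected twins of discordant pairs"),
        ContrastSpec(3, "concordant-negative twins vs unaffected twins of discordant pairs"),
        ContrastSpec(4, "twin 1 vs twin 2 within concordant-negative pairs"),
        ContrastSpec(5, "twin 1 vs twin 2 within concordant-positive pairs"),
    ]


def validate_contrasts(specs: list[ContrastSpec]) -> None:
    n_interest = sum(s.is_interest for s in specs)
    if n_interest != 1:
        raise ValueError(f"exactly one contrast must be of interest, got {n_interest}")


@dataclass
class Region:
    """A contiguous same-direction run of probes with its trapezoidal score.

    ``start``/``end`` are the 1-based positions of the first and last member
    probes; consecutive members are at most 1 kb apart and share the sign of
    their univariate statistic.  ``auc`` is the trapezoidal area of influence:
    for consecutive probes with statistics a, b separated by h bp the
    contribution is h * (|a| + |b|) / 2, summed along the region.
    """

    chrom: str
    start: int
    end: int
    probe_ids: list[str]
    kind: str  # "DMR" | "VMR"
    direction: str  # hyper/hypo or more_variable/less_variable
    auc: float = np.nan
    n_probes: int = 0
    fdr: float = np.nan

    def __post_init__(self) -> None:
        if self.kind not in ("DMR", "VMR"):
            raise ValueError(f"kind must be DMR or VMR, got {self.kind!r}")
        if self.n_probes == 0:
            self.n_probes = len(self.probe_ids)
        if self.n_probes < 2:
            raise ValueError("a region needs at least 2 member probes")
        if self.end < self.start:
            raise ValueError("region end before start")


def regions_to_frame(regions: list[Region]) -> pd.DataFrame:
    rows = [
        {
            "chrom": r.chrom,
            "start": r.start,
            "end": r.end,
            "kind": r.kind,
            "direction": r.direction,
            "n_probes": r.n_probes,
            "auc": r.auc,
            "fdr": r.fdr,
            "probe_ids": ",".join(r.probe_ids),
        }
        for r in regions
    ]
    cols = ["chrom", "start", "end", "kind", "direction", "n_probes", "auc", "fdr", "probe_ids"]
    return pd.DataFrame(rows, columns=cols)


@dataclass
class AnnotationTrack:
    """A named set of (chrom, start, end[, state]) intervals, 0-based half-open.

    Intervals sharing one (chrom, state) must be non-overlapping after
    normalization; this is validated on construction.
    """

    name: str
    intervals: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.intervals.copy()
        required = {"chrom", "start", "end"}
        missing = required - set(t.columns)
        if missing:
            raise ValueError(f"annotation track missing columns: {sorted(missing)}")
        if "state" not in t.columns:
            t["state"] = self.name
        t["start"] = t["start"].astype(np.int64)
        t["end"] = t["end"].astype(np.int64)
        if (t["end"] <= t["start"]).any():
            raise ValueError("annotation intervals must have end > start")
        key = t["chrom"].map(chrom_sort_key)
        t = t.loc[sorted(t.index, key=lambda i: (key[i], t["start"][i]))].reset_index(drop=True)
        for (chrom, state), grp in t.groupby(["chrom", "state"], sort=False):
            if (grp["start"].to_numpy()[1:] < grp["end"].to_numpy()[:-1]).any():
                raise ValueError(f"overlapping intervals in track {self.name!r} ({chrom}, {state})")
        self.intervals = t

    @property
    def states(self) -> list[str]:
        return list(dict.fromkeys(self.intervals["state"]))

    def total_bp(self, state: str | None = None) -> int:
        t = self.intervals
        if state is not None:
            t = t[t["state"] == state]
        return int((t["end"] - t["start"]).sum())
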