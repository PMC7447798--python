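"""Synthetic twin methylome generator.

Emulates the statistical structure the downstream analysis assumes: a 450K-like
probe layout where most probes sit in tight clusters but about a quarter are
isolated (no neighbor within 1 kb); a cohort of monozygotic twin pairs split
into discordant, concordant-unaffected and concordant-affected classes
(defaults 27 / 42 / 6, i.e. 150 samples); M-value matrices with a shared
within-pair component, slide batch shifts, an NK-cell-proportion covariate
component, and injected case effects: regional mean shifts (hyper/hypo
methylation in affected twins) and regional variance inflation.

Effects are injected additively on the M scale.  Affected twins in
concordant-positive pairs carry the case effect in both twins, matching the
twin design's premise that the shared background plus the disease effect,
not twin identity, drives the signal.

Everything is driven by one integer seed through ``numpy.random.default_rng``;
identical config + seed reproduces identical outputs bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .core import MethylationMatrix, ProbeManifest, SampleSheet, AnnotationTrack
from .preprocess import m_to_beta

__all__ = [
    "InjectedDMR",
    "InjectedVMR",
    "SimulationConfig",
    "simulate_manifest",
    "simulate_cohort",
    "simulate_methylation",
    "SimulationResult",
    "simulate_chromhmm",
    "simulate_cpg_islands",
    "simulate_ld_blocks",
    "simulate_rho_table",
]


@dataclass(frozen=True)
class InjectedDMR:
    """A ground-truth differentially methylated region to plant.

    ``min_span``/``max_span`` constrain the bp extent of the host probe run;
    defaults bracket the spans reported for real array DMRs (roughly half a
    kilobase to two kilobases).
    """

    n_probes: int = 4
    delta: float = 0.4  # case mean shift, M units
    direction: str = "hyper"  # or "hypo"
    min_span: int = 500
    max_span: int = 2500


@dataclass(frozen=True)
class InjectedVMR:
    """A ground-truth variably methylated region to plant."""

    n_probes: int = 4
    var_ratio: float = 4.0  # case variance / control variance
    min_span: int = 500
    max_span: int = 2500


@dataclass
class SimulationConfig:
    """Stated world for the synthetic cohort.

    Pair composition defaults to 27 discordant / 42 concordant-negative /
    6 concordant-positive pairs (150 twins).  ``pair_icc`` is the within-pair
    correlation of M-values attributable to the shared pair component alone,
    sigma_pair^2 / (sigma_pair^2 + noise_sd^2); slide and NK components are
    additional shared structure on top of it.
    """

    n_pairs_discordant: int = 27
    n_pairs_concneg: int = 42
    n_pairs_concpos: int = 6
    n_probes: int = 10_000
    isolated_fraction: float = 0.25
    within_cluster_gap_mean: float = 250.0  # bp, truncated exponential in [2, 1000]
    between_cluster_gap_mean: float = 20_000.0  # bp beyond the 1 kb isolation floor
    cluster_size_mean: float = 4.0  # cluster sizes ~ 2 + Poisson(mean - 2)
    n_chroms: int = 22
    chrom_length: int | None = None  # optional hard span; exceeded -> error
    pair_icc: float = 0.5
    noise_sd: float = 0.25  # residual SD on the M scale
    slide_effect_sd: float = 0.1
    pairs_per_slide: int = 6  # one 450K BeadChip holds 12 samples
    nk_range: tuple[float, float] = (0.02, 0.12)
    nk_case_shift: float = 0.0  # optional NK confounding (mean shift in cases)
    nk_coef_sd: float = 0.0  # per-probe slope of M on NK proportion
    injected_dmrs: list[InjectedDMR] = field(default_factory=list)
    injected_vmrs: list[InjectedVMR] = field(default_factory=list)
    beta_offset: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_pairs_discordant, self.n_pairs_concneg, self.n_pairs_concpos) < 0:
            raise ValueError("pair counts must be nonnegative")
        if self.n_pairs_discordant + self.n_pairs_concneg + self.n_pairs_concpos < 1:
            raise ValueError("at least one twin pair required")
        if not 0 < self.pair_icc < 1:
            raise ValueError("pair_icc must be in (0, 1)")
        if not 0 <= self.isolated_fraction < 1:
            raise ValueError("isolated_fraction must be in [0, 1)")
        for v in self.injected_vmrs:
            if v.var_ratio <= 0:
                raise ValueError("var_ratio must be positive")

    @property
    def n_pairs(self) -> int:
        return self.n_pairs_discordant + self.n_pairs_concneg + self.n_pairs_concpos

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng((self.seed, stream))


def _cluster_sizes(cfg: SimulationConfig, rng: np.random.Generator) -> list[int]:
    """Partition probes into singletons (isolated) and clusters of >= 2."""
    n_isolated = int(round(cfg.isolated_fraction * cfg.n_probes))
    n_clustered = cfg.n_probes - n_isolated
    if n_clustered == 1:  # a lone leftover cannot form a cluster
        n_isolated += 1
        n_clustered = 0
    sizes: list[int] = []
    remaining = n_clustered
    lam = max(cfg.cluster_size_mean - 2.0, 0.0)
    while remaining > 0:
        s = 2 + int(rng.poisson(lam))
        if remaining - s == 1:  # never strand a single probe
            s += 1
        s = min(s, remaining)
        if s == 1:
            sizes[-1] += 1
            remaining = 0
            break
        sizes.append(s)
        remaining -= s
    blocks = sizes + [1] * n_isolated
    perm = rng.permutation(len(blocks))
    return [blocks[i] for i in perm]


def simulate_manifest(cfg: SimulationConfig) -> ProbeManifest:
    """Clustered probe placement with a controlled isolated-probe fraction.

    Probes are laid down block by block: within a block consecutive gaps are
    <= 1 kb (truncated-exponential spacing), and blocks are separated by
    > 1 kb, so a size-1 block is an isolated probe by construction.
    """
    if cfg.n_probes < 2:
        raise ValueError("need at least 2 probes")
    rng = cfg.rng(1)
    blocks = _cluster_sizes(cfg, rng)
    # deal blocks across chromosomes round-robin so each chrom gets a share
    n_chroms = min(cfg.n_chroms, len(blocks))
    per_chrom: list[list[int]] = [[] for _ in range(n_chroms)]
    for i, b in enumerate(blocks):
        per_chrom[i % n_chroms].append(b)
    records = []
    probe_no = 0
    for ci, chrom_blocks in enumerate(per_chrom, start=1):
        pos = 0
        chrom = f"chr{ci}"
        for b in chrom_blocks:
            pos += 1001 + int(rng.exponential(cfg.between_cluster_gap_mean))
            for k in range(b):
                if k > 0:
                    gap = 2 + int(rng.exponential(cfg.within_cluster_gap_mean))
                    pos += min(gap, 1000)
                records.append((f"cg{probe_no:07d}", chrom, pos))
                probe_no += 1
        if cfg.chrom_length is not None and pos > cfg.chrom_length:
            raise ValueError(
                f"infeasible geometry: {chrom} needs {pos} bp but chrom_length={cfg.chrom_length}"
            )
    df = pd.DataFrame(records, columns=["probe_id", "chrom", "pos"])
    return ProbeManifest(df)


def simulate_cohort(cfg: SimulationConfig) -> SampleSheet:
    """Twin-pair sample sheet with the configured concordance composition.

    Both twins of a pair share a slide; within a discordant pair the affected
    twin is chosen at random.  NK proportions are uniform on ``nk_range`` with
    an optional mean shift in affected twins (clipped back to [0, 1]).
    """
    rng = cfg.rng(2)
    classes = (
        ["discordant"] * cfg.n_pairs_discordant
        + ["concordant_negative"] * cfg.n_pairs_concneg
        + ["concordant_positive"] * cfg.n_pairs_concpos
    )
    # randomize pairs onto slides, as a real plating protocol would
    slide_order = rng.permutation(len(classes))
    rows = []
    for p, cls in enumerate(classes):
        pair_id = f"P{p + 1:03d}"
        slide = f"S{slide_order[p] // cfg.pairs_per_slide + 1:02d}"
        if cls == "discordant":
            affected_twin = int(rng.integers(1, 3))
            status = {1: 0, 2: 0}
            status[affected_twin] = 1
        elif cls == "concordant_negative":
            status = {1: 0, 2: 0}
        else:
            status = {1: 1, 2: 1}
        for twin in (1, 2):
            nk = float(rng.uniform(*cfg.nk_range))
            if status[twin] == 1:
                nk = float(np.clip(nk + cfg.nk_case_shift, 0.0, 1.0))
            rows.append(
                {
                    "sample_id": f"{pair_id}_T{twin}",
                    "pair_id": pair_id,
                    "twin_index": twin,
                    "md_status": status[twin],
                    "nk_prop": nk,
                    "slide": slide,
                }
            )
    return SampleSheet(pd.DataFrame(rows))


def _contiguous_runs(manifest: ProbeManifest, max_gap: int = 1000) -> list[pd.DataFrame]:
    runs = []
    for _, sub in manifest.table.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        breaks = np.flatnonzero(np.diff(pos) > max_gap) + 1
        for chunk in np.split(np.arange(len(sub)), breaks):
            if len(chunk) >= 2:
                runs.append(sub.iloc[chunk])
    return runs


def _place_regions(
    specs: list, manifest: ProbeManifest, rng: np.random.Generator, taken: set[str]
) -> list[dict]:
    """Assign each injected-region spec a disjoint run of clustered probes."""
    runs = _contiguous_runs(manifest)
    order = rng.permutation(len(runs))
    placements = []
    for spec in specs:
        placed = False
        for ri in order:
            run = runs[ri]
            if len(run) < spec.n_probes:
                continue
            ids = run["probe_id"].tolist()
            if any(i in taken for i in ids):
                continue
            pos = run["pos"].to_numpy()
            spans = pos[spec.n_probes - 1 :] - pos[: len(pos) - spec.n_probes + 1]
            eligible = np.flatnonzero((spans >= spec.min_span) & (spans <= spec.max_span))
            if eligible.size == 0:
                continue
            start_idx = int(eligible[rng.integers(eligible.size)])
            members = run.iloc[start_idx : start_idx + spec.n_probes]
            taken.update(members["probe_id"])
            placements.append({"spec": spec, "members": members})
            placed = True
            break
        if not placed:
            raise ValueError(
                f"cannot place injected region: no free probe run with {spec.n_probes} probes "
                f"spanning {spec.min_span}-{spec.max_span} bp in the manifest"
            )
    return placements


@dataclass
class SimulationResult:
    m_matrix: MethylationMatrix
    beta_matrix: MethylationMatrix
    truth: pd.DataFrame  # chrom, start, end, kind, effect, n_probes, probe_ids


def simulate_methylation(
    cfg: SimulationConfig, manifest: ProbeManifest, sheet: SampleSheet
) -> SimulationResult:
    """Simulate the probe x sample M-value matrix plus its ground truth.

    Model per probe i, sample s in pair j on slide b:

        M_is = mu_i + u_ij + g_ib + c_i * (nk_s - nk_bar) + delta_i * md_s + e_is

    with u ~ N(0, sigma_p^2) shared by the twins of a pair,
    sigma_p^2 = noise_sd^2 * icc / (1 - icc), g a slide shift, and e the
    residual.  Inside an injected variance region, affected samples receive an
    extra independent deviation sized so their total variance is ``var_ratio``
    times the control total variance.
    """
    rng = cfg.rng(3)
    n_probes = len(manifest)
    probes = manifest.probe_ids
    samples = sheet.sample_ids
    n_samples = len(samples)

    # bimodal-ish baseline: mostly un/fully methylated CpGs plus a middle band
    comp = rng.choice(3, size=n_probes, p=[0.4, 0.2, 0.4])
    base_beta = np.where(
        comp == 0,
        rng.beta(2, 18, n_probes),
        np.where(comp == 1, rng.beta(5, 5, n_probes), rng.beta(18, 2, n_probes)),
    )
    off = cfg.beta_offset
    mu = np.log2((base_beta + off) / (1 - base_beta + off))

    pair_ids = sheet.table["pair_id"].to_numpy()
    pair_levels, pair_idx = np.unique(pair_ids, return_inverse=True)
    slide_levels, slide_idx = np.unique(sheet.table["slide"].to_numpy(), return_inverse=True)
    md = sheet.table["md_status"].to_numpy().astype(float)
    nk = sheet.table["nk_prop"].to_numpy()

    sigma_p = cfg.noise_sd * np.sqrt(cfg.pair_icc / (1 - cfg.pair_icc))
    u = rng.normal(0.0, sigma_p, size=(n_probes, len(pair_levels)))
    g = rng.normal(0.0, cfg.slide_effect_sd, size=(n_probes, len(slide_levels)))
    c = rng.normal(0.0, cfg.nk_coef_sd, size=n_probes) if cfg.nk_coef_sd > 0 else np.zeros(n_probes)

    M = (
        mu[:, None]
        + u[:, pair_idx]
        + g[:, slide_idx]
        + np.outer(c, nk - nk.mean())
        + rng.normal(0.0, cfg.noise_sd, size=(n_probes, n_samples))
    )

    taken: set[str] = set()
    truth_rows = []
    probe_loc = pd.Series(np.arange(n_probes), index=probes)

    placements = _place_regions(list(cfg.injected_dmrs), manifest, rng, taken)
    for pl in placements:
        spec, members = pl["spec"], pl["members"]
        sgn = 1.0 if spec.direction == "hyper" else -1.0
        rows = probe_loc[members["probe_id"]].to_numpy()
        M[np.ix_(rows, np.flatnonzero(md == 1))] += sgn * spec.delta
        truth_rows.append(
            {
                "chrom": members["chrom"].iloc[0],
                "start": int(members["pos"].min()),
                "end": int(members["pos"].max()),
                "kind": "DMR",
                "effect": sgn * spec.delta,
                "n_probes": len(members),
                "probe_ids": ",".join(members["probe_id"]),
            }
        )

    total_var = sigma_p**2 + cfg.slide_effect_sd**2 + cfg.noise_sd**2
    placements = _place_regions(list(cfg.injected_vmrs), manifest, rng, taken)
    for pl in placements:
        spec, members = pl["spec"], pl["members"]
        rows = probe_loc[members["probe_id"]].to_numpy()
        cases = np.flatnonzero(md == 1)
        extra_sd = np.sqrt(max(spec.var_ratio - 1.0, 0.0) * total_var)
        M[np.ix_(rows, cases)] += rng.normal(0.0, extra_sd, size=(len(rows), len(cases)))
        truth_rows.append(
            {
                "chrom": members["chrom"].iloc[0],
                "start": int(members["pos"].min()),
                "end": int(members["pos"].max()),
                "kind": "VMR",
                "effect": spec.var_ratio,
                "n_probes": len(members),
                "probe_ids": ",".join(members["probe_id"]),
            }
        )

    mvals = pd.DataFrame(M, index=probes, columns=samples)
    m_matrix = MethylationMatrix(mvals, "M", ["simulated"])
    beta = m_to_beta(m_matrix, offset=off)
    truth = pd.DataFrame(
        truth_rows,
        columns=["chrom", "start", "end", "kind", "effect", "n_probes", "probe_ids"],
    )
    return SimulationResult(m_matrix, beta, truth)


# ---------------------------------------------------------------------------
# Synthetic annotation tracks (for exercising the enrichment stage without
# external downloads).  These emulate shape, not biology.
# ---------------------------------------------------------------------------

_CHROMHMM_STATES = (
    "TssA", "TxStrong", "Enh", "EnhG", "ZNF/Rpts", "Het", "ReprPC", "Quies",
)


def _chrom_spans(manifest: ProbeManifest, pad: int = 5000) -> pd.DataFrame:
    g = manifest.table.groupby("chrom", sort=False)["pos"]
    return pd.DataFrame(
        {"chrom": g.min().index, "start": np.maximum(g.min().to_numpy() - pad, 0),
         "end": g.max().to_numpy() + pad}
    )


def simulate_chromhmm(
    manifest: ProbeManifest,
    seed: int,
    states: tuple[str, ...] = _CHROMHMM_STATES,
    mean_len: float = 10_000.0,
) -> AnnotationTrack:
    """Tile each chromosome span with random-length chromatin-state segments."""
    rng = np.random.default_rng((seed, 11))
    rows = []
    for span in _chrom_spans(manifest).itertuples(index=False):
        pos = int(span.start)
        while pos < span.end:
            seg = 200 + int(rng.exponential(mean_len))
            end = min(pos + seg, int(span.end))
            rows.append({"chrom": span.chrom, "start": pos, "end": end,
                         "state": states[int(rng.integers(len(states)))]})
            pos = end
    return AnnotationTrack("chromhmm_synthetic", pd.DataFrame(rows))


def simulate_cpg_islands(manifest: ProbeManifest, seed: int, fraction: float = 0.3) -> AnnotationTrack:
    """Declare a random subset of probe clusters to be CpG islands."""
    rng = np.random.default_rng((seed, 12))
    rows = []
    for run in _contiguous_runs(manifest):
        if rng.random() < fraction:
            rows.append(
                {"chrom": run["chrom"].iloc[0], "start": int(run["pos"].min()) - 1,
                 "end": int(run["pos"].max()), "state": "island"}
            )
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "state"])
    return AnnotationTrack("cpg_islands_synthetic", df)


def simulate_ld_blocks(
    manifest: ProbeManifest, seed: int, n_blocks: int = 44, mean_len: float = 200_000.0
) -> AnnotationTrack:
    """Random non-overlapping LD-block intervals across the manifest's chromosomes."""
    rng = np.random.default_rng((seed, 13))
    spans = _chrom_spans(manifest)
    rows = []
    for _ in range(n_blocks):
        span = spans.iloc[int(rng.integers(len(spans)))]
        length = 10_000 + int(rng.exponential(mean_len))
        lo = int(span.start)
        hi = max(int(span.end) - length, lo + 1)
        start = int(rng.integers(lo, hi))
        rows.append({"chrom": span.chrom, "start": start, "end": start + length})
    df = pd.DataFrame(rows).sort_values(["chrom", "start"]).reset_index(drop=True)
    # merge overlaps within chromosome so the track is valid
    merged = []
    for chrom, grp in df.groupby("chrom", sort=False):
        cur = None
        for row in grp.itertuples(index=False):
            if cur is None or row.start > cur[2]:
                if cur is not None:
                    merged.append(cur)
                cur = [chrom, row.start, row.end]
            else:
                cur[2] = max(cur[2], row.end)
        if cur is not None:
            merged.append(cur)
    out = pd.DataFrame(merged, columns=["chrom", "start", "end"])
    out["state"] = "ld_block"
    return AnnotationTrack("ld_blocks_synthetic", out)


def simulate_rho_table(manifest: ProbeManifest, seed: int, missing_fraction: float = 0.02) -> pd.Series:
    """Per-CpG blood-brain Spearman correlations, a few probes missing."""
    rng = np.random.default_rng((seed, 14))
    rho = np.clip(rng.normal(0.15, 0.35, len(manifest)), -0.95, 0.95)
    keep = rng.random(len(manifest)) >= missing_fraction
    s = pd.Series(rho[keep], index=manifest.probe_ids[keep], name="rho")
    s.index.name = "probe_id"
    return s


def config_to_dict(cfg: SimulationConfig) -> dict:
    return asdict(cfg)
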