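"""End-to-end orchestration: simulate -> preprocess -> probe tests ->
permutation study -> probe/region calls -> enrichment -> blood-brain -> report.

Every stage reads its inputs from and writes its outputs to one results
directory, so stages can be re-run individually from the command line.  A run
manifest (JSON) records the config hash, master seed, package versions and
the completion status of each stage; identical config + seed reproduces every
table byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import platform
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import Region, chrom_sort_key
from . import io as tio
from .enrichment import (
    bloodbrain_summarize,
    derive_island_context,
    elements_frame,
    ldblock_overlap,
    sequence_overlap_enrichment,
)
from .permutation import PermutationNull, run_permutation_study, sam_region_fdr
from .preprocess import adjust_batch, beta_to_m, filter_probes, pca_batch_report, quantile_normalize
from .probes import call_probes, compute_probe_stats
from .regions import build_background_regions, build_candidate_regions, score_regions, select_region_probes
from .simulate import (
    InjectedDMR,
    InjectedVMR,
    SimulationConfig,
    simulate_chromhmm,
    simulate_cohort,
    simulate_cpg_islands,
    simulate_ld_blocks,
    simulate_manifest,
    simulate_methylation,
    simulate_rho_table,
)

log = logging.getLogger(__name__)

STAGES = [
    "simulate",
    "preprocess",
    "test_probes",
    "permute",
    "call",
    "enrich",
    "bloodbrain",
    "report",
]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "simulate": {},  # SimulationConfig fields; set to None to consume external inputs
    "inputs": {},  # external file paths when simulate is disabled
    "preprocess": {"offset": 0.001, "quantile_normalize": True, "adjust_batch": True},
    "permutations": {"k": 1000, "checkpoint_every": 100},
    "calling": {
        "dmp_fdr": 0.01,
        "vmp_fdr": 0.01,
        "dmr_fdr": 0.10,
        "vmr_fdr": 0.17,
        "nuisance_alpha": 0.05,
        "max_gap": 1000,
        "min_probes": 2,
        "trim_quantile": 0.001,
    },
    "enrichment": {"n_resample": 1000, "n_boot": 1000},
}


class ConfigError(ValueError):
    """Raised for invalid configuration (CLI exit code 2)."""


def load_config(path_or_dict) -> dict:
    """Load and validate a YAML config against the default schema."""
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict) as fh:
            user = yaml.safe_load(fh) or {}
    else:
        user = dict(path_or_dict or {})
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    unknown = set(user) - set(cfg)
    if unknown:
        raise ConfigError(f"unknown config sections: {sorted(unknown)}")
    for key, val in user.items():
        if isinstance(cfg.get(key), dict) and isinstance(val, dict):
            sub_known = set(cfg[key]) | (
                {f.name for f in dataclasses.fields(SimulationConfig)} if key == "simulate" else set()
            )
            if key not in ("simulate", "inputs"):
                bad = set(val) - set(cfg[key])
                if bad:
                    raise ConfigError(f"unknown keys in config section {key!r}: {sorted(bad)}")
            elif key == "simulate":
                bad = set(val) - sub_known
                if bad:
                    raise ConfigError(f"unknown simulate keys: {sorted(bad)}")
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _sim_config(cfg: dict) -> SimulationConfig:
    d = dict(cfg["simulate"] or {})
    d.setdefault("seed", cfg["seed"])
    dmrs = [InjectedDMR(**x) if isinstance(x, dict) else x for x in d.pop("injected_dmrs", [])]
    vmrs = [InjectedVMR(**x) if isinstance(x, dict) else x for x in d.pop("injected_vmrs", [])]
    if "nk_range" in d:
        d["nk_range"] = tuple(d["nk_range"])
    return SimulationConfig(injected_dmrs=dmrs, injected_vmrs=vmrs, **d)


class PipelineRun:
    """One results directory plus the config that drives it."""

    def __init__(self, outdir: str | Path, config: dict | str | Path | None = None) -> None:
        self.outdir = Path(outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.cfg = load_config(config)
        self.manifest_path = self.outdir / "run_manifest.json"
        if self.manifest_path.exists():
            with open(self.manifest_path) as fh:
                self.run_manifest = json.load(fh)
        else:
            self.run_manifest = {
                "config_hash": config_hash(self.cfg),
                "seed": self.cfg["seed"],
                "versions": {
                    "twinmeth": __version__,
                    "python": platform.python_version(),
                    "numpy": np.__version__,
                    "pandas": pd.__version__,
                },
                "stages": {},
            }

    # -- bookkeeping --------------------------------------------------------
    def _mark(self, stage: str, **info) -> None:
        self.run_manifest["stages"][stage] = {"status": "complete", **info}
        with open(self.manifest_path, "w") as fh:
            json.dump(self.run_manifest, fh, indent=2, sort_keys=True)

    def _path(self, name: str) -> Path:
        return self.outdir / name

    def _input_path(self, key: str, produced: str) -> Path:
        ext = self.cfg["inputs"].get(key)
        return Path(ext) if ext else self._path(produced)

    # -- stages -------------------------------------------------------------
    def simulate(self) -> None:
        if self.cfg["simulate"] is None:
            log.info("simulate stage disabled; consuming external inputs")
            self._mark("simulate", skipped=True)
            return
        sim = _sim_config(self.cfg)
        manifest = simulate_manifest(sim)
        sheet = simulate_cohort(sim)
        result = simulate_methylation(sim, manifest, sheet)
        tio.write_manifest(manifest, self._path("manifest.tsv"))
        tio.write_sample_sheet(sheet, self._path("samples.tsv"))
        tio.write_matrix(result.beta_matrix, self._path("beta.tsv"))
        result.truth.to_csv(self._path("truth.tsv"), sep="\t", index=False)
        with open(self._path("truth.bed"), "w") as fh:
            for row in result.truth.itertuples(index=False):
                fh.write(f"{row.chrom}\t{row.start - 1}\t{row.end}\t{row.kind}\t{row.effect:.4g}\t.\n")
        tio.write_annotation_bed(simulate_chromhmm(manifest, sim.seed), self._path("chromhmm.bed"))
        tio.write_annotation_bed(simulate_cpg_islands(manifest, sim.seed), self._path("islands.bed"))
        tio.write_annotation_bed(simulate_ld_blocks(manifest, sim.seed), self._path("ldblocks.bed"))
        rho = simulate_rho_table(manifest, sim.seed)
        rho.reset_index().to_csv(self._path("rho.tsv"), sep="\t", index=False)
        self._mark("simulate", n_probes=len(manifest), n_samples=len(sheet.table),
                   n_truth_regions=len(result.truth))

    def preprocess(self) -> None:
        pp = self.cfg["preprocess"]
        beta = tio.read_matrix(self._input_path("beta", "beta.tsv"), scale="beta")
        sheet = tio.read_sample_sheet(self._input_path("samples", "samples.tsv"))
        det_path = self.cfg["inputs"].get("detection_p")
        detection = pd.read_csv(det_path, sep="\t", index_col=0) if det_path else None
        ch_path = self.cfg["inputs"].get("crosshyb")
        crosshyb = set(Path(ch_path).read_text().split()) if ch_path else set()
        beta, report = filter_probes(beta, detection, crosshyb)
        report.to_csv(self._path("probe_removals.tsv"), sep="\t", index=False)
        if pp["quantile_normalize"]:
            beta = quantile_normalize(beta)
        m = beta_to_m(beta, offset=pp["offset"])
        if pp["adjust_batch"]:
            m = adjust_batch(m, sheet)
        pca_batch_report(m, sheet).to_csv(self._path("pca_report.tsv"), sep="\t", index=False)
        tio.write_matrix(m, self._path("mvals.tsv"))
        with open(self._path("transform_log.txt"), "w") as fh:
            fh.write("\n".join(m.transform_log) + "\n")
        self._mark("preprocess", n_probes=len(m.probe_ids), n_removed=len(report))

    def test_probes(self) -> None:
        m = tio.read_matrix(self._path("mvals.tsv"), scale="M")
        sheet = tio.read_sample_sheet(self._input_path("samples", "samples.tsv"))
        stats = compute_probe_stats(m, sheet)
        stats.to_csv(self._path("probe_stats.tsv"), sep="\t", index=False, float_format="%.10g")
        self._mark("test_probes", n_probes=len(stats))

    def permute(self) -> None:
        pm = self.cfg["permutations"]
        call_cfg = self.cfg["calling"]
        m = tio.read_matrix(self._path("mvals.tsv"), scale="M")
        sheet = tio.read_sample_sheet(self._input_path("samples", "samples.tsv"))
        manifest = tio.read_manifest(self._input_path("manifest", "manifest.tsv"))
        null = run_permutation_study(
            m,
            sheet,
            manifest,
            k=pm["k"],
            seed=self.cfg["seed"],
            max_gap=call_cfg["max_gap"],
            min_probes=call_cfg["min_probes"],
            checkpoint_path=self._path("perm_null.npz"),
            checkpoint_every=pm["checkpoint_every"],
        )
        null.save(self._path("perm_null.npz"))
        self._mark("permute", k=null.k)

    def call(self) -> None:
        cc = self.cfg["calling"]
        stats = pd.read_csv(self._path("probe_stats.tsv"), sep="\t", dtype={"probe_id": str})
        manifest = tio.read_manifest(self._input_path("manifest", "manifest.tsv"))
        null_path = self._path("perm_null.npz")
        null = PermutationNull.load(null_path) if null_path.exists() else PermutationNull(0, self.cfg["seed"])
        if null.k == 0:
            log.warning("no permutation null available; probe calls use parametric p-values")
        funnel: dict[str, int | float] = {}
        for kind, fdr_key, stat_null in (
            ("DMP", "dmp_fdr", null.stat_mean_null),
            ("VMP", "vmp_fdr", null.stat_var_null),
        ):
            calls = call_probes(
                stats,
                kind,
                nuisance_alpha=cc["nuisance_alpha"],
                fdr_thresh=cc[fdr_key],
                perm_null=stat_null if null.k else None,
            )
            calls.table.to_csv(self._path(f"{kind.lower()}s.tsv"), sep="\t", index=False,
                               float_format="%.10g")
            funnel[f"n_{kind.lower()}"] = len(calls.table)
            funnel[f"n_{kind.lower()}_after_nuisance"] = calls.n_after_nuisance
        for kind, fdr_key, auc_nulls in (
            ("DMR", "dmr_fdr", null.dmr_auc_nulls),
            ("VMR", "vmr_fdr", null.vmr_auc_nulls),
        ):
            retained = select_region_probes(stats, kind)
            cands = build_candidate_regions(retained, manifest, kind, cc["max_gap"], cc["min_probes"])
            scored = score_regions(cands, retained, manifest)
            funnel[f"n_{kind.lower()}_candidates"] = len(scored)
            if scored and auc_nulls:
                sam = sam_region_fdr(
                    np.array([r.auc for r in scored]), auc_nulls, trim_quantile=cc["trim_quantile"]
                )
                sam.table.to_csv(self._path(f"sam_{kind.lower()}.tsv"), sep="\t", index=False,
                                 float_format="%.10g")
                idx, fdr = sam.called_at(cc[fdr_key])
                called = [scored[i] for i in idx]
                for r in called:
                    r.fdr = fdr
            else:
                called = []
            called.sort(key=lambda r: (chrom_sort_key(r.chrom), r.start))
            tio.write_regions_tsv(called, self._path(f"{kind.lower()}s.tsv"))
            tio.write_regions_bed(called, self._path(f"{kind.lower()}s.bed"))
            tio.write_regions_tsv(scored, self._path(f"{kind.lower()}_candidates.tsv"))
            funnel[f"n_{kind.lower()}"] = len(called)
        self._mark("call", **funnel)

    # -- helpers for downstream stages --------------------------------------
    def _load_called_regions(self, kinds=("DMR", "VMR")) -> list[Region]:
        regions = []
        for kind in kinds:
            path = self._path(f"{kind.lower()}s.tsv")
            if not path.exists():
                continue
            df = pd.read_csv(path, sep="\t")
            for row in df.itertuples(index=False):
                regions.append(
                    Region(
                        chrom=str(row.chrom), start=int(row.start), end=int(row.end),
                        probe_ids=str(row.probe_ids).split(","), kind=row.kind,
                        direction=row.direction, auc=float(row.auc),
                        fdr=float(row.fdr) if np.isfinite(row.fdr) else np.nan,
                    )
                )
        return regions

    def _load_called_probes(self, kinds=("dmp", "vmp")) -> list[str]:
        out: list[str] = []
        for kind in kinds:
            path = self._path(f"{kind}s.tsv")
            if path.exists():
                df = pd.read_csv(path, sep="\t", dtype={"probe_id": str})
                out.extend(df["probe_id"].tolist())
        return out

    def enrich(self) -> None:
        en = self.cfg["enrichment"]
        manifest = tio.read_manifest(self._input_path("manifest", "manifest.tsv"))
        background = build_background_regions(manifest)
        chromhmm = tio.read_annotation_bed(self._input_path("chromhmm", "chromhmm.bed"), "chromhmm")
        islands = tio.read_annotation_bed(self._input_path("islands", "islands.bed"), "islands")
        blocks = tio.read_annotation_bed(self._input_path("ldblocks", "ldblocks.bed"), "ld_blocks")
        spans = manifest.table.groupby("chrom")["pos"].max() + 5000
        context = derive_island_context(islands, chrom_sizes=spans.to_dict())
        results = {}
        for label, kinds, pkinds in (
            ("differential", ("DMR",), ("dmp",)),
            ("variable", ("VMR",), ("vmp",)),
        ):
            regions = self._load_called_regions(kinds)
            probes = self._load_called_probes(pkinds)
            called = elements_frame(regions, probes, manifest)
            if called.empty:
                log.info("no called %s elements; enrichment skipped", label)
                continue
            for track_label, track in (("chromhmm", chromhmm), ("island_context", context)):
                res = sequence_overlap_enrichment(
                    called, background, track, manifest,
                    n_resample=en["n_resample"], n_boot=en["n_boot"], seed=self.cfg["seed"],
                )
                res.insert(0, "set", label)
                res.to_csv(self._path(f"enrichment_{track_label}_{label}.tsv"), sep="\t",
                           index=False, float_format="%.6g")
            ld = ldblock_overlap(
                called, blocks, background, manifest,
                n_resample=en["n_resample"], n_boot=en["n_boot"], seed=self.cfg["seed"],
            )
            pd.DataFrame(
                [{"set": label, "observed": ld.observed, "ci_lo": ld.ci_lo, "ci_hi": ld.ci_hi,
                  "null_mean": ld.null_mean, "p": ld.p}]
            ).to_csv(self._path(f"ldblock_{label}.tsv"), sep="\t", index=False, float_format="%.6g")
            ld.per_block.to_csv(self._path(f"ldblock_{label}_per_block.tsv"), sep="\t", index=False)
            results[label] = len(called)
        self._mark("enrich", **results)

    def bloodbrain(self) -> None:
        rho = tio.read_rho_table(self._input_path("rho", "rho.tsv"))
        regions = self._load_called_regions()
        summary = bloodbrain_summarize(regions, rho)
        summary.to_csv(self._path("bloodbrain.tsv"), sep="\t", index=False, float_format="%.4g")
        self._mark("bloodbrain", n_regions=len(summary))

    def report(self) -> str:
        lines = ["twinmeth run report", "=" * 40]
        lines.append(f"config hash: {self.run_manifest['config_hash']}  seed: {self.run_manifest['seed']}")
        stages = self.run_manifest["stages"]
        incomplete = [s for s in STAGES[:-1] if s not in stages]
        if incomplete:
            lines.append(f"INCOMPLETE: stages missing: {', '.join(incomplete)}")
        call_info = stages.get("call", {})
        lines.append("")
        lines.append("Calls")
        lines.append("-" * 40)
        for kind in ("dmp", "vmp", "dmr", "vmr"):
            n = call_info.get(f"n_{kind}", "?")
            lines.append(f"  {kind.upper()}s called: {n}")
        for kind in ("DMR", "VMR"):
            path = self._path(f"{kind.lower()}s.tsv")
            if not path.exists():
                continue
            df = pd.read_csv(path, sep="\t")
            lines.append("")
            lines.append(f"{kind} table (Chr, Start, End, N CpGs, AUC, direction)")
            if df.empty:
                lines.append("  (zero calls)")
            for row in df.itertuples(index=False):
                lines.append(
                    f"  {row.chrom}\t{row.start}\t{row.end}\t{row.n_probes}\t{row.auc:.2f}\t{row.direction}"
                )
        bb_path = self._path("bloodbrain.tsv")
        if bb_path.exists():
            bb = pd.read_csv(bb_path, sep="\t")
            lines.append("")
            lines.append("Blood-brain correlation summaries (median / min / max rho)")
            if bb.empty:
                lines.append("  (no called regions)")
            for row in bb.itertuples(index=False):
                lines.append(
                    f"  {row.chrom}:{row.start}-{row.end} {row.kind}: "
                    f"{row.median_rho:.2f} / {row.min_rho:.2f} / {row.max_rho:.2f}"
                    + (f"  [missing {row.n_missing}]" if row.n_missing else "")
                )
        truth_path = self._path("truth.tsv")
        if truth_path.exists():
            truth = pd.read_csv(truth_path, sep="\t")
            called = self._load_called_regions()
            lines.append("")
            lines.append("Truth vs called (region overlap confusion)")
            for kind in ("DMR", "VMR"):
                tk = truth[truth["kind"] == kind]
                ck = [r for r in called if r.kind == kind]
                hits = 0
                for row in tk.itertuples(index=False):
                    if any(r.chrom == row.chrom and r.start <= row.end and r.end >= row.start for r in ck):
                        hits += 1
                fp = sum(
                    1
                    for r in ck
                    if not any(
                        r.chrom == row.chrom and r.start <= row.end and r.end >= row.start
                        for row in tk.itertuples(index=False)
                    )
                )
                lines.append(f"  {kind}: injected {len(tk)}, recovered {hits}, extra called {fp}")
        text = "\n".join(lines) + "\n"
        (self._path("report.txt")).write_text(text)
        self._mark("report")
        return text

    def run_all(self) -> None:
        for stage in STAGES:
            fn = getattr(self, stage)
            try:
                fn()
            except Exception as exc:  # halt with a stage-tagged error, keep partials
                raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc


def run_all(config: dict | str | Path | None, outdir: str | Path) -> PipelineRun:
    run = PipelineRun(outdir, config)
    run.run_all()
    return run
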