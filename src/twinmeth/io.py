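"""Readers and writers for the tabular and BED formats the pipeline touches.

All tables are plain TSV with a header row.  Malformed input is rejected with
an error naming the offending line or record; nothing is silently coerced.
Region BED output is BED6-style, converting the internal 1-based inclusive
coordinates to 0-based half-open at the boundary.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .core import AnnotationTrack, MethylationMatrix, ProbeManifest, Region, SampleSheet

__all__ = [
    "read_manifest",
    "write_manifest",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_matrix",
    "write_matrix",
    "write_regions_bed",
    "write_regions_tsv",
    "read_annotation_bed",
    "write_annotation_bed",
    "read_rho_table",
]


def read_manifest(path: str | Path) -> ProbeManifest:
    """Read a probe manifest TSV with columns probe_id, chrom, pos."""
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "chrom": str})
    missing = {"probe_id", "chrom", "pos"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing manifest columns {sorted(missing)}")
    pos_numeric = pd.to_numeric(df["pos"], errors="coerce")
    bad = pos_numeric.isna() | (pos_numeric != np.floor(pos_numeric))
    if bad.any():
        # +2: one for the header, one for 1-based line numbering
        line = int(np.flatnonzero(bad)[0]) + 2
        raise ValueError(f"{path}:{line}: non-integer pos {df['pos'][bad.idxmax()]!r}")
    df["pos"] = pos_numeric.astype(np.int64)
    return ProbeManifest(df)


def write_manifest(manifest: ProbeManifest, path: str | Path) -> None:
    manifest.table.to_csv(path, sep="\t", index=False)


def read_sample_sheet(path: str | Path) -> SampleSheet:
    """Read a sample sheet TSV; pair structure is validated on construction."""
    df = pd.read_csv(
        path, sep="\t", dtype={"sample_id": str, "pair_id": str, "slide": str}
    )
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.table.to_csv(path, sep="\t", index=False)


def read_matrix(path: str | Path, scale: str) -> MethylationMatrix:
    """Read a probe x sample matrix TSV (first column = probe_id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return MethylationMatrix(df, scale)


def write_matrix(matrix: MethylationMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="probe_id", float_format="%.10g")


def write_regions_bed(regions: list[Region], path: str | Path, score_scale: float = 1.0) -> None:
    """Write regions as BED6: 0-based half-open, name = kind:direction, score = scaled AUC."""
    with open(path, "w") as fh:
        for r in regions:
            score = 0.0 if np.isnan(r.auc) else r.auc * score_scale
            strand = "."
            fh.write(
                f"{r.chrom}\t{r.start - 1}\t{r.end}\t{r.kind}:{r.direction}\t{score:.6g}\t{strand}\n"
            )


def write_regions_tsv(regions: list[Region], path: str | Path) -> None:
    from .core import regions_to_frame

    regions_to_frame(regions).to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_annotation_bed(path: str | Path, name: str | None = None) -> AnnotationTrack:
    """Read a BED file as an annotation track.

    Column 4, when present, is taken as the state label (ChromHMM-style);
    otherwise every interval carries the track name as its state.
    """
    path = Path(path)
    rows = []
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: BED line has fewer than 3 columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: non-integer BED coordinates") from exc
            row = {"chrom": parts[0], "start": start, "end": end}
            if len(parts) >= 4:
                row["state"] = parts[3]
            rows.append(row)
    track_name = name if name is not None else path.stem
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "state"] if rows and "state" in rows[0] else ["chrom", "start", "end"])
    if df.empty:
        df = pd.DataFrame(columns=["chrom", "start", "end"])
    return AnnotationTrack(track_name, df)


def write_annotation_bed(track: AnnotationTrack, path: str | Path) -> None:
    t = track.intervals
    with open(path, "w") as fh:
        for row in t.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.state}\n")


def read_rho_table(path: str | Path) -> pd.Series:
    """Read a per-CpG blood-brain correlation table (probe_id, rho[, p])."""
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str})
    if "probe_id" not in df.columns or "rho" not in df.columns:
        raise ValueError(f"{path}: rho table needs columns probe_id, rho")
    if df["probe_id"].duplicated().any():
        dup = df.loc[df["probe_id"].duplicated(), "probe_id"].iloc[0]
        raise ValueError(f"{path}: duplicate probe_id {dup!r} in rho table")
    return df.set_index("probe_id")["rho"].astype(float)
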