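"""Methylation matrix preprocessing: logit transform, probe filters,
quantile normalization and slide-batch adjustment.

The beta -> M transform is M = log2((beta + offset) / (1 - beta + offset));
the offset guards against zero numerators/denominators at fully (un)methylated
CpGs.  Batch adjustment is a per-probe location/scale standardization across
slides — deliberately simpler than full empirical-Bayes ComBat, since twin
pairs share slides and the primary within-pair contrast is batch-immune by
design.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .core import MethylationMatrix, SampleSheet

__all__ = [
    "beta_to_m",
    "m_to_beta",
    "filter_probes",
    "quantile_normalize",
    "adjust_batch",
    "pca_batch_report",
]

log = logging.getLogger(__name__)

DEFAULT_OFFSET = 0.001


def beta_to_m(matrix: MethylationMatrix, offset: float = DEFAULT_OFFSET) -> MethylationMatrix:
    """Logit-transform beta values to M values (base 2, offset-protected)."""
    if matrix.scale != "beta":
        raise ValueError("beta_to_m expects a beta-scale matrix")
    if offset <= 0:
        raise ValueError("offset must be positive")
    b = matrix.values
    m = np.log2((b + offset) / (1 - b + offset))
    return MethylationMatrix(m, "M", [*matrix.transform_log, f"beta_to_m(offset={offset})"])


def m_to_beta(matrix: MethylationMatrix, offset: float = DEFAULT_OFFSET) -> MethylationMatrix:
    """Inverse of :func:`beta_to_m`; output clipped to [0, 1]."""
    if matrix.scale != "M":
        raise ValueError("m_to_beta expects an M-scale matrix")
    if offset <= 0:
        raise ValueError("offset must be positive")
    e = np.exp2(matrix.values)
    beta = (e * (1 + offset) - offset) / (1 + e)
    beta = beta.clip(0.0, 1.0)
    return MethylationMatrix(beta, "beta", [*matrix.transform_log, f"m_to_beta(offset={offset})"])


def filter_probes(
    matrix: MethylationMatrix,
    detection_p: pd.DataFrame | None = None,
    crosshyb: set[str] | None = None,
    p_thresh: float = 0.01,
    frac_thresh: float = 0.10,
) -> tuple[MethylationMatrix, pd.DataFrame]:
    """Remove failed and cross-hybridizing probes.

    A probe is removed if its detection p-value exceeds ``p_thresh`` in at
    least ``frac_thresh`` of samples (inclusive boundary), or if it appears in
    the cross-hybridizing blacklist.  Returns the filtered matrix and a
    removal report (probe_id, reason).  A missing detection matrix skips the
    detection rule and logs that it did so.
    """
    crosshyb = crosshyb or set()
    reasons: dict[str, str] = {}
    if detection_p is not None:
        if not detection_p.index.equals(matrix.probe_ids) or not detection_p.columns.equals(
            matrix.sample_ids
        ):
            raise ValueError("detection-p matrix labels do not match methylation matrix")
        frac_fail = (detection_p.to_numpy() > p_thresh).mean(axis=1)
        for pid in matrix.probe_ids[frac_fail >= frac_thresh]:
            reasons[pid] = "detection"
    else:
        log.info("no detection-p matrix supplied; detection filtering skipped")
    for pid in matrix.probe_ids:
        if pid in crosshyb and pid not in reasons:
            reasons[pid] = "crosshyb"
    report = pd.DataFrame(
        {"probe_id": list(reasons), "reason": list(reasons.values())},
        columns=["probe_id", "reason"],
    )
    keep = ~matrix.probe_ids.isin(reasons)
    out = MethylationMatrix(
        matrix.values.loc[keep],
        matrix.scale,
        [*matrix.transform_log, f"filter_probes(removed={len(reasons)})"],
    )
    return out, report


def quantile_normalize(matrix: MethylationMatrix) -> MethylationMatrix:
    """Force every sample onto the cross-sample mean order-statistic distribution.

    Within-sample ranks are preserved; ties receive the mean of the reference
    values they span.
    """
    v = matrix.values.to_numpy(dtype=float)
    if v.shape[1] < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    reference = np.sort(v, axis=0).mean(axis=1)
    out = np.empty_like(v)
    grid = np.arange(1, v.shape[0] + 1, dtype=float)
    for j in range(v.shape[1]):
        ranks = rankdata(v[:, j], method="average")
        out[:, j] = np.interp(ranks, grid, reference)
    values = pd.DataFrame(out, index=matrix.probe_ids, columns=matrix.sample_ids)
    return MethylationMatrix(values, matrix.scale, [*matrix.transform_log, "quantile_normalize"])


def adjust_batch(
    matrix: MethylationMatrix,
    sheet: SampleSheet,
    batch_field: str = "slide",
    scale_shrinkage: float = 30.0,
) -> MethylationMatrix:
    """Remove per-probe batch location/scale differences, preserving the grand mean.

    Each batch's per-probe mean is shifted to the grand mean.  The per-probe
    batch variance is first shrunk toward the pooled per-probe variance with
    ``scale_shrinkage`` pseudo-observations before rescaling, so a noisy
    per-probe variance estimate from a dozen samples (or genuine biology such
    as group-specific variability concentrated in one batch) is not wiped out
    wholesale; only systematic scale differences supported by the data are
    removed.  ``scale_shrinkage=0`` gives full location/scale
    standardization.  With a single batch (or batches too small to estimate a
    variance) the transform is the identity, with a warning.
    """
    batches = sheet.table.set_index("sample_id")[batch_field].reindex(matrix.sample_ids)
    if batches.isna().any():
        raise ValueError("matrix contains samples absent from the sample sheet")
    levels = batches.unique()
    sizes = batches.value_counts()
    if len(levels) < 2 or (sizes < 2).any():
        log.warning("batch adjustment skipped: need >= 2 batches each with >= 2 samples")
        return matrix.logged("adjust_batch(identity)")
    md = sheet.table.set_index("sample_id")["md_status"].reindex(matrix.sample_ids)
    for b in levels:
        vals = md[batches == b]
        if vals.nunique() == 1 and md.nunique() > 1:
            log.warning("batch %r is perfectly confounded with md_status; adjustment may absorb signal", b)
    v = matrix.values.to_numpy(dtype=float)
    grand_mean = v.mean(axis=1, keepdims=True)
    centered = np.empty_like(v)
    pooled_var = np.zeros(v.shape[0])
    batch_cols = {b: np.flatnonzero((batches == b).to_numpy()) for b in levels}
    for b, cols in batch_cols.items():
        sub = v[:, cols]
        centered[:, cols] = sub - sub.mean(axis=1, keepdims=True)
        pooled_var += centered[:, cols].var(axis=1, ddof=1) * (len(cols) - 1)
    pooled_var_hat = pooled_var / (v.shape[1] - len(levels))
    out = np.empty_like(v)
    for b, cols in batch_cols.items():
        df_b = len(cols) - 1
        batch_var = v[:, cols].var(axis=1, ddof=1)
        shrunk = (df_b * batch_var + scale_shrinkage * pooled_var_hat) / (df_b + scale_shrinkage)
        scale = np.where(shrunk > 0, np.sqrt(pooled_var_hat / np.where(shrunk > 0, shrunk, 1.0)), 1.0)
        out[:, cols] = centered[:, cols] * scale[:, None] + grand_mean
    values = pd.DataFrame(out, index=matrix.probe_ids, columns=matrix.sample_ids)
    return MethylationMatrix(
        values, matrix.scale, [*matrix.transform_log, f"adjust_batch({batch_field})"]
    )


def pca_batch_report(
    matrix: MethylationMatrix, sheet: SampleSheet, n_components: int = 10
) -> pd.DataFrame:
    """Correlate top principal components of the matrix with design factors.

    Diagnostic only: reports |Pearson r| between each PC score and md_status,
    nk_prop and a numeric batch coding, to surface extraneous structure.
    """
    v = matrix.values.to_numpy(dtype=float)
    n_components = min(n_components, min(v.shape) - 1)
    centered = v - v.mean(axis=1, keepdims=True)
    # samples are the observations; PC scores from the thin SVD of samples x probes
    u, s, _ = np.linalg.svd(centered.T, full_matrices=False)
    scores = u[:, :n_components] * s[:n_components]
    meta = sheet.table.set_index("sample_id").reindex(matrix.sample_ids)
    factors = {
        "md_status": meta["md_status"].to_numpy(dtype=float),
        "nk_prop": meta["nk_prop"].to_numpy(dtype=float),
        "slide": pd.factorize(meta["slide"])[0].astype(float),
    }
    rows = []
    for k in range(n_components):
        s = scores[:, k]
        row = {"pc": k + 1}
        for name, f in factors.items():
            if np.std(f) == 0 or np.std(s) == 0:
                row[name] = 0.0
            else:
                row[name] = float(abs(np.corrcoef(s, f)[0, 1]))
        rows.append(row)
    return pd.DataFrame(rows)
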