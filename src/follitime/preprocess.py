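"""Expression-matrix filtering and normalization-adjacent transforms.

The pipeline ingests already-normalized log-scale matrices; this module
provides the intensity/variability gene filter, per-gene standardization
and mean-centering, and joint quantile normalization across datasets.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix

__all__ = [
    "FilterReport",
    "filter_genes",
    "standardize_rows",
    "mean_center_rows",
    "quantile_normalize",
]


@dataclass
class FilterReport:
    """Bookkeeping for the intensity/variability gene filter."""

    n_input: int
    n_passed_intensity: int
    n_passed_sd: int
    n_retained: int
    pass_intensity: pd.Series
    pass_sd: pd.Series

    def to_json(self, path: str | Path) -> None:
        payload = {k: v for k, v in asdict(self).items() if not isinstance(v, pd.Series)}
        Path(path).write_text(json.dumps(payload, indent=1))


def filter_genes(
    m: ExpressionMatrix,
    intensity_threshold: float = 3.0,
    sd_threshold: float = 0.3,
    intensity_summary: str = "mean",
) -> tuple[ExpressionMatrix, FilterReport]:
    """Retain genes whose summary intensity and across-sample SD exceed thresholds.

    Both rules are applied conjunctively in one pass.  ``intensity_summary``
    selects the per-gene summary statistic: ``"mean"`` (default) or ``"max"``
    across samples.
    """
    if m.n_genes == 0:
        raise ValueError("matrix is empty")
    if not (np.isfinite(intensity_threshold) or intensity_threshold == -np.inf) or not (
        np.isfinite(sd_threshold) or sd_threshold == -np.inf
    ):
        raise ValueError("thresholds must be finite or -inf")
    if intensity_summary == "mean":
        intensity = m.values.mean(axis=1)
    elif intensity_summary == "max":
        intensity = m.values.max(axis=1)
    else:
        raise ValueError("intensity_summary must be 'mean' or 'max'")
    sd = m.values.std(axis=1, ddof=1)
    pass_intensity = intensity > intensity_threshold
    pass_sd = sd > sd_threshold
    keep = pass_intensity & pass_sd
    if not keep.any():
        warnings.warn("intensity/SD filter removed every gene", stacklevel=2)
    report = FilterReport(
        n_input=m.n_genes,
        n_passed_intensity=int(pass_intensity.sum()),
        n_passed_sd=int(pass_sd.sum()),
        n_retained=int(keep.sum()),
        pass_intensity=pass_intensity,
        pass_sd=pass_sd,
    )
    return m.subset_genes(m.gene_ids[keep]), report


def standardize_rows(m: ExpressionMatrix, ddof: int = 1) -> ExpressionMatrix:
    """Scale each gene to mean 0, SD 1 across samples (sample SD, ddof=1)."""
    vals = m.values.to_numpy(dtype=float)
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=ddof, keepdims=True)
    zero = np.where(sd[:, 0] == 0)[0]
    if zero.size:
        raise ValueError(
            f"cannot standardize zero-variance gene(s): {m.gene_ids[zero[:5]].tolist()}"
        )
    out = pd.DataFrame((vals - mean) / sd, index=m.gene_ids, columns=m.sample_ids)
    return ExpressionMatrix(out, m.sample_meta.copy())


def mean_center_rows(m: ExpressionMatrix) -> ExpressionMatrix:
    """Subtract each gene's mean across samples; variances unchanged."""
    if m.n_genes == 0:
        raise ValueError("matrix is empty")
    vals = m.values.to_numpy(dtype=float)
    out = pd.DataFrame(
        vals - vals.mean(axis=1, keepdims=True), index=m.gene_ids, columns=m.sample_ids
    )
    return ExpressionMatrix(out, m.sample_meta.copy())


def _quantile_normalize_array(values: np.ndarray) -> np.ndarray:
    """Force every column to the per-rank mean distribution (ties -> mean of tied ranks)."""
    sorted_vals = np.sort(values, axis=0)
    ref = sorted_vals.mean(axis=1)
    csum = np.concatenate([[0.0], np.cumsum(ref)])
    out = np.empty_like(values, dtype=float)
    n = values.shape[0]
    for j in range(values.shape[1]):
        col = values[:, j]
        order = np.argsort(col, kind="stable")
        sorted_col = col[order]
        # runs of tied values occupy consecutive sorted positions; each member
        # receives the mean of the reference over its run
        starts = np.concatenate([[0], np.flatnonzero(np.diff(sorted_col) != 0) + 1, [n]])
        lengths = np.diff(starts)
        run_means = (csum[starts[1:]] - csum[starts[:-1]]) / lengths
        out[order, j] = np.repeat(run_means, lengths)
    return out


def quantile_normalize(ms: list[ExpressionMatrix]) -> list[ExpressionMatrix]:
    """Jointly quantile-normalize one or more matrices over an identical gene set.

    All columns of all inputs are pooled, each column is replaced by the mean
    of the sorted column values at its ranks, and the matrices are returned
    split back apart.  Gene ID sets and ordering must match exactly.
    """
    if not ms:
        raise ValueError("no matrices given")
    ref_index = ms[0].gene_ids
    for m in ms[1:]:
        if not ref_index.equals(m.gene_ids):
            raise ValueError("gene ID sets/ordering differ between matrices")
    combined = np.hstack([m.values.to_numpy(dtype=float) for m in ms])
    normed = _quantile_normalize_array(combined)
    out: list[ExpressionMatrix] = []
    start = 0
    for m in ms:
        stop = start + m.n_samples
        vals = pd.DataFrame(normed[:, start:stop], index=ref_index, columns=m.sample_ids)
        out.append(ExpressionMatrix(vals, m.sample_meta.copy()))
        start = stop
    return out
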