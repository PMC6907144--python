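"""Quality control, CPM normalization, and gene-wise centering/scaling.

Cell QC removes outliers beyond ``n_mads`` scaled median absolute
deviations from the median of three per-cell summaries: library size,
mitochondrial fraction, and ribosomal fraction. Gene filtering drops
undetected and weakly expressed genes. Scaling parameters learned on
training data are persisted and reapplied verbatim to test data.
"""

from __future__ import annotations

import re
from typing import Tuple

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .containers import CountMatrix, GeneScaling, ScaledMatrix

MAD_CONSTANT = 1.4826  # consistency with the normal sd

DEFAULT_MITO_PATTERN = r"^MT-"
DEFAULT_RIBO_PATTERN = r"^RP[LS]"


def _row_sums(values) -> np.ndarray:
    if sp.issparse(values):
        return np.asarray(values.sum(axis=1)).ravel()
    return values.sum(axis=1)


def _mad_bounds(x: np.ndarray, n_mads: float) -> Tuple[float, float]:
    med = float(np.median(x))
    mad = MAD_CONSTANT * float(np.median(np.abs(x - med)))
    return med - n_mads * mad, med + n_mads * mad


def qc_filter_cells(
    counts: CountMatrix,
    mito_pattern: str = DEFAULT_MITO_PATTERN,
    ribo_pattern: str = DEFAULT_RIBO_PATTERN,
    n_mads: float = 3.0,
) -> Tuple[CountMatrix, pd.DataFrame]:
    """Remove outlier cells on library size and mito/ribo content.

    A cell is kept when each metric lies within median +/- n_mads * 1.4826*MAD.
    A metric whose MAD is zero is skipped (no cell removed on it); a pattern
    matching zero genes yields all-zero fractions, hence MAD zero, hence a
    skip. Returns the filtered matrix and a per-cell report with metric
    values and pass/fail flags.
    """
    if counts.unit != "counts":
        raise ValueError("qc_filter_cells expects raw counts")
    if counts.n_cells == 0:
        raise ValueError("empty matrix")

    totals = _row_sums(counts.values).astype(float)
    gene_ids = counts.gene_ids.astype(str)
    mito = np.array([bool(re.search(mito_pattern, g)) for g in gene_ids])
    ribo = np.array([bool(re.search(ribo_pattern, g)) for g in gene_ids])

    dense_needed = counts.values.tocsc() if sp.issparse(counts.values) else counts.values
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(
            totals > 0, np.asarray(dense_needed[:, mito].sum(axis=1)).ravel() / np.maximum(totals, 1), 0.0
        )
        ribo_frac = np.where(
            totals > 0, np.asarray(dense_needed[:, ribo].sum(axis=1)).ravel() / np.maximum(totals, 1), 0.0
        )

    report = pd.DataFrame(
        {
            "cell_id": counts.cell_ids,
            "library_size": totals,
            "mito_fraction": mito_frac,
            "ribo_fraction": ribo_frac,
        }
    )
    keep = np.ones(counts.n_cells, dtype=bool)
    for name, metric in (
        ("library_size", totals),
        ("mito_fraction", mito_frac),
        ("ribo_fraction", ribo_frac),
    ):
        med = np.median(metric)
        if np.median(np.abs(metric - med)) == 0:
            report[f"pass_{name}"] = True
            continue
        lo, hi = _mad_bounds(metric, n_mads)
        ok = (metric >= lo) & (metric <= hi)
        report[f"pass_{name}"] = ok
        keep &= ok

    if not keep.any():
        raise ValueError("cell QC removed every cell")
    report["pass"] = keep
    return counts.subset_cells(keep), report


def _cpm(values) -> np.ndarray:
    dense = np.asarray(values.todense()) if sp.issparse(values) else np.asarray(values, float)
    totals = dense.sum(axis=1, keepdims=True)
    if np.any(totals == 0):
        raise ValueError("cell with zero total count")
    return 1e6 * dense / totals


def filter_genes(
    counts: CountMatrix,
    min_cell_frac: float = 0.01,
    min_mean_cpm: float = 5.0,
) -> CountMatrix:
    """Drop undetected, rarely detected, and weakly expressed genes.

    Keeps genes that (a) are detected (count > 0) in at least
    ``min_cell_frac`` of cells and (b) have mean CPM across cells strictly
    above ``min_mean_cpm``. Gene order is preserved.
    """
    if counts.unit != "counts":
        raise ValueError("filter_genes expects raw counts")
    dense = counts.dense().astype(float)
    detected = (dense > 0).mean(axis=0)
    keep = detected >= min_cell_frac
    keep &= detected > 0  # all-zero genes always go
    mean_cpm = _cpm(dense).mean(axis=0)
    keep &= mean_cpm > min_mean_cpm
    if not keep.any():
        raise ValueError("gene filtering removed every gene")
    return counts.subset_genes(keep)


def normalize_log_cpm(counts: CountMatrix) -> CountMatrix:
    """Transform raw counts to log2(CPM + 1)."""
    if counts.unit != "counts":
        raise ValueError("normalize_log_cpm expects raw counts")
    log_vals = np.log2(_cpm(counts.values) + 1.0)
    return CountMatrix(log_vals, counts.cell_ids, counts.gene_ids, unit="logCPM")


def fit_center_scale(log_matrix: CountMatrix) -> GeneScaling:
    """Learn per-gene mean and sample (n-1) standard deviation.

    Genes with zero variance are excluded from the scaling and recorded in
    ``dropped_gene_ids``.
    """
    if log_matrix.unit != "logCPM":
        raise ValueError("fit_center_scale expects a logCPM matrix")
    if log_matrix.n_cells < 2:
        raise ValueError("need at least 2 cells to estimate a standard deviation")
    X = log_matrix.dense()
    mu = X.mean(axis=0)
    sigma = X.std(axis=0, ddof=1)
    keep = sigma > 0
    return GeneScaling(
        mu=mu[keep],
        sigma=sigma[keep],
        gene_ids=log_matrix.gene_ids[keep],
        dropped_gene_ids=log_matrix.gene_ids[~keep],
    )


def apply_center_scale(
    log_matrix: CountMatrix,
    scaling: GeneScaling,
    min_overlap_frac: float = 0.5,
) -> ScaledMatrix:
    """Center and scale by gene identifier against a fitted ``GeneScaling``.

    Output columns follow ``scaling.gene_ids`` exactly. Genes present in the
    scaling but absent from the input get scaled value 0 (the gene mean);
    input genes unknown to the scaling are dropped. Fails when fewer than
    ``min_overlap_frac`` of the scaling genes are present.
    """
    if log_matrix.unit != "logCPM":
        raise ValueError("apply_center_scale expects a logCPM matrix")
    pos = {g: j for j, g in enumerate(log_matrix.gene_ids)}
    idx = np.array([pos.get(g, -1) for g in scaling.gene_ids])
    overlap = float((idx >= 0).mean()) if len(idx) else 0.0
    if overlap < min_overlap_frac:
        raise ValueError(
            f"only {overlap:.1%} of the {len(idx)} scaling genes are present "
            f"in the input (minimum {min_overlap_frac:.0%})"
        )
    X = log_matrix.dense()
    out = np.zeros((log_matrix.n_cells, len(scaling.gene_ids)))
    present = idx >= 0
    out[:, present] = (X[:, idx[present]] - scaling.mu[present]) / scaling.sigma[present]
    return ScaledMatrix(out, log_matrix.cell_ids, scaling.gene_ids.copy(), scaling)
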