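"""Core in-memory containers shared across the pipeline.

The central objects mirror the training/prediction algebra: a raw
``CountMatrix`` (cells x genes), a ``GeneScaling`` holding the per-gene
mean/sd of log2(CPM+1) learned on training data, the ``Eigenspace`` from
the truncated SVD of the scaled training matrix, per-class ``PcSelection``
feature sets, per-class calibrated ``SvmModel`` classifiers, and the
``PredictorBundle`` tying them together with a rejection threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import scipy.sparse as sp

UNASSIGNED = "Unassigned"

Unit = str  # one of {"counts", "CPM", "logCPM"}
_VALID_UNITS = ("counts", "CPM", "logCPM")


def _check_ids(ids: np.ndarray, what: str) -> np.ndarray:
    ids = np.asarray(ids, dtype=object)
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate {what} identifiers")
    return ids


@dataclass
class CountMatrix:
    """Cells x genes expression matrix with identifiers.

    ``values`` may be a dense ndarray or a scipy sparse matrix; rows are
    cells, columns genes. ``unit`` records the normalization state.
    """

    values: "np.ndarray | sp.spmatrix"
    cell_ids: np.ndarray
    gene_ids: np.ndarray
    unit: Unit = "counts"

    def __post_init__(self) -> None:
        if self.unit not in _VALID_UNITS:
            raise ValueError(f"unknown unit {self.unit!r}")
        self.cell_ids = _check_ids(self.cell_ids, "cell")
        self.gene_ids = _check_ids(self.gene_ids, "gene")
        n, m = self.values.shape
        if n != len(self.cell_ids) or m != len(self.gene_ids):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.cell_ids)} cells x {len(self.gene_ids)} genes"
            )
        if self.min() < 0:
            raise ValueError("negative expression values")
        if self.unit == "counts":
            arr = self.values.data if sp.issparse(self.values) else self.values
            if arr.size and not np.allclose(np.asarray(arr) % 1, 0):
                raise ValueError("unit='counts' requires integer-valued entries")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def min(self) -> float:
        if sp.issparse(self.values):
            return float(self.values.data.min(initial=0.0))
        return float(self.values.min(initial=0.0))

    def dense(self) -> np.ndarray:
        if sp.issparse(self.values):
            return np.asarray(self.values.todense())
        return np.asarray(self.values)

    def subset_cells(self, mask_or_idx) -> "CountMatrix":
        vals = self.values.tocsr()[mask_or_idx] if sp.issparse(self.values) else self.values[mask_or_idx]
        return CountMatrix(vals, self.cell_ids[mask_or_idx], self.gene_ids, self.unit)

    def subset_genes(self, mask_or_idx) -> "CountMatrix":
        vals = self.values.tocsc()[:, mask_or_idx].tocsr() if sp.issparse(self.values) else self.values[:, mask_or_idx]
        return CountMatrix(vals, self.cell_ids, self.gene_ids[mask_or_idx], self.unit)


@dataclass
class GeneScaling:
    """Per-gene centering/scaling parameters (mean and n-1 sd of log2 CPM)."""

    mu: np.ndarray
    sigma: np.ndarray
    gene_ids: np.ndarray
    dropped_gene_ids: np.ndarray = field(default_factory=lambda: np.array([], dtype=object))

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, float)
        self.sigma = np.asarray(self.sigma, float)
        self.gene_ids = _check_ids(self.gene_ids, "gene")
        if not (len(self.mu) == len(self.sigma) == len(self.gene_ids)):
            raise ValueError("mu, sigma, gene_ids length mismatch")
        if np.any(self.sigma <= 0):
            raise ValueError("sigma must be positive for every retained gene")


@dataclass
class ScaledMatrix:
    """Centered/scaled cells x genes matrix in the training gene order."""

    values: np.ndarray
    cell_ids: np.ndarray
    gene_ids: np.ndarray
    scaling: Optional[GeneScaling] = None


@dataclass
class Eigenspace:
    """Truncated SVD of the scaled training matrix M = U S V^T.

    ``rotation`` is V (genes x k), ``scores`` is US (cells x k), and
    ``var_explained`` divides each squared singular value by the full
    Frobenius norm of M, so the fractions refer to total variance even
    under truncation.
    """

    rotation: np.ndarray
    singular_values: np.ndarray
    scores: np.ndarray
    var_explained: np.ndarray
    total_variance: float
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    scaling: GeneScaling

    @property
    def n_components(self) -> int:
        return self.rotation.shape[1]


@dataclass
class ScoreMatrix:
    """Cells x k PC-score matrix with the originating PC indices (0-based)."""

    values: np.ndarray
    pc_indices: np.ndarray
    cell_ids: np.ndarray

    def __post_init__(self) -> None:
        self.pc_indices = np.asarray(self.pc_indices, dtype=int)
        if self.pc_indices.size == 0:
            raise ValueError("ScoreMatrix needs at least one PC")
        if np.any(np.diff(np.sort(self.pc_indices)) == 0):
            raise ValueError("duplicate PC indices")


@dataclass
class PcSelection:
    """Class-informative PCs ranked by BH-adjusted rank-sum p-value."""

    class_name: str
    pc_indices: np.ndarray          # selected, sorted by (p_adj, index)
    tested_pc_indices: np.ndarray   # the BH family
    p_raw: np.ndarray
    p_adj: np.ndarray
    alpha: float


@dataclass
class SvmModel:
    """Radial-kernel SVM with Platt sigmoid calibration.

    The decision function is f(x) = sum_i alpha_i k(x, x_i) + b with
    k(x, y) = exp(-sigma ||x - y||^2); the calibrated probability is
    Pr(y=1 | f) = 1 / (1 + exp(A f + B)).
    """

    class_name: str
    kernel_sigma: float
    cost: float
    support_vectors: np.ndarray
    dual_coefs: np.ndarray
    intercept: float
    platt_a: float
    platt_b: float
    cv_summary: Optional[object] = None  # DataFrame of per-grid-point CV metrics

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        from .svm import rbf_kernel_matrix

        K = rbf_kernel_matrix(X, self.support_vectors, self.kernel_sigma)
        return K @ self.dual_coefs + self.intercept

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        f = self.decision_function(X)
        return 1.0 / (1.0 + np.exp(self.platt_a * f + self.platt_b))


@dataclass
class PredictorBundle:
    """Everything needed to classify independent cells."""

    eigenspace: Eigenspace
    selections: dict
    models: dict
    class_names: list
    threshold: float = 0.9
    parameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 < self.threshold <= 1:
            raise ValueError("threshold must be in (0, 1]")
        collapsed = (
            self.parameters.get("binary_collapse")
            and len(self.class_names) == 2
            and len(self.models) == 1
        )
        if set(self.selections) != set(self.models) and not collapsed:
            raise ValueError("selections and models must cover identical classes")


@dataclass
class ProbabilityTable:
    cell_ids: np.ndarray
    class_names: list
    probabilities: np.ndarray  # cells x classes, unnormalized one-vs-all

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, float)
        if p.size and (p.min() < 0 or p.max() > 1):
            raise ValueError("probabilities outside [0, 1]")
        self.probabilities = p


@dataclass
class PredictionTable:
    cell_ids: np.ndarray
    class_names: list
    probabilities: np.ndarray
    predicted_label: np.ndarray
    max_probability: np.ndarray

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.probabilities, columns=self.class_names)
        df.insert(0, "cell_id", self.cell_ids)
        df["predicted_label"] = self.predicted_label
        return df
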