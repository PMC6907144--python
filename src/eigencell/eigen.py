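"""Truncated SVD of the scaled expression matrix and projection of new cells.

The scaled training matrix M (cells x genes) is factorized as
M = U S V^T. The PC scores are S = U Sigma; the rotation V maps scaled
gene space into PC space, so independent cells scaled with the training
parameters project as P = M_test V. Variance explained per PC divides the
squared singular value by the *full* squared Frobenius norm of M, so the
fractions remain meaningful under truncation.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from sklearn.utils.extmath import randomized_svd

from .containers import Eigenspace, ScaledMatrix, ScoreMatrix

# below this size a dense LAPACK SVD is cheaper and exactly deterministic
_DENSE_CUTOFF = 1500


def _sign_fix(U: np.ndarray, Vt: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Fix the SVD sign ambiguity: the largest-|loading| entry of each
    rotation column is made positive (ties broken by first index)."""
    signs = np.empty(Vt.shape[0])
    for k in range(Vt.shape[0]):
        j = int(np.argmax(np.abs(Vt[k])))
        signs[k] = 1.0 if Vt[k, j] >= 0 else -1.0
    return U * signs, Vt * signs[:, None]


def fit_eigenspace(
    scaled: ScaledMatrix,
    n_components: Optional[int] = None,
    seed: int = 0,
) -> Eigenspace:
    """Truncated SVD of a centered/scaled training matrix.

    Parameters
    ----------
    scaled
        Output of ``apply_center_scale`` on the training data itself.
    n_components
        Number of PCs to keep; defaults to min(n_cells - 1, n_genes, 100).
    seed
        Seeds the randomized solver used for large matrices; small
        matrices use a deterministic dense LAPACK decomposition.
    """
    M = np.asarray(scaled.values, float)
    if not np.all(np.isfinite(M)):
        raise ValueError("non-finite entries in the scaled matrix")
    n, m = M.shape
    max_rank = min(n, m)
    if n_components is None:
        n_components = min(n - 1, m, 100)
    if not 1 <= n_components <= max_rank:
        raise ValueError(
            f"n_components={n_components} out of range [1, {max_rank}] "
            f"for a {n} x {m} matrix"
        )

    total_variance = float(np.sum(M * M))
    if min(n, m) <= _DENSE_CUTOFF or n_components > 0.5 * min(n, m):
        U, s, Vt = np.linalg.svd(M, full_matrices=False)
        U, s, Vt = U[:, :n_components], s[:n_components], Vt[:n_components]
    else:
        U, s, Vt = randomized_svd(
            M, n_components=n_components, n_iter=7, random_state=seed
        )
    U, Vt = _sign_fix(U, Vt)

    return Eigenspace(
        rotation=Vt.T,
        singular_values=s,
        scores=U * s,
        var_explained=s**2 / total_variance,
        total_variance=total_variance,
        gene_ids=scaled.gene_ids.copy(),
        cell_ids=scaled.cell_ids.copy(),
        scaling=scaled.scaling,
    )


def filter_by_variance(space: Eigenspace, min_frac: float = 1e-4) -> ScoreMatrix:
    """Keep PCs explaining at least ``min_frac`` of total variance."""
    if not 0 < min_frac < 1:
        raise ValueError("min_frac must lie in (0, 1)")
    keep = np.flatnonzero(space.var_explained >= min_frac)
    if keep.size == 0:
        raise ValueError(
            "no PC passes the variance filter; lower min_frac "
            f"(largest fraction is {space.var_explained.max():.2e})"
        )
    return ScoreMatrix(space.scores[:, keep], keep, space.cell_ids.copy())


def project_cells(
    test_scaled: ScaledMatrix,
    space: Eigenspace,
    pc_indices: Optional[Sequence[int]] = None,
) -> ScoreMatrix:
    """Project scaled test cells through the training rotation: P = M_test V."""
    if not np.array_equal(test_scaled.gene_ids, space.gene_ids):
        raise ValueError("gene order of the scaled matrix does not match the eigenspace")
    if pc_indices is None:
        pc_indices = np.arange(space.n_components)
    idx = np.asarray(pc_indices, int)
    P = np.asarray(test_scaled.values) @ space.rotation[:, idx]
    return ScoreMatrix(P, idx, test_scaled.cell_ids.copy())
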