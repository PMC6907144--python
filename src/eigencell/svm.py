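"""Calibrated radial-kernel SVM training.

Each one-vs-all class model is a soft-margin SVM with the Gaussian radial
basis kernel k(x, x_i) = exp(-sigma ||x - x_i||^2). The kernel width sigma
and cost C are chosen by stratified k-fold cross-validation over a small
grid, maximizing mean validation AUROC. Probabilities come from a Platt
sigmoid Pr(y=1|f) = 1/(1 + exp(A f + B)) fitted by damped Newton iterations
on *out-of-fold* decision values, so the calibration never sees its own
training fit.

The quadratic-programming solve is delegated to scikit-learn's SVC; the
stored (support vectors, dual coefficients, intercept) reproduce its
decision function exactly, which the test suite asserts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import NearestNeighbors
from sklearn.svm import SVC

from .containers import (
    Eigenspace,
    PcSelection,
    PredictorBundle,
    ScoreMatrix,
    SvmModel,
)
from .metrics import auroc
from .pc_features import bh_adjust, rank_sum_test

DEFAULT_COST_GRID = (0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 16.0)
SIGMA_QUANTILES = (0.1, 0.5, 0.9)


def rbf_kernel(x, y, sigma: float) -> float:
    """Gaussian radial basis kernel exp(-sigma ||x - y||^2)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    d = x - y
    return float(np.exp(-sigma * np.dot(d, d)))


def rbf_kernel_matrix(X: np.ndarray, Y: np.ndarray, sigma: float) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, float))
    Y = np.atleast_2d(np.asarray(Y, float))
    sq = (
        (X**2).sum(axis=1)[:, None]
        - 2.0 * X @ Y.T
        + (Y**2).sum(axis=1)[None, :]
    )
    return np.exp(-sigma * np.maximum(sq, 0.0))


def default_sigma_grid(X: np.ndarray, rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """Kernel-width candidates from the spread of pairwise squared distances.

    Takes the {0.1, 0.5, 0.9} quantiles of the nonzero pairwise squared
    distances (subsampled to at most 200 points) and returns their
    reciprocals, a median-heuristic-style bracket around 1/median(d^2).
    """
    X = np.asarray(X, float)
    n = X.shape[0]
    if n > 200:
        rng = rng or np.random.default_rng(0)
        X = X[rng.choice(n, 200, replace=False)]
    sq = (
        (X**2).sum(axis=1)[:, None]
        - 2.0 * X @ X.T
        + (X**2).sum(axis=1)[None, :]
    )
    d2 = sq[np.triu_indices_from(sq, k=1)]
    d2 = d2[d2 > 1e-12]
    if d2.size == 0:
        return np.array([1.0])
    q = np.quantile(d2, SIGMA_QUANTILES)
    return np.unique(1.0 / q[::-1])  # ascending sigma


def fit_platt_scaling(decision_values, labels) -> tuple[float, float]:
    """Maximum-likelihood sigmoid fit Pr(y=1|f) = 1/(1 + exp(A f + B)).

    Uses the regularized targets t+ = (N+ + 1)/(N+ + 2), t- = 1/(N- + 2)
    and damped Newton steps until the gradient norm drops below 1e-8
    (at most 100 iterations).
    """
    f = np.asarray(decision_values, float)
    y = np.asarray(labels).astype(bool)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to calibrate")
    t = np.where(y, (n_pos + 1.0) / (n_pos + 2.0), 1.0 / (n_neg + 2.0))

    A, B = 0.0, np.log((n_neg + 1.0) / (n_pos + 1.0))
    for _ in range(100):
        z = A * f + B
        # p = 1/(1+e^z); stable split by sign of z
        p = np.where(z >= 0, np.exp(-z) / (1 + np.exp(-z)), 1 / (1 + np.exp(z)))
        # negative log-likelihood of targets t under p; gradient wrt (A, B)
        d = p - t
        gA = -np.dot(d, f)
        gB = -d.sum()
        if max(abs(gA), abs(gB)) < 1e-8:
            break
        w = p * (1 - p) + 1e-12
        hAA = np.dot(w, f * f)
        hAB = np.dot(w, f)
        hBB = w.sum()
        det = hAA * hBB - hAB * hAB
        if det <= 1e-300:
            break
        dA = (hBB * gA - hAB * gB) / det
        dB = (hAA * gB - hAB * gA) / det

        def nll(a, b):
            # with p = 1/(1+e^z): -[t log p + (1-t) log(1-p)] = log(1+e^z) - (1-t) z
            zz = a * f + b
            return float(np.sum(np.logaddexp(0.0, zz) - (1 - t) * zz))

        base = nll(A, B)
        step = 1.0
        while step > 1e-10 and nll(A - step * dA, B - step * dB) > base + 1e-12:
            step /= 2.0
        A -= step * dA
        B -= step * dB
    else:
        raise RuntimeError("Platt scaling failed to converge in 100 iterations")
    return float(A), float(B)


def tune_and_train_svm(
    features,
    labels,
    folds: int = 10,
    grid: Optional[dict] = None,
    seed: int = 0,
    class_name: str = "positive",
) -> SvmModel:
    """Grid-searched, cross-validated, Platt-calibrated RBF SVM.

    ``features`` is a ScoreMatrix or a cells x k array; ``labels`` a binary
    vector (truthy = positive class). Selection maximizes mean validation
    AUROC; ties prefer the smaller cost, then the smaller sigma. The final
    model is refit on all data at the chosen grid point and calibrated on
    the out-of-fold decision values collected at that point.
    """
    X = features.values if isinstance(features, ScoreMatrix) else np.asarray(features, float)
    X = np.atleast_2d(X)
    y = np.asarray(labels).astype(bool)
    if y.all() or not y.any():
        raise ValueError("labels contain a single class")

    min_class = min(int(y.sum()), int((~y).sum()))
    if min_class < folds:
        warnings.warn(
            f"reducing folds from {folds} to {max(2, min_class)} "
            f"(smallest class has {min_class} cells)",
            stacklevel=2,
        )
        folds = max(2, min_class)

    grid = grid or {}
    sigmas = np.asarray(grid.get("sigma", default_sigma_grid(X, np.random.default_rng(seed))), float)
    costs = np.asarray(grid.get("cost", DEFAULT_COST_GRID), float)
    if sigmas.size == 0 or costs.size == 0:
        raise ValueError("empty tuning grid")

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))

    rows = []
    oof = {}  # (sigma, cost) -> out-of-fold decision values
    for sigma in sigmas:
        for cost in costs:
            dec = np.empty(len(y))
            aucs = []
            for tr, va in splits:
                clf = SVC(C=cost, kernel="rbf", gamma=sigma)
                clf.fit(X[tr], y[tr])
                dec[va] = clf.decision_function(X[va])
                aucs.append(auroc(dec[va], y[va]))
            rows.append({"sigma": sigma, "cost": cost, "cv_auroc": float(np.mean(aucs))})
            oof[(sigma, cost)] = dec.copy()
    cv_summary = pd.DataFrame(rows)

    # argmax with deterministic tie-breaks: auroc desc, cost asc, sigma asc
    best = cv_summary.sort_values(
        ["cv_auroc", "cost", "sigma"], ascending=[False, True, True]
    ).iloc[0]
    sigma, cost = float(best["sigma"]), float(best["cost"])

    clf = SVC(C=cost, kernel="rbf", gamma=sigma)
    clf.fit(X, y)
    A, B = fit_platt_scaling(oof[(sigma, cost)], y)

    return SvmModel(
        class_name=class_name,
        kernel_sigma=sigma,
        cost=cost,
        support_vectors=clf.support_vectors_.copy(),
        dual_coefs=clf.dual_coef_.ravel().copy(),
        intercept=float(clf.intercept_[0]),
        platt_a=A,
        platt_b=B,
        cv_summary=cv_summary,
    )


def smote_oversample(
    features,
    labels,
    k_neighbors: int = 5,
    seed: int = 0,
):
    """SMOTE: balance a binary sample by interpolating minority neighbors.

    Each synthetic point is x + lambda (x_nn - x) with lambda ~ U(0,1) and
    x_nn one of the k nearest minority neighbors of the minority point x.
    Originals are preserved unchanged; synthetic cells get ids
    ``smote_<i>``.
    """
    is_score = isinstance(features, ScoreMatrix)
    X = features.values if is_score else np.asarray(features, float)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("smote_oversample expects exactly two classes")
    minority = classes[np.argmin(counts)]
    n_min, n_maj = counts.min(), counts.max()
    if n_min < 2:
        raise ValueError("minority class needs at least 2 cells")
    n_new = int(n_maj - n_min)
    if n_new == 0:
        return features, y.copy()

    rng = np.random.default_rng(seed)
    Xm = X[y == minority]
    k = min(k_neighbors, n_min - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(Xm)
    _, idx = nn.kneighbors(Xm)  # column 0 is the point itself

    base = rng.integers(0, n_min, size=n_new)
    pick = rng.integers(1, k + 1, size=n_new)
    lam = rng.uniform(0.0, 1.0, size=n_new)
    neigh = idx[base, pick]
    synth = Xm[base] + lam[:, None] * (Xm[neigh] - Xm[base])

    X_out = np.vstack([X, synth])
    y_out = np.concatenate([y, np.full(n_new, minority, dtype=y.dtype)])
    if is_score:
        ids = np.concatenate(
            [features.cell_ids, np.array([f"smote_{i}" for i in range(n_new)], dtype=object)]
        )
        return ScoreMatrix(X_out, features.pc_indices, ids), y_out
    return X_out, y_out


def train_one_vs_all(
    eigenspace: Eigenspace,
    selections: dict,
    labels,
    folds: int = 10,
    grid: Optional[dict] = None,
    seed: int = 0,
    threshold: float = 0.9,
    balance: str = "none",
    min_class_size: int = 20,
    binary_collapse: bool = False,
) -> PredictorBundle:
    """Assemble the one-vs-all multiclass bundle.

    Each class's SVM is trained on that class's own informative-PC scores.
    With ``binary_collapse`` and exactly two classes, a single model is
    trained for the first class and the second class's probability is the
    complement at prediction time.
    """
    labels = np.asarray(labels)
    class_names = sorted(selections)
    if len(class_names) < 2:
        raise ValueError("need at least 2 classes")
    for c in class_names:
        n_c = int((labels == c).sum())
        if n_c < 2:
            raise ValueError(f"class {c!r} has {n_c} cells; cannot train")
        if n_c < min_class_size:
            warnings.warn(
                f"class {c!r} has only {n_c} cells (< {min_class_size}); "
                "expect degraded accuracy",
                stacklevel=2,
            )

    to_train = class_names[:1] if (binary_collapse and len(class_names) == 2) else class_names
    models = {}
    for i, c in enumerate(to_train):
        sel: PcSelection = selections[c]
        if sel.pc_indices.size == 0:
            raise ValueError(f"no informative PCs selected for class {c!r}")
        feats = ScoreMatrix(
            eigenspace.scores[:, sel.pc_indices], sel.pc_indices, eigenspace.cell_ids
        )
        y = labels == c
        if balance == "smote":
            feats, y = smote_oversample(feats, y, seed=seed + 17 * i)
        models[c] = tune_and_train_svm(
            feats, y, folds=folds, grid=grid, seed=seed + i, class_name=c
        )

    return PredictorBundle(
        eigenspace=eigenspace,
        selections=selections,
        models=models,
        class_names=class_names,
        threshold=threshold,
        parameters={
            "folds": folds,
            "seed": seed,
            "balance": balance,
            "binary_collapse": bool(binary_collapse),
        },
    )


# ---------------------------------------------------------------------------
# baseline predictors


@dataclass
class Baseline:
    """A reference predictor used to contextualize the main pipeline.

    ``decision_function`` consumes the mode's feature representation:
    anything sized for intercept_only, informative-PC scores for
    unit_coefficients, all PC scores for all_pcs, per-cell mean logCPM for
    mean_logcpm, and the selected genes' logCPM columns for de_genes.
    """

    mode: str
    svm: Optional[SvmModel] = None
    intercept: float = 0.0
    gene_ids: Optional[np.ndarray] = None

    def decision_function(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, float))
        if self.mode == "intercept_only":
            return np.full(X.shape[0], self.intercept)
        if self.mode == "unit_coefficients":
            return X.sum(axis=1) + self.intercept
        return self.svm.decision_function(X)


def train_baseline(mode: str, data: dict, config: Optional[dict] = None) -> Baseline:
    """Train one of the reference predictors.

    modes: intercept_only (constant decision value), unit_coefficients
    (unweighted sum of informative-PC scores), all_pcs (SVM on every PC),
    mean_logcpm (SVM on the per-cell mean of log2(CPM+1)), de_genes (SVM on
    genes passing a rank-sum + fold-change screen).
    """
    config = config or {}
    folds = int(config.get("folds", 5))
    seed = int(config.get("seed", 0))

    if mode == "intercept_only":
        return Baseline(mode=mode, intercept=0.0)

    y = np.asarray(data["labels"]) == data["positive_class"]

    if mode == "unit_coefficients":
        scores = np.asarray(data["scores"], float)  # informative-PC scores
        return Baseline(mode=mode, intercept=-float(scores.sum(axis=1).mean()))

    if mode == "all_pcs":
        X = data["eigenspace"].scores
    elif mode == "mean_logcpm":
        X = data["log_matrix"].dense().mean(axis=1, keepdims=True)
    elif mode == "de_genes":
        log = data["log_matrix"]
        X_full = log.dense()
        p = np.array(
            [rank_sum_test(X_full[y, j], X_full[~y, j]) for j in range(X_full.shape[1])]
        )
        lfc = X_full[y].mean(axis=0) - X_full[~y].mean(axis=0)
        keep = (bh_adjust(p) < 0.05) & (np.abs(lfc) > 1.0)
        if keep.sum() == 0:
            raise ValueError(
                "no differentially expressed genes pass BH < 0.05 and "
                "|log2 fold-change| > 1; cannot train the de_genes baseline"
            )
        X = X_full[:, keep]
        model = tune_and_train_svm(X, y, folds=folds, seed=seed, class_name=str(data["positive_class"]))
        return Baseline(mode=mode, svm=model, gene_ids=log.gene_ids[keep])
    else:
        raise ValueError(f"unknown baseline mode {mode!r}")

    model = tune_and_train_svm(X, y, folds=folds, seed=seed, class_name=str(data["positive_class"]))
    return Baseline(mode=mode, svm=model)
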