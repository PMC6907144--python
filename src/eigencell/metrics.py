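"""Rejection-aware evaluation metrics and robustness utilities.

The rejection option changes the bookkeeping: an unassigned cell is
counted as *incorrect* for its true class, so sensitivity is
TP / (all true positives, unassigned included) and specificity is the
analogue on the negative class. AUROC/AUPRC are computed on raw
probabilities before thresholding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import rankdata
from sklearn.metrics import average_precision_score
from sklearn.model_selection import train_test_split

from .containers import UNASSIGNED, CountMatrix, PredictionTable


@dataclass
class MetricsReport:
    positive_class: str
    sensitivity: float
    specificity: float
    precision: float
    f1: float
    accuracy: float
    counts: dict = field(default_factory=dict)
    auroc: Optional[float] = None
    auprc: Optional[float] = None
    bootstrap: Optional[pd.DataFrame] = None


def confusion_with_rejection(pred: PredictionTable, truth, positive_class: str) -> MetricsReport:
    """Confusion counts and rates with "Unassigned" counted as incorrect."""
    truth = np.asarray(truth)
    labels = np.asarray(pred.predicted_label)
    if len(truth) != len(labels):
        raise ValueError("prediction and truth cover different cells")
    if positive_class not in truth:
        raise ValueError(f"positive class {positive_class!r} absent from truth")

    pos = truth == positive_class
    said_pos = labels == positive_class
    unassigned = labels == UNASSIGNED

    tp = int((pos & said_pos).sum())
    fn = int((pos & ~said_pos & ~unassigned).sum())
    un_pos = int((pos & unassigned).sum())
    tn = int((~pos & ~said_pos & ~unassigned).sum())
    fp = int((~pos & said_pos).sum())
    un_neg = int((~pos & unassigned).sum())

    n_pos = int(pos.sum())
    n_neg = int((~pos).sum())
    sens = tp / n_pos
    spec = tn / n_neg if n_neg else float("nan")
    prec = tp / (tp + fp) if (tp + fp) else 0.0
    f1 = 2 * prec * sens / (prec + sens) if (prec + sens) else 0.0
    acc = (tp + tn) / (n_pos + n_neg)
    return MetricsReport(
        positive_class=positive_class,
        sensitivity=sens,
        specificity=spec,
        precision=prec,
        f1=f1,
        accuracy=acc,
        counts={
            "TP": tp,
            "FP": fp,
            "TN": tn,
            "FN": fn,
            "unassigned_pos": un_pos,
            "unassigned_neg": un_neg,
        },
    )


def auroc(scores, truth) -> float:
    """Area under the ROC curve as the probability of concordance.

    Computed from the Mann-Whitney U statistic with midranks, so tied
    scores count 0.5; a constant predictor scores exactly 0.5.
    """
    s = np.asarray(scores, float)
    y = np.asarray(truth).astype(bool)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    r = rankdata(s)
    u = r[y].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def auprc(scores, truth) -> float:
    """Area under the precision-recall curve (step-wise, non-interpolated)."""
    y = np.asarray(truth).astype(bool)
    if not y.any():
        raise ValueError("no positive cells")
    return float(average_precision_score(y, np.asarray(scores, float)))


def bootstrap_evaluate(
    counts: CountMatrix,
    labels,
    fit_predict: Callable,
    n_replicates: int = 10,
    split_frac: float = 0.75,
    seed: int = 0,
    metrics_classes: Optional[list] = None,
) -> pd.DataFrame:
    """Repeated stratified train/test splits with percentile CIs.

    ``fit_predict(train_counts, train_labels, test_counts, seed)`` must
    return a PredictionTable for the test cells. The seeded partitions are
    reproducible, so competing methods can share them. Returns a tidy
    frame with one row per (replicate, class) plus summary rows carrying
    the mean and the percentile 2.5/97.5 bounds per metric.
    """
    if n_replicates < 2:
        raise ValueError("need at least 2 replicates")
    labels = np.asarray(labels)
    classes = metrics_classes or sorted(np.unique(labels))
    rng = np.random.default_rng(seed)

    rows = []
    for rep in range(n_replicates):
        for attempt in range(10):
            rep_seed = int(rng.integers(0, 2**31 - 1))
            idx_tr, idx_te = train_test_split(
                np.arange(counts.n_cells),
                train_size=split_frac,
                random_state=rep_seed % (2**32 - 1),
                stratify=labels,
            )
            tr_ok = set(np.unique(labels[idx_tr])) >= set(classes)
            te_ok = set(np.unique(labels[idx_te])) >= set(classes)
            if tr_ok and te_ok:
                break
        else:
            raise RuntimeError("could not draw a split containing every class")
        pred = fit_predict(
            counts.subset_cells(idx_tr), labels[idx_tr], counts.subset_cells(idx_te), rep_seed
        )
        truth = labels[idx_te]
        for c in classes:
            rep_metrics = confusion_with_rejection(pred, truth, c)
            rows.append(
                {
                    "replicate": rep,
                    "class": c,
                    "sensitivity": rep_metrics.sensitivity,
                    "specificity": rep_metrics.specificity,
                    "precision": rep_metrics.precision,
                    "f1": rep_metrics.f1,
                    "accuracy": rep_metrics.accuracy,
                }
            )
    per_rep = pd.DataFrame(rows)

    summaries = []
    value_cols = ["sensitivity", "specificity", "precision", "f1", "accuracy"]
    for c in classes:
        sub = per_rep[per_rep["class"] == c]
        for stat, fn in (
            ("mean", np.mean),
            ("ci_low", lambda v: np.percentile(v, 2.5)),
            ("ci_high", lambda v: np.percentile(v, 97.5)),
        ):
            summaries.append(
                {"replicate": stat, "class": c, **{m: fn(sub[m].to_numpy()) for m in value_cols}}
            )
    return pd.concat([per_rep, pd.DataFrame(summaries)], ignore_index=True)


def downsample_reads(counts: CountMatrix, target_per_cell: int, seed: int = 0) -> CountMatrix:
    """Thin each cell to at most ``target_per_cell`` total reads.

    Sampling is without replacement (multivariate hypergeometric), so the
    thinned profile is an exact subsample of the observed reads; cells at
    or below the target are untouched.
    """
    if target_per_cell < 1:
        raise ValueError("target_per_cell must be >= 1")
    if counts.unit != "counts":
        raise ValueError("downsample_reads expects raw counts")
    rng = np.random.default_rng(seed)
    X = counts.dense().astype(np.int64)
    out = X.copy()
    for i in range(X.shape[0]):
        total = int(X[i].sum())
        if total > target_per_cell:
            out[i] = rng.multivariate_hypergeometric(X[i], target_per_cell)
    values = sp.csr_matrix(out) if sp.issparse(counts.values) else out
    return CountMatrix(values, counts.cell_ids, counts.gene_ids, unit="counts")
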