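"""Classify independent cells through a trained bundle.

Prediction follows the training geometry exactly: test counts are CPM/log
normalized, centered and scaled with the *training* gene means and
standard deviations, projected through the training rotation, and each
one-vs-all SVM scores the projection restricted to its own informative
PCs. The cell takes the class of the highest calibrated probability when
that probability exceeds the rejection threshold (strictly), otherwise it
is labeled "Unassigned" — unknown cell types are not forced into known
classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import (
    UNASSIGNED,
    CountMatrix,
    PredictionTable,
    PredictorBundle,
    ProbabilityTable,
)
from .eigen import project_cells
from .preprocess import apply_center_scale, normalize_log_cpm


def predict_probabilities(bundle: PredictorBundle, test_counts: CountMatrix) -> ProbabilityTable:
    """One calibrated probability per (cell, class); unnormalized across classes."""
    if test_counts.n_cells == 0:
        return ProbabilityTable(
            test_counts.cell_ids, list(bundle.class_names), np.zeros((0, len(bundle.class_names)))
        )
    log = normalize_log_cpm(test_counts)
    scaled = apply_center_scale(log, bundle.eigenspace.scaling)

    probs = np.zeros((test_counts.n_cells, len(bundle.class_names)))
    for j, c in enumerate(bundle.class_names):
        if c not in bundle.models:
            continue  # binary collapse: filled from the complement below
        sel = bundle.selections[c]
        feats = project_cells(scaled, bundle.eigenspace, sel.pc_indices)
        probs[:, j] = bundle.models[c].predict_proba(feats.values)
    if bundle.parameters.get("binary_collapse") and len(bundle.class_names) == 2:
        trained = bundle.class_names.index(next(iter(bundle.models)))
        probs[:, 1 - trained] = 1.0 - probs[:, trained]
    return ProbabilityTable(test_counts.cell_ids.copy(), list(bundle.class_names), probs)


def assign_labels(probs: ProbabilityTable, threshold: float = 0.9) -> PredictionTable:
    """Max-probability rule with rejection.

    label = argmax class when max prob > threshold (strict), else
    "Unassigned". Ties at the max resolve to the lexicographically
    smallest class name.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    P = probs.probabilities
    n = P.shape[0]
    labels = np.full(n, UNASSIGNED, dtype=object)
    max_p = P.max(axis=1) if n else np.zeros(0)
    order = np.argsort(np.asarray(probs.class_names, dtype=object))  # lexicographic preference
    for i in range(n):
        if max_p[i] > threshold:
            tied = [j for j in order if P[i, j] == max_p[i]]
            labels[i] = probs.class_names[tied[0]]
    return PredictionTable(
        cell_ids=probs.cell_ids.copy(),
        class_names=list(probs.class_names),
        probabilities=P.copy(),
        predicted_label=labels,
        max_probability=np.asarray(max_p, float),
    )


def predict(bundle: PredictorBundle, test_counts: CountMatrix, threshold=None) -> PredictionTable:
    """Convenience: probabilities + label assignment in one call."""
    t = bundle.threshold if threshold is None else threshold
    return assign_labels(predict_probabilities(bundle, test_counts), t)


@dataclass
class HierarchyNode:
    """A node in a layered classification tree.

    ``children`` maps a class name of this node's bundle to the node that
    refines it; classes without children are leaves of the annotation.
    """

    node_name: str
    bundle: PredictorBundle
    children: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.children) - set(self.bundle.class_names)
        if unknown:
            raise ValueError(f"child keys {sorted(unknown)} not among bundle classes")
        seen = set()
        stack = [self]
        while stack:
            node = stack.pop()
            if id(node) in seen:
                raise ValueError("hierarchy contains a cycle")
            seen.add(id(node))
            stack.extend(node.children.values())


def predict_hierarchical(
    root: HierarchyNode, test_counts: CountMatrix, threshold: float = 0.9
) -> PredictionTable:
    """Depth-first layered classification.

    A child bundle scores only the cells its parent assigned to that
    child's class. The final label is the deepest successful path, joined
    with "/" (e.g. ``lymphoid/T/cytotoxic``); a cell rejected at some
    level keeps its deepest assigned prefix, and a root-level rejection is
    "Unassigned". The returned probability columns are the root bundle's.
    """
    n = test_counts.n_cells
    final = np.full(n, UNASSIGNED, dtype=object)

    root_pred = predict(root.bundle, test_counts, threshold)

    def descend(node: HierarchyNode, idx: np.ndarray, prefix: str, pred: PredictionTable) -> None:
        for j, c in enumerate(pred.predicted_label):
            if c != UNASSIGNED:
                final[idx[j]] = f"{prefix}{c}"
        for c, child in node.children.items():
            sub = np.flatnonzero(pred.predicted_label == c)
            if sub.size == 0:
                continue
            child_idx = idx[sub]
            child_pred = predict(child.bundle, test_counts.subset_cells(child_idx), threshold)
            descend(child, child_idx, f"{prefix}{c}/", child_pred)

    descend(root, np.arange(n), "", root_pred)
    return PredictionTable(
        cell_ids=test_counts.cell_ids.copy(),
        class_names=list(root.bundle.class_names),
        probabilities=root_pred.probabilities,
        predicted_label=final,
        max_probability=root_pred.max_probability,
    )
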