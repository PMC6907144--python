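"""High-level train/predict pipelines used by the CLI and evaluation code."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .containers import CountMatrix, PredictionTable, PredictorBundle
from .eigen import filter_by_variance, fit_eigenspace
from .pc_features import select_informative_pcs
from .predict import predict
from .preprocess import (
    DEFAULT_MITO_PATTERN,
    DEFAULT_RIBO_PATTERN,
    apply_center_scale,
    filter_genes,
    fit_center_scale,
    normalize_log_cpm,
    qc_filter_cells,
)
from .svm import train_one_vs_all


@dataclass
class PipelineConfig:
    """All tunables of the end-to-end training pipeline in one place."""

    qc: bool = True
    n_mads: float = 3.0
    mito_pattern: str = DEFAULT_MITO_PATTERN
    ribo_pattern: str = DEFAULT_RIBO_PATTERN
    min_cell_frac: float = 0.01
    min_mean_cpm: float = 5.0
    n_components: Optional[int] = None
    var_threshold: float = 1e-4
    alpha: float = 0.05
    folds: int = 10
    grid: Optional[dict] = None
    threshold: float = 0.9
    balance: str = "none"
    min_class_size: int = 20
    seed: int = 0
    extra: dict = field(default_factory=dict)


def train_model(counts: CountMatrix, labels, config: Optional[PipelineConfig] = None) -> PredictorBundle:
    """Full training pipeline: QC -> gene filter -> logCPM -> scale -> SVD ->
    variance filter -> per-class PC selection -> one-vs-all SVMs."""
    cfg = config or PipelineConfig()
    labels = np.asarray(labels)
    if len(labels) != counts.n_cells:
        raise ValueError("labels do not match the cells")

    if cfg.qc:
        counts, report = qc_filter_cells(
            counts, cfg.mito_pattern, cfg.ribo_pattern, cfg.n_mads
        )
        labels = labels[report["pass"].to_numpy()]
    counts = filter_genes(counts, cfg.min_cell_frac, cfg.min_mean_cpm)
    log = normalize_log_cpm(counts)
    scaling = fit_center_scale(log)
    scaled = apply_center_scale(log, scaling)
    space = fit_eigenspace(scaled, cfg.n_components, seed=cfg.seed)
    filtered = filter_by_variance(space, cfg.var_threshold)

    selections = {
        c: select_informative_pcs(filtered, labels, c, cfg.alpha)
        for c in sorted(np.unique(labels))
    }
    bundle = train_one_vs_all(
        space,
        selections,
        labels,
        folds=cfg.folds,
        grid=cfg.grid,
        seed=cfg.seed,
        threshold=cfg.threshold,
        balance=cfg.balance,
        min_class_size=cfg.min_class_size,
        binary_collapse=bool(cfg.extra.get("binary_collapse", False)),
    )
    bundle.parameters.update(
        alpha=cfg.alpha,
        var_threshold=cfg.var_threshold,
        n_components=space.n_components,
    )
    return bundle


def fit_predict_split(
    train_counts: CountMatrix,
    train_labels,
    test_counts: CountMatrix,
    seed: int,
    config: Optional[PipelineConfig] = None,
) -> PredictionTable:
    """Train on one partition and predict the other; the shape expected by
    ``metrics.bootstrap_evaluate``."""
    cfg = config or PipelineConfig()
    cfg = PipelineConfig(**{**cfg.__dict__, "seed": int(seed) % (2**31 - 1)})
    bundle = train_model(train_counts, train_labels, cfg)
    return predict(bundle, test_counts)
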