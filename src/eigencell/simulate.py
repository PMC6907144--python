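"""Class-structured synthetic scRNA-seq counts.

The generator emulates the statistical setting the classifier is designed
for: cell classes that differ through many small shifts in mean expression
spread across hundreds of genes, overlaid on strong per-cell library-size
variation and negative-binomial (gamma-Poisson) counting noise.

Per gene g a baseline mean is drawn log-normally. Each class c owns a
disjoint set of effect genes whose log2 mean is shifted by +/- effect_size
(random sign per gene). A cell of class c with drawn library size L has
expected counts L * m_cg / sum_g m_cg and observed counts drawn
NB(mean=mu, dispersion=phi) with Var = mu + phi mu^2. Mitochondrial and
ribosomal genes are tagged by the conventional MT- / RPL/RPS id prefixes so
the QC stage has something to measure. An optional unseen class (disjoint
effect genes, excluded from training by the caller) exercises the
rejection option, and an optional class hierarchy layers parent effects
shared by all descendants under child-specific effects.

Every draw flows from the mandatory seed, so a config reproduces its
dataset exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .containers import CountMatrix

UNSEEN_CLASS = "unseen"


@dataclass
class SimulationConfig:
    n_cells_per_class: int = 200
    n_genes: int = 2000
    n_effect_genes: int = 200
    effect_size: float = 1.0          # log2-fold shift on effect genes
    nb_dispersion: float = 0.5        # Var = mu + phi mu^2
    library_size_range: tuple = (20_000, 60_000)
    class_names: tuple = ("alpha", "beta")
    n_mito_genes: int = 10
    n_ribo_genes: int = 20
    batch_shift: Optional[np.ndarray] = None  # per-gene log2 shift added to a second batch
    unseen_class: bool = False
    hierarchy: Optional[dict] = None  # nested {name: subtree}; leaves are classes
    seed: int = 0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.n_cells_per_class < 1 or self.n_genes < 1:
            raise ValueError("cell and gene counts must be positive")
        if self.n_effect_genes > self.n_genes:
            raise ValueError("more effect genes than genes")
        lo, hi = self.library_size_range
        if not (0 < lo <= hi):
            raise ValueError("invalid library_size_range")


@dataclass
class SimulatedDataset:
    counts: CountMatrix
    labels: np.ndarray
    truth: dict = field(default_factory=dict)


def _gene_ids(cfg: SimulationConfig) -> np.ndarray:
    ids = []
    for i in range(cfg.n_mito_genes):
        ids.append(f"MT-{i + 1}")
    for i in range(cfg.n_ribo_genes):
        prefix = "RPL" if i % 2 == 0 else "RPS"
        ids.append(f"{prefix}{i + 1}")
    for i in range(cfg.n_genes - len(ids)):
        ids.append(f"G{i + 1:05d}")
    return np.asarray(ids[: cfg.n_genes], dtype=object)


def _sample_counts(
    class_means: np.ndarray, lib_sizes: np.ndarray, phi: float, rng: np.random.Generator
) -> np.ndarray:
    p = class_means / class_means.sum()
    mu = lib_sizes[:, None] * p[None, :]
    if phi <= 0:
        return rng.poisson(mu)
    lam = rng.gamma(shape=1.0 / phi, scale=mu * phi)
    return rng.poisson(lam)


def _effect_partition(rng, n_genes, groups, n_effect):
    """Disjoint effect-gene sets, one per group name."""
    needed = n_effect * len(groups)
    if needed > n_genes:
        raise ValueError(f"{needed} effect genes requested but only {n_genes} genes")
    pool = rng.permutation(n_genes)[:needed]
    return {g: np.sort(pool[i * n_effect : (i + 1) * n_effect]) for i, g in enumerate(groups)}


def generate_class_counts(config: SimulationConfig) -> SimulatedDataset:
    """Flat multi-class dataset; see the module docstring for the model."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    gene_ids = _gene_ids(cfg)

    base_log2 = rng.normal(loc=3.0, scale=1.2, size=cfg.n_genes)  # log2 mean expression
    classes = list(cfg.class_names)
    all_classes = classes + [UNSEEN_CLASS] if cfg.unseen_class else classes
    effect_genes = _effect_partition(rng, cfg.n_genes, all_classes, cfg.n_effect_genes)
    signs = {c: rng.choice([-1.0, 1.0], size=cfg.n_effect_genes) for c in all_classes}

    blocks, labels, libs, batches = [], [], [], []
    lo, hi = cfg.library_size_range
    for c in all_classes:
        log2_means = base_log2.copy()
        log2_means[effect_genes[c]] += signs[c] * cfg.effect_size
        L = rng.integers(lo, hi + 1, size=cfg.n_cells_per_class)
        if cfg.batch_shift is None:
            blocks.append(
                _sample_counts(2.0**log2_means, L.astype(float), cfg.nb_dispersion, rng)
            )
            batches.extend([0] * cfg.n_cells_per_class)
        else:
            # split the class across two technical batches; batch 2 adds a
            # per-gene log2 shift in mean space (no correction downstream)
            half = cfg.n_cells_per_class // 2
            shift = np.asarray(cfg.batch_shift, float)
            blocks.append(
                _sample_counts(2.0**log2_means, L[:half].astype(float), cfg.nb_dispersion, rng)
            )
            blocks.append(
                _sample_counts(
                    2.0 ** (log2_means + shift), L[half:].astype(float), cfg.nb_dispersion, rng
                )
            )
            batches.extend([0] * half + [1] * (cfg.n_cells_per_class - half))
        labels.extend([c] * cfg.n_cells_per_class)
        libs.append(L)

    X = np.vstack(blocks).astype(np.int64)
    labels = np.asarray(labels, dtype=object)
    cell_ids = np.asarray([f"cell_{i:05d}" for i in range(X.shape[0])], dtype=object)

    counts = CountMatrix(X, cell_ids, gene_ids, unit="counts")
    truth = {
        "effect_genes": {c: effect_genes[c].tolist() for c in all_classes},
        "effect_signs": {c: signs[c].tolist() for c in all_classes},
        "base_log2_means": base_log2.tolist(),
        "library_sizes": np.concatenate(libs).tolist(),
        "classes": all_classes,
        "batch": batches,
        "seed": cfg.seed,
    }
    return SimulatedDataset(counts, labels, truth)


def _flatten_paths(tree: dict, prefix: str = "") -> list:
    paths = []
    for name, sub in tree.items():
        p = f"{prefix}{name}"
        if sub:
            paths.extend(_flatten_paths(sub, p + "/"))
        else:
            paths.append(p)
    return paths


def _nodes_of(tree: dict, prefix: str = "") -> list:
    out = []
    for name, sub in tree.items():
        p = f"{prefix}{name}"
        out.append(p)
        if sub:
            out.extend(_nodes_of(sub, p + "/"))
    return out


def generate_hierarchical_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Lineage-structured dataset: labels are full paths such as lymphoid/T.

    Every node of the hierarchy (internal or leaf) owns a disjoint effect
    gene set; a leaf class expresses the summed shifts of every node along
    its path, so sibling leaves share their ancestors' effects and differ
    only in their own.
    """
    cfg = config
    if not cfg.hierarchy:
        raise ValueError("hierarchy spec missing")
    rng = np.random.default_rng(cfg.seed)
    gene_ids = _gene_ids(cfg)

    nodes = _nodes_of(cfg.hierarchy)
    leaves = _flatten_paths(cfg.hierarchy)
    base_log2 = rng.normal(loc=3.0, scale=1.2, size=cfg.n_genes)
    effect_genes = _effect_partition(rng, cfg.n_genes, nodes, cfg.n_effect_genes)
    signs = {nd: rng.choice([-1.0, 1.0], size=cfg.n_effect_genes) for nd in nodes}

    blocks, labels, libs = [], [], []
    lo, hi = cfg.library_size_range
    for leaf in leaves:
        log2_means = base_log2.copy()
        parts = leaf.split("/")
        for depth in range(1, len(parts) + 1):
            nd = "/".join(parts[:depth])
            log2_means[effect_genes[nd]] += signs[nd] * cfg.effect_size
        means = 2.0 ** log2_means
        L = rng.integers(lo, hi + 1, size=cfg.n_cells_per_class)
        blocks.append(_sample_counts(means, L.astype(float), cfg.nb_dispersion, rng))
        labels.extend([leaf] * cfg.n_cells_per_class)
        libs.append(L)

    X = np.vstack(blocks).astype(np.int64)
    cell_ids = np.asarray([f"cell_{i:05d}" for i in range(X.shape[0])], dtype=object)
    counts = CountMatrix(X, cell_ids, gene_ids, unit="counts")
    truth = {
        "effect_genes": {nd: effect_genes[nd].tolist() for nd in nodes},
        "effect_signs": {nd: signs[nd].tolist() for nd in nodes},
        "base_log2_means": base_log2.tolist(),
        "library_sizes": np.concatenate(libs).tolist(),
        "leaves": leaves,
        "nodes": nodes,
        "hierarchy": cfg.hierarchy,
        "seed": cfg.seed,
    }
    return SimulatedDataset(counts, np.asarray(labels, dtype=object), truth)
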