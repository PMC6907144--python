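"""Reading and writing the standard matrix formats and model bundles.

Expression input is either Matrix Market coordinate format with the
CellRanger orientation (genes as rows, cells as columns) plus gene/barcode
TSV sidecars, or a dense TSV/CSV with gene ids in the header row and cell
ids in the first column. In memory everything is cells x genes.

A trained model is persisted as a *bundle*: a directory holding a JSON
manifest plus one .npy file per numeric array, each listed in the manifest
with its SHA-256 checksum so silent corruption is caught on load.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .containers import (
    CountMatrix,
    Eigenspace,
    GeneScaling,
    PcSelection,
    PredictionTable,
    PredictorBundle,
    SvmModel,
)

FORMAT_VERSION = "1"


def _read_id_column(path) -> np.ndarray:
    ids = pd.read_csv(path, sep="\t", header=None, dtype=str)[0].to_numpy(dtype=object)
    return ids


def read_expression_input(
    matrix_path,
    genes_path: Optional[str] = None,
    cells_path: Optional[str] = None,
) -> CountMatrix:
    """Read an expression matrix into cells x genes orientation.

    A ``.mtx`` matrix requires both sidecars (genes then barcodes); any
    other extension is parsed as a dense delimited table with gene ids in
    the header and cell ids in the first column.
    """
    matrix_path = Path(matrix_path)
    if matrix_path.suffix == ".mtx":
        if genes_path is None or cells_path is None:
            raise ValueError("MTX input needs genes and cells sidecar files")
        mat = scipy.io.mmread(str(matrix_path))  # genes x cells on disk
        genes = _read_id_column(genes_path)
        cells = _read_id_column(cells_path)
        if mat.shape != (len(genes), len(cells)):
            raise ValueError(
                f"matrix is {mat.shape[0]} x {mat.shape[1]} but sidecars list "
                f"{len(genes)} genes and {len(cells)} cells"
            )
        values = sp.csr_matrix(mat.T)
        return CountMatrix(values, cells, genes, unit="counts")

    sep = "," if matrix_path.suffix == ".csv" else "\t"
    df = pd.read_csv(matrix_path, sep=sep, index_col=0)
    return CountMatrix(
        df.to_numpy(),
        df.index.to_numpy(dtype=object),
        df.columns.to_numpy(dtype=object),
        unit="counts",
    )


def write_expression_mtx(counts: CountMatrix, out_dir) -> None:
    """Write matrix.mtx + genes.tsv + barcodes.tsv (genes-as-rows on disk)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mat = counts.values.T if sp.issparse(counts.values) else sp.csr_matrix(counts.values).T
    scipy.io.mmwrite(str(out / "matrix.mtx"), sp.coo_matrix(mat))
    pd.Series(counts.gene_ids).to_csv(out / "genes.tsv", sep="\t", header=False, index=False)
    pd.Series(counts.cell_ids).to_csv(out / "barcodes.tsv", sep="\t", header=False, index=False)


def write_predictions(table: PredictionTable, path) -> None:
    df = table.to_frame()
    prob_cols = table.class_names
    df[prob_cols] = df[prob_cols].map(lambda v: f"{v:.6f}")
    df.to_csv(path, sep="\t", index=False)


def read_predictions(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# model bundles


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _save_array(dir_: Path, name: str, arr, inventory: dict) -> None:
    path = dir_ / f"{name}.npy"
    np.save(path, np.asarray(arr), allow_pickle=False)
    inventory[f"{name}.npy"] = _sha256(path)


def save_model_bundle(bundle: PredictorBundle, dir_) -> dict:
    """Write the bundle directory and return its manifest."""
    missing_sel = [c for c in bundle.class_names if c not in bundle.selections]
    if missing_sel:
        raise ValueError(f"partial bundle: missing selections for classes {missing_sel}")
    missing = [c for c in bundle.class_names if c not in bundle.models]
    collapsed = (
        bundle.parameters.get("binary_collapse")
        and len(bundle.class_names) == 2
        and len(bundle.models) == 1
    )
    if missing and not collapsed:
        raise ValueError(f"partial bundle: missing models for classes {missing}")

    dir_ = Path(dir_)
    dir_.mkdir(parents=True, exist_ok=True)
    inv: dict = {}
    es = bundle.eigenspace
    _save_array(dir_, "rotation", es.rotation, inv)
    _save_array(dir_, "singular_values", es.singular_values, inv)
    _save_array(dir_, "scores", es.scores, inv)
    _save_array(dir_, "var_explained", es.var_explained, inv)
    _save_array(dir_, "scaling_mu", es.scaling.mu, inv)
    _save_array(dir_, "scaling_sigma", es.scaling.sigma, inv)

    classes_meta = {}
    for i, c in enumerate(bundle.class_names):
        tag = f"class{i}"
        sel = bundle.selections[c]
        _save_array(dir_, f"{tag}_pc_indices", sel.pc_indices, inv)
        _save_array(dir_, f"{tag}_tested_pc_indices", sel.tested_pc_indices, inv)
        _save_array(dir_, f"{tag}_p_raw", sel.p_raw, inv)
        _save_array(dir_, f"{tag}_p_adj", sel.p_adj, inv)
        meta = {"alpha": sel.alpha, "tag": tag, "has_model": c in bundle.models}
        if c in bundle.models:
            m = bundle.models[c]
            _save_array(dir_, f"{tag}_support_vectors", m.support_vectors, inv)
            _save_array(dir_, f"{tag}_dual_coefs", m.dual_coefs, inv)
            meta.update(
                kernel_sigma=m.kernel_sigma,
                cost=m.cost,
                intercept=m.intercept,
                platt_a=m.platt_a,
                platt_b=m.platt_b,
            )
        classes_meta[c] = meta

    manifest = {
        "format_version": FORMAT_VERSION,
        "class_names": list(bundle.class_names),
        "threshold": bundle.threshold,
        "parameters": bundle.parameters,
        "gene_ids": [str(g) for g in es.gene_ids],
        "cell_ids": [str(c) for c in es.cell_ids],
        "dropped_gene_ids": [str(g) for g in es.scaling.dropped_gene_ids],
        "total_variance": es.total_variance,
        "classes": classes_meta,
        "files": inv,
    }
    (dir_ / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def _load_array(dir_: Path, name: str, manifest: dict) -> np.ndarray:
    fname = f"{name}.npy"
    path = dir_ / fname
    if fname not in manifest["files"]:
        raise ValueError(f"{fname} not listed in the bundle manifest")
    if not path.exists():
        raise ValueError(f"bundle file {fname} is missing")
    if _sha256(path) != manifest["files"][fname]:
        raise ValueError(f"checksum mismatch for {fname}; bundle is corrupted")
    return np.load(path, allow_pickle=False)


def load_model_bundle(dir_) -> PredictorBundle:
    dir_ = Path(dir_)
    mpath = dir_ / "manifest.json"
    if not mpath.exists():
        raise ValueError(f"{dir_} is not a model bundle (no manifest.json)")
    manifest = json.loads(mpath.read_text())
    if manifest.get("format_version", "?") > FORMAT_VERSION:
        raise ValueError(
            f"bundle format {manifest['format_version']} is newer than supported ({FORMAT_VERSION})"
        )

    gene_ids = np.asarray(manifest["gene_ids"], dtype=object)
    scaling = GeneScaling(
        mu=_load_array(dir_, "scaling_mu", manifest),
        sigma=_load_array(dir_, "scaling_sigma", manifest),
        gene_ids=gene_ids,
        dropped_gene_ids=np.asarray(manifest["dropped_gene_ids"], dtype=object),
    )
    es = Eigenspace(
        rotation=_load_array(dir_, "rotation", manifest),
        singular_values=_load_array(dir_, "singular_values", manifest),
        scores=_load_array(dir_, "scores", manifest),
        var_explained=_load_array(dir_, "var_explained", manifest),
        total_variance=float(manifest["total_variance"]),
        gene_ids=gene_ids,
        cell_ids=np.asarray(manifest["cell_ids"], dtype=object),
        scaling=scaling,
    )
    selections, models = {}, {}
    for c, meta in manifest["classes"].items():
        tag = meta["tag"]
        selections[c] = PcSelection(
            class_name=c,
            pc_indices=_load_array(dir_, f"{tag}_pc_indices", manifest).astype(int),
            tested_pc_indices=_load_array(dir_, f"{tag}_tested_pc_indices", manifest).astype(int),
            p_raw=_load_array(dir_, f"{tag}_p_raw", manifest),
            p_adj=_load_array(dir_, f"{tag}_p_adj", manifest),
            alpha=float(meta["alpha"]),
        )
        if meta["has_model"]:
            models[c] = SvmModel(
                class_name=c,
                kernel_sigma=float(meta["kernel_sigma"]),
                cost=float(meta["cost"]),
                support_vectors=_load_array(dir_, f"{tag}_support_vectors", manifest),
                dual_coefs=_load_array(dir_, f"{tag}_dual_coefs", manifest),
                intercept=float(meta["intercept"]),
                platt_a=float(meta["platt_a"]),
                platt_b=float(meta["platt_b"]),
            )
    return PredictorBundle(
        eigenspace=es,
        selections=selections,
        models=models,
        class_names=list(manifest["class_names"]),
        threshold=float(manifest["threshold"]),
        parameters=dict(manifest["parameters"]),
    )
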