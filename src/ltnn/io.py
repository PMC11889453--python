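"""Data model and file input/output.

The central container is :class:`CellMatrix`, a cells × genes count matrix
with cell/gene identifiers, a mitochondrial-gene mask and an optional
normalized layer.  Readers exist for MatrixMarket directories (matrix +
barcodes + features sidecars), dense CSV/TSV and the HDF5 single-cell
container (``.h5ad``); every writer has a matching reader and round-trips
losslessly.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

MODEL_FORMAT_VERSION = 1
DEFAULT_MITO_REGEX = r"^MT-"


class ValidationError(ValueError):
    """Raised when an input violates a data-model invariant."""


@dataclass
class CellMatrix:
    """Raw (and optionally normalized) expression of cells × genes.

    Parameters
    ----------
    counts
        Nonnegative matrix, cells in rows, genes in columns. Dense ndarray
        or scipy sparse.
    cell_ids, gene_ids
        Unique string identifiers for rows and columns.
    mito_mask
        Boolean per gene, True for mitochondrially encoded genes.
    layer_normalized
        Optional normalized matrix of identical shape (filled by
        :func:`ltnn.preprocess.normalize_total`).
    cell_meta
        Per-cell annotation table indexed by cell id (cluster labels,
        known cell types, ...).
    """

    counts: np.ndarray | sp.spmatrix
    cell_ids: np.ndarray
    gene_ids: np.ndarray
    mito_mask: np.ndarray
    layer_normalized: np.ndarray | sp.spmatrix | None = None
    cell_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.mito_mask = np.asarray(self.mito_mask, dtype=bool)
        self.validate()

    # -- invariants ---------------------------------------------------
    def validate(self) -> None:
        n_cells, n_genes = self.counts.shape
        if len(self.cell_ids) != n_cells:
            raise ValidationError(
                f"{len(self.cell_ids)} cell ids for {n_cells} matrix rows"
            )
        if len(self.gene_ids) != n_genes:
            raise ValidationError(
                f"{len(self.gene_ids)} gene ids for {n_genes} matrix columns"
            )
        if len(set(self.cell_ids)) != n_cells:
            raise ValidationError("duplicate cell ids")
        if len(set(self.gene_ids)) != n_genes:
            raise ValidationError("duplicate gene ids")
        if len(self.mito_mask) != n_genes:
            raise ValidationError("mito_mask length does not match gene count")
        if self._min(self.counts) < 0:
            raise ValidationError("counts contain negative entries")
        if self.layer_normalized is not None and (
            self.layer_normalized.shape != self.counts.shape
        ):
            raise ValidationError("layer_normalized shape differs from counts")
        if self.cell_meta is not None and not self.cell_meta.index.equals(
            pd.Index(self.cell_ids)
        ):
            raise ValidationError("cell_meta index does not match cell_ids")

    @staticmethod
    def _min(m) -> float:
        if sp.issparse(m):
            return m.data.min() if m.nnz else 0.0
        return float(m.min()) if m.size else 0.0

    # -- conveniences -------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def counts_dense(self) -> np.ndarray:
        return self.counts.toarray() if sp.issparse(self.counts) else np.asarray(self.counts)

    def normalized_dense(self) -> np.ndarray:
        if self.layer_normalized is None:
            raise ValidationError("normalized layer not present; run normalize_total first")
        x = self.layer_normalized
        return x.toarray() if sp.issparse(x) else np.asarray(x)

    def subset_cells(self, keep: np.ndarray) -> "CellMatrix":
        """Return a new CellMatrix restricted to a boolean or index mask of cells."""
        keep = np.asarray(keep)
        counts = self.counts[keep]
        layer = None if self.layer_normalized is None else self.layer_normalized[keep]
        meta = None if self.cell_meta is None else self.cell_meta.iloc[np.flatnonzero(keep) if keep.dtype == bool else keep]
        return CellMatrix(
            counts=counts,
            cell_ids=self.cell_ids[keep],
            gene_ids=self.gene_ids,
            mito_mask=self.mito_mask,
            layer_normalized=layer,
            cell_meta=meta,
        )


@dataclass
class PseudotimeTable:
    """Named per-cell pseudotime vectors accumulated over the pipeline."""

    cell_ids: np.ndarray
    columns: dict[str, np.ndarray] = field(default_factory=dict)

    def set(self, name: str, values: np.ndarray) -> None:
        values = np.asarray(values, dtype=float)
        if len(values) != len(self.cell_ids):
            raise ValidationError(
                f"column {name!r} has {len(values)} values for {len(self.cell_ids)} cells"
            )
        self.columns[name] = values

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.columns, index=pd.Index(self.cell_ids, name="cell_id"))


def make_mito_mask(gene_ids, pattern: str = DEFAULT_MITO_REGEX) -> np.ndarray:
    """Flag mitochondrial genes by symbol regex (case-insensitive by default)."""
    rx = re.compile(pattern, re.IGNORECASE)
    return np.array([bool(rx.search(str(g))) for g in gene_ids], dtype=bool)


# ---------------------------------------------------------------------
# count loading
# ---------------------------------------------------------------------

def _read_ids(path: Path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t", header=None)
    return df.iloc[:, 0].astype(str).to_numpy(dtype=object)


def load_counts(
    path,
    format: str = "mtx_dir",
    transpose: bool = False,
    mito_regex: str = DEFAULT_MITO_REGEX,
) -> CellMatrix:
    """Read a count matrix into a :class:`CellMatrix`.

    ``mtx_dir`` expects ``matrix.mtx`` plus ``barcodes.tsv`` and
    ``features.tsv`` (or ``genes.tsv``) sidecars; the matrix may be stored
    in either orientation and is aligned to cells × genes from the sidecar
    lengths.  ``csv`` expects cells in rows and genes in columns (use
    ``transpose=True`` for gene-major files).  ``h5`` reads an ``.h5ad``
    container (the ``X`` matrix is taken as counts).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input path does not exist: {path}")

    if format == "mtx_dir":
        mtx = path / "matrix.mtx"
        barcodes = path / "barcodes.tsv"
        features = path / "features.tsv"
        if not features.exists():
            features = path / "genes.tsv"
        for f in (mtx, barcodes, features):
            if not f.exists():
                raise FileNotFoundError(f"missing file in MTX directory: {f}")
        m = scipy.io.mmread(mtx).tocsr()
        cells = _read_ids(barcodes)
        genes = _read_ids(features)
        if m.shape == (len(genes), len(cells)) and m.shape != (len(cells), len(genes)):
            m = m.T.tocsr()
        elif m.shape != (len(cells), len(genes)):
            raise ValidationError(
                f"matrix shape {m.shape} matches neither "
                f"(cells={len(cells)}, genes={len(genes)}) nor its transpose"
            )
    elif format == "csv":
        df = pd.read_csv(path, index_col=0)
        if transpose:
            df = df.T
        m = df.to_numpy(dtype=float)
        cells = df.index.astype(str).to_numpy(dtype=object)
        genes = df.columns.astype(str).to_numpy(dtype=object)
    elif format == "h5":
        import anndata as ad

        adata = ad.read_h5ad(path)
        m = adata.X
        if sp.issparse(m):
            m = m.tocsr()
        cells = adata.obs_names.astype(str).to_numpy(dtype=object)
        genes = adata.var_names.astype(str).to_numpy(dtype=object)
    else:
        raise ValueError(f"unknown format {format!r}; expected mtx_dir, csv or h5")

    return CellMatrix(
        counts=m,
        cell_ids=cells,
        gene_ids=genes,
        mito_mask=make_mito_mask(genes, mito_regex),
    )


# ---------------------------------------------------------------------
# result tables
# ---------------------------------------------------------------------

def write_results(table: PseudotimeTable, states, graph, out_dir) -> dict[str, Path]:
    """Write the per-cell table and the cluster-graph edge list as TSV.

    ``states`` is a :class:`ltnn.states.StateAssignment`, ``graph`` a
    :class:`ltnn.transitions.ClusterGraph`.  Returns the written paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if not np.array_equal(np.asarray(table.cell_ids), np.asarray(states.cell_ids)):
        raise ValidationError("pseudotime table and state assignment cover different cells")

    cells = table.to_frame()
    cells["state"] = states.state
    cells["cluster"] = states.cluster
    cell_path = out_dir / "cells.tsv"
    cells.to_csv(cell_path, sep="\t", float_format="%.12g")

    rows = []
    retained = set(map(tuple, graph.retained_edges))
    n = graph.n_clusters
    for i in range(n):
        for j in range(n):
            if i == j or graph.weights[i, j] == 0:
                continue
            rows.append(
                {
                    "source": i,
                    "target": j,
                    "w": graph.weights[i, j],
                    "T": graph.confidence[i, j],
                    "retained": int((i, j) in retained),
                }
            )
    edges = pd.DataFrame(rows, columns=["source", "target", "w", "T", "retained"])
    edge_path = out_dir / "cluster_graph.tsv"
    edges.to_csv(edge_path, sep="\t", index=False, float_format="%.12g")
    return {"cells": cell_path, "edges": edge_path}


def read_results(out_dir) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read back what :func:`write_results` wrote."""
    out_dir = Path(out_dir)
    cells = pd.read_csv(out_dir / "cells.tsv", sep="\t", index_col=0)
    edges = pd.read_csv(out_dir / "cluster_graph.tsv", sep="\t")
    return cells, edges


# ---------------------------------------------------------------------
# model persistence
# ---------------------------------------------------------------------

def save_model(model, path) -> Path:
    """Serialize a trained regressor (plus the LSI factors it expects).

    The file embeds the architecture hyperparameters and, when attached,
    the latent-space factors needed to project a fresh dataset, so a
    pre-trained model can be reused end to end.
    """
    path = Path(path)
    payload: dict[str, np.ndarray] = {
        "format_version": np.array(MODEL_FORMAT_VERSION),
        "spec_json": np.frombuffer(
            json.dumps(model.spec.to_dict()).encode(), dtype=np.uint8
        ),
    }
    for i, (w, b) in enumerate(zip(model.weights, model.biases)):
        payload[f"w{i}"] = w
        payload[f"b{i}"] = b
    if model.lsi is not None:
        payload["lsi_components"] = model.lsi.components
        payload["lsi_singular_values"] = model.lsi.singular_values
        payload["lsi_gene_ids"] = np.asarray(model.lsi.gene_ids, dtype="U")
    np.savez(path, **payload)
    return path


def load_model(path):
    """Inverse of :func:`save_model`; predictions are bitwise identical."""
    from .ann import RegressorSpec, TrainedRegressor
    from .lsi import LSIEmbedding

    path = Path(path)
    try:
        data = np.load(path, allow_pickle=False)
    except Exception as exc:  # corrupted or not an npz
        raise ValidationError(f"cannot parse model file {path}: {exc}") from exc
    if "format_version" not in data:
        raise ValidationError(f"{path} is not a model file (no format_version)")
    version = int(data["format_version"])
    if version != MODEL_FORMAT_VERSION:
        raise ValidationError(
            f"model file version {version} does not match code version "
            f"{MODEL_FORMAT_VERSION}"
        )
    spec = RegressorSpec.from_dict(json.loads(bytes(data["spec_json"]).decode()))
    weights, biases = [], []
    i = 0
    while f"w{i}" in data:
        weights.append(data[f"w{i}"])
        biases.append(data[f"b{i}"])
        i += 1
    lsi = None
    if "lsi_components" in data:
        comp = data["lsi_components"]
        sv = data["lsi_singular_values"]
        lsi = LSIEmbedding(
            scores=np.zeros((0, comp.shape[0])),
            components=comp,
            singular_values=sv,
            gene_ids=data["lsi_gene_ids"].astype(object),
        )
    return TrainedRegressor(spec=spec, weights=weights, biases=biases, lsi=lsi)
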