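"""Latent semantic indexing of the HVG expression matrix.

A rank-k truncated SVD of the normalized cell × HVG matrix,
``X ~ U_k S_k V_k^T``; cell scores are ``U_k S_k`` and the right singular
vectors are kept so fresh cells can be projected into a fitted space.
The decomposition is exact and deterministic (no randomized solver), with
a sign convention that makes serialized models reproducible: each
component's entry of largest magnitude is made positive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg

from .io import CellMatrix, ValidationError
from .preprocess import HVGResult

log = logging.getLogger(__name__)


@dataclass
class LSIEmbedding:
    scores: np.ndarray            # cells x k  (U_k S_k)
    components: np.ndarray        # k x genes  (V_k^T), rows orthonormal
    singular_values: np.ndarray   # k, nonincreasing
    gene_ids: np.ndarray

    @property
    def rank(self) -> int:
        return len(self.singular_values)


def _fix_signs(u: np.ndarray, vt: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    for i in range(vt.shape[0]):
        j = int(np.argmax(np.abs(vt[i])))
        if vt[i, j] < 0:
            vt[i] *= -1
            u[:, i] *= -1
    return u, vt


def fit_lsi(m: CellMatrix, hvg: HVGResult, k: int = 20) -> LSIEmbedding:
    """Truncated SVD of the normalized cell × selected-HVG matrix."""
    if k < 1:
        raise ValidationError(f"LSI rank must be >= 1; got {k}")
    x = m.layer_normalized
    if x is None:
        raise ValidationError("normalized layer not present; run normalize_total first")
    sel = hvg.selected_mask
    x = x[:, sel] if not sp.issparse(x) else x.tocsc()[:, sel]
    n_cells, n_sel = x.shape
    if k > min(n_cells, n_sel):
        raise ValidationError(
            f"LSI rank {k} exceeds min(n_cells={n_cells}, n_genes={n_sel})"
        )
    if sp.issparse(x) and min(x.shape) > 2000 and k < min(x.shape) - 1:
        v0 = np.ones(min(x.shape))
        u, s, vt = sp.linalg.svds(x.asfptype(), k=k, v0=v0)
        order = np.argsort(s)[::-1]
        u, s, vt = u[:, order], s[order], vt[order]
    else:
        xd = x.toarray() if sp.issparse(x) else np.asarray(x, dtype=float)
        u, s, vt = np.linalg.svd(xd, full_matrices=False)
        u, s, vt = u[:, :k], s[:k], vt[:k]
    u, vt = _fix_signs(u, vt)
    return LSIEmbedding(
        scores=u * s,
        components=vt,
        singular_values=s,
        gene_ids=m.gene_ids[sel],
    )


def transform_lsi(emb: LSIEmbedding, m: CellMatrix) -> np.ndarray:
    """Project normalized cells onto a fitted latent space.

    Genes are matched by id; genes absent from the new matrix contribute
    zeros.  Applying this to the training matrix reproduces the fitted
    scores (X V_k = U_k S_k).
    """
    x = m.layer_normalized
    if x is None:
        raise ValidationError("normalized layer not present; run normalize_total first")
    pos = {g: i for i, g in enumerate(m.gene_ids)}
    idx = np.array([pos.get(g, -1) for g in emb.gene_ids])
    overlap = int((idx >= 0).sum())
    if overlap == 0:
        raise ValidationError("no gene overlap with the fitted latent space")
    if overlap < 0.5 * len(emb.gene_ids):
        log.warning(
            "only %d of %d latent-space genes present in the data",
            overlap,
            len(emb.gene_ids),
        )
    xd = x.toarray() if sp.issparse(x) else np.asarray(x, dtype=float)
    aligned = np.zeros((m.n_cells, len(emb.gene_ids)))
    present = idx >= 0
    aligned[:, present] = xd[:, idx[present]]
    return aligned @ emb.components.T
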