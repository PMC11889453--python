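"""Quality control, normalization, highly-variable-gene selection and the
HVG distribution-feature statistics.

The HVG ranking follows the variance-stabilizing approach popularized by
Seurat v3: a smooth mean-variance trend is fitted to per-gene statistics of
the raw counts on the log10 scale, each gene's counts are standardized by
the trend-predicted standard deviation with clipping at sqrt(n_cells), and
genes are scored by the variance of the clipped standardized values.  The
trend here is a low-degree polynomial rather than a loess smoother; the
degree is configurable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.stats import ks_2samp

from .io import CellMatrix, ValidationError

log = logging.getLogger(__name__)


@dataclass
class HVGResult:
    """Ranked gene variability with a top-``hvg_count`` selection mask.

    ``ranked_gene_ids`` is ordered by decreasing score (ties broken by
    lexical gene id); ``scores`` and ``selected_mask`` are aligned with the
    gene order of the matrix the ranking was computed on.
    """

    gene_ids: np.ndarray          # matrix gene order
    ranked_gene_ids: np.ndarray   # decreasing score
    scores: np.ndarray            # aligned with gene_ids
    selected_mask: np.ndarray     # aligned with gene_ids
    nhvg_mask: np.ndarray | None = None

    @property
    def n_selected(self) -> int:
        return int(self.selected_mask.sum())


@dataclass
class DistributionFeatures:
    """Per-cell summary statistics of selected-HVG expression."""

    max: np.ndarray
    mean: np.ndarray
    median: np.ndarray
    std: np.ndarray
    label: str = ""


def qc_filter(
    m: CellMatrix, min_counts: int = 1000, max_mito_frac: float = 0.2
) -> CellMatrix:
    """Drop low-depth and high-mitochondrial cells.

    A cell is kept when its total count is at least ``min_counts`` and the
    fraction of counts mapped to mitochondrial genes does not exceed
    ``max_mito_frac`` (strictly above the cut is dropped).  The gene set is
    unchanged and the operation is idempotent.
    """
    counts = m.counts
    totals = np.asarray(counts.sum(axis=1)).ravel()
    if m.mito_mask.any():
        mito = np.asarray(counts[:, m.mito_mask].sum(axis=1)).ravel()
    else:
        mito = np.zeros_like(totals)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(totals > 0, mito / np.maximum(totals, 1e-300), 0.0)
    keep = (totals >= min_counts) & (frac <= max_mito_frac)
    n_removed = int((~keep).sum())
    if not keep.any():
        raise ValidationError(
            "QC removed every cell; lower min_counts "
            f"(currently {min_counts}) or raise max_mito_frac "
            f"(currently {max_mito_frac})"
        )
    log.info(
        "qc_filter: removed %d of %d cells (%d low-count, %d high-mito)",
        n_removed,
        m.n_cells,
        int((totals < min_counts).sum()),
        int((frac > max_mito_frac).sum()),
    )
    return m.subset_cells(keep)


def normalize_total(
    m: CellMatrix, target_sum: float | None = None, log1p: bool = False
) -> CellMatrix:
    """Depth-normalize each cell by its total molecule count.

    Fills ``layer_normalized`` with counts / cell total, optionally scaled
    to ``target_sum`` and log(1+x)-transformed.  Raw counts are retained.
    """
    totals = np.asarray(m.counts.sum(axis=1)).ravel()
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValidationError(
            f"cells with zero total counts cannot be normalized: "
            f"{list(m.cell_ids[zero[:5]])}"
        )
    scale = (target_sum if target_sum is not None else 1.0) / totals
    if sp.issparse(m.counts):
        x = sp.diags(scale) @ m.counts.tocsr()
        if log1p:
            x = x.copy()
            x.data = np.log1p(x.data)
    else:
        x = m.counts_dense() * scale[:, None]
        if log1p:
            x = np.log1p(x)
    return CellMatrix(
        counts=m.counts,
        cell_ids=m.cell_ids,
        gene_ids=m.gene_ids,
        mito_mask=m.mito_mask,
        layer_normalized=x,
        cell_meta=m.cell_meta,
    )


def _gene_mean_var(counts) -> tuple[np.ndarray, np.ndarray]:
    n = counts.shape[0]
    if sp.issparse(counts):
        counts = counts.tocsc()
        mean = np.asarray(counts.mean(axis=0)).ravel()
        sq = np.asarray(counts.multiply(counts).mean(axis=0)).ravel()
    else:
        x = np.asarray(counts, dtype=float)
        mean = x.mean(axis=0)
        sq = (x * x).mean(axis=0)
    var = (sq - mean**2) * n / max(n - 1, 1)
    return mean, np.maximum(var, 0.0)


def variability_scores(
    m: CellMatrix, trend_degree: int = 2
) -> np.ndarray:
    """Clipped-standardized-variance score per gene on raw counts."""
    n = m.n_cells
    mean, var = _gene_mean_var(m.counts)
    scores = np.zeros(m.n_genes)
    usable = (mean > 0) & (var > 0)
    if usable.sum() >= trend_degree + 1:
        lm, lv = np.log10(mean[usable]), np.log10(var[usable])
        coef = np.polyfit(lm, lv, deg=trend_degree)
        pred_sd = np.sqrt(10.0 ** np.polyval(coef, np.log10(mean[usable])))
    else:  # too few genes for a trend; fall back to raw sd
        pred_sd = np.sqrt(var[usable])
    x = m.counts_dense()[:, usable]
    z = (x - mean[usable][None, :]) / pred_sd[None, :]
    np.clip(z, None, np.sqrt(n), out=z)
    scores[usable] = z.var(axis=0, ddof=1)
    return scores


def select_hvgs(
    m: CellMatrix, hvg_count: int = 10_000, trend_degree: int = 2
) -> HVGResult:
    """Rank genes by variance-stabilized dispersion and select the top set.

    Ties are broken by lexical gene-id order; a gene constant across all
    cells scores 0 and ranks last.
    """
    if hvg_count < 1:
        raise ValidationError(f"hvg_count must be >= 1; got {hvg_count}")
    if m.n_cells < 2:
        raise ValidationError("HVG selection needs at least 2 cells")
    scores = variability_scores(m, trend_degree=trend_degree)
    order = np.lexsort((m.gene_ids.astype(str), -scores))
    n_sel = min(hvg_count, m.n_genes)
    selected = np.zeros(m.n_genes, dtype=bool)
    selected[order[:n_sel]] = True
    return HVGResult(
        gene_ids=m.gene_ids,
        ranked_gene_ids=m.gene_ids[order],
        scores=scores,
        selected_mask=selected,
    )


def nhvg_set(
    hvg: HVGResult, m: CellMatrix, recurrence_frac: float = 0.1
) -> np.ndarray:
    """Non-HVGs detected in at least ``recurrence_frac`` of cells.

    Returns the gene ids and records the mask on ``hvg.nhvg_mask``; the set
    is disjoint from the selected HVGs by construction.
    """
    counts = m.counts
    if sp.issparse(counts):
        detected = np.asarray((counts > 0).sum(axis=0)).ravel()
    else:
        detected = (np.asarray(counts) > 0).sum(axis=0)
    recur = detected / m.n_cells >= recurrence_frac
    mask = recur & ~hvg.selected_mask
    hvg.nhvg_mask = mask
    return m.gene_ids[mask]


def distribution_features(
    m: CellMatrix, hvg: HVGResult, label: str = ""
) -> DistributionFeatures:
    """Per-cell max / mean / median / std over the selected-HVG columns of
    the normalized layer (the median of an even-length vector is the mean
    of the two central order statistics)."""
    x = m.normalized_dense()[:, hvg.selected_mask]
    return DistributionFeatures(
        max=x.max(axis=1),
        mean=x.mean(axis=1),
        median=np.median(x, axis=1),
        std=x.std(axis=1),
        label=label,
    )


def ks_similarity(a, b) -> float:
    """Two-sample Kolmogorov-Smirnov statistic sup_x |ECDF_a - ECDF_b|."""
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("ks_similarity requires nonempty samples")
    return float(ks_2samp(a, b, method="asymp").statistic)


def ks_similarity_matrix(features: list[DistributionFeatures]) -> np.ndarray:
    """Symmetric pairwise KS statistics over per-cell std feature vectors."""
    k = len(features)
    out = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            out[i, j] = out[j, i] = ks_similarity(features[i].std, features[j].std)
    return out
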