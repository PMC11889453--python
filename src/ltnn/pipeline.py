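"""End-to-end pseudotime inference.

Chains the stages: QC and normalization, HVG selection, latent semantic
indexing, pre-trained-regressor latent time, orientation, embedding
clustering, origin/middle/end state calling, diffusion pseudotime,
refinement regression, distribution merge, and the directed cluster
transition graph.  All randomness derives from ``RunConfig.seed``, so a
fixed configuration reproduces identical labels and pseudotimes
run-to-run.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass

import numpy as np

from . import ann, merge, metrics, preprocess, states, transitions
from .config import RunConfig
from .io import CellMatrix, PseudotimeTable, ValidationError
from .lsi import LSIEmbedding, fit_lsi

log = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    matrix: CellMatrix                      # post-QC, normalized
    table: PseudotimeTable
    states: states.StateAssignment
    graph: transitions.ClusterGraph
    neighbor_graph: states.NeighborGraph
    hvg: preprocess.HVGResult
    lsi: LSIEmbedding
    pre_model: ann.TrainedRegressor
    re_model: ann.TrainedRegressor
    fit_dw: merge.DistributionFit
    fit_n: merge.DistributionFit


def run_pipeline(
    matrix: CellMatrix,
    training_time: np.ndarray,
    config: RunConfig | None = None,
    mst: bool = False,
    annotation_column: str | None = None,
    pre_model: ann.TrainedRegressor | None = None,
) -> PipelineResult:
    """Run the full inference on a raw count matrix.

    ``training_time`` is the per-cell training latent-time vector (aligned
    with ``matrix.cell_ids``); it is only used to fit the first regressor
    and may be omitted (None) when a ``pre_model`` with attached latent
    factors is supplied.  ``annotation_column`` names a ``cell_meta``
    column used to label clusters for evaluation.
    """
    cfg = config or RunConfig()

    # --- preprocessing ------------------------------------------------
    kept = preprocess.qc_filter(
        matrix, min_counts=cfg.min_counts, max_mito_frac=cfg.max_mito_frac
    )
    if training_time is not None:
        training_time = np.asarray(training_time, dtype=float)
        if len(training_time) != matrix.n_cells:
            raise ValidationError(
                f"{len(training_time)} training times for {matrix.n_cells} cells"
            )
        pos = {c: i for i, c in enumerate(matrix.cell_ids)}
        training_time = training_time[[pos[c] for c in kept.cell_ids]]
    m = preprocess.normalize_total(
        kept, target_sum=cfg.target_sum, log1p=cfg.log1p
    )
    hvg = preprocess.select_hvgs(m, hvg_count=cfg.hvg_count)

    # --- latent space + first regressor -------------------------------
    if pre_model is not None and pre_model.lsi is not None:
        from .lsi import transform_lsi

        emb = pre_model.lsi
        scores = transform_lsi(emb, m)
        model = pre_model
    else:
        emb = fit_lsi(m, hvg, k=cfg.lsi_rank)
        scores = emb.scores
        if pre_model is not None:
            model = pre_model
        else:
            if training_time is None:
                raise ValidationError(
                    "either a training latent-time vector or a pre-trained "
                    "model is required"
                )
            spec = ann.RegressorSpec(
                input_dim=cfg.lsi_rank,
                batch_size=cfg.batch_size,
                epochs=cfg.epochs,
                learning_rate=cfg.learning_rate,
                weight_decay=cfg.weight_decay,
                patience=cfg.patience,
                seed=cfg.seed,
            )
            model = ann.train_regressor(scores, training_time, spec)
            model.lsi = emb

    t_ann = ann.predict_time(model, scores)
    t_p = states.orient_time(
        t_ann,
        m,
        low=cfg.orient_low,
        high=cfg.orient_high,
        score=cfg.diversity_score,
        flip=cfg.flip_orientation,
    )

    # --- clustering + states ------------------------------------------
    emb512 = ann.extract_embedding(model, scores)
    g, labels = states.cluster_cells(
        emb512,
        n_neighbors=cfg.n_neighbors,
        resolution=cfg.resolution,
        seed=cfg.seed + 3,
    )
    timeline = states.position_fluctuation_threshold(t_p, labels)
    st = states.assign_origin_end(
        t_p,
        labels,
        timeline,
        cell_ids=m.cell_ids,
        origin_frac=cfg.origin_frac,
        end_frac=cfg.end_frac,
    )
    t_dpt = states.compute_dpt(
        scores,
        st.root_index,
        n_components=cfg.dpt_components,
        n_neighbors=cfg.n_neighbors,
    )
    st = states.assign_middle(t_dpt, st, middle_frac=cfg.middle_frac)

    # --- refinement + merge -------------------------------------------
    idx, targets = merge.build_reann_targets(st, seed=cfg.seed + 1)
    re_spec = ann.RegressorSpec(
        input_dim=scores.shape[1],
        batch_size=cfg.batch_size,
        epochs=cfg.epochs,
        learning_rate=cfg.learning_rate,
        weight_decay=cfg.weight_decay,
        patience=cfg.patience,
        seed=cfg.seed + 2,
    )
    re_model, t_reann = merge.train_reann(scores, idx, targets, re_spec)
    re_model.lsi = emb
    fit_dw = merge.fit_dweibull(t_dpt)
    fit_n = merge.fit_normal(t_reann)
    t_ltnn = merge.merge_times(t_reann, t_dpt, fit_dw, fit_n)

    # --- transition graph ---------------------------------------------
    edges = transitions.filter_edges_by_time(g, t_ltnn, labels, epsilon=cfg.epsilon)
    n_clusters = int(labels.max()) + 1
    cluster_times = np.array(
        [t_ltnn[labels == c].mean() for c in range(n_clusters)]
    )
    names = None
    if annotation_column is not None:
        if m.cell_meta is None or annotation_column not in m.cell_meta:
            raise ValidationError(
                f"annotation column {annotation_column!r} not in cell_meta"
            )
        names = metrics.majority_labels(
            labels, m.cell_meta[annotation_column].to_numpy()
        )
    cg = transitions.transition_confidence(
        edges, labels, cluster_times=cluster_times, names=names
    )
    cg = transitions.apply_threshold(cg, floor=cfg.confidence_floor)
    if mst and cg.retained_edges:
        cg = transitions.prune_mst(cg)

    table = PseudotimeTable(cell_ids=m.cell_ids)
    table.set("pre_ann_time", t_ann)
    table.set("oriented_time", t_p)
    table.set("dpt_time", t_dpt)
    table.set("reann_time", t_reann)
    table.set("ltnn_time", t_ltnn)

    return PipelineResult(
        matrix=m,
        table=table,
        states=st,
        graph=cg,
        neighbor_graph=g,
        hvg=hvg,
        lsi=emb,
        pre_model=model,
        re_model=re_model,
        fit_dw=fit_dw,
        fit_n=fit_n,
    )
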