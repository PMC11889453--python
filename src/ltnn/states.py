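"""Cell-state determination.

Orient the predicted latent time with a transcriptional-diversity score,
cluster cells on the regressor's penultimate embedding, derive the
position-fluctuation threshold from adjacent cluster mean times, and call
origin / middle / end states; diffusion pseudotime from an origin root
pins down the middle state.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import igraph
import leidenalg
import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from sklearn.neighbors import NearestNeighbors

from .io import CellMatrix, ValidationError

log = logging.getLogger(__name__)


@dataclass
class NeighborGraph:
    """Symmetric kNN graph with edge distances."""

    n_neighbors: int
    adjacency: sp.csr_matrix  # symmetric, entries = Euclidean distances
    metric: str = "euclidean"

    def edge_list(self) -> np.ndarray:
        """Undirected edges as an (m, 2) array with i < j."""
        coo = sp.triu(self.adjacency, k=1).tocoo()
        return np.column_stack([coo.row, coo.col])


@dataclass
class ClusterTimeline:
    """Clusters ordered by mean oriented time, with adjacent-gap statistics."""

    cluster_ids: np.ndarray   # sorted by mean time, ascending
    times: np.ndarray         # mean oriented time per cluster, ascending
    gaps: np.ndarray          # adjacent differences, length n_clusters - 1
    mean_gap: float           # the position-fluctuation threshold


@dataclass
class StateAssignment:
    """Per-cell origin / middle / end / other labels plus supporting data."""

    cell_ids: np.ndarray
    state: np.ndarray               # object array of labels
    cluster: np.ndarray             # int labels
    t_p: np.ndarray                 # oriented time
    timeline: ClusterTimeline | None = None
    root_cell: object = None
    root_index: int | None = None

    def mask(self, label: str) -> np.ndarray:
        return self.state == label

    @property
    def origin_mask(self) -> np.ndarray:
        return self.mask("origin")

    @property
    def middle_mask(self) -> np.ndarray:
        return self.mask("middle")

    @property
    def end_mask(self) -> np.ndarray:
        return self.mask("end")


# ---------------------------------------------------------------------
# orientation
# ---------------------------------------------------------------------

def diversity_scores(m: CellMatrix, kind: str = "gene_count") -> np.ndarray:
    """Per-cell transcriptional-diversity signal.

    ``gene_count`` counts the genes detected (count > 0) in each cell;
    ``mean_expression`` averages the normalized expression instead.
    """
    if kind == "gene_count":
        c = m.counts
        if sp.issparse(c):
            return np.asarray((c > 0).sum(axis=1)).ravel().astype(float)
        return (np.asarray(c) > 0).sum(axis=1).astype(float)
    if kind == "mean_expression":
        return m.normalized_dense().mean(axis=1)
    raise ValidationError(f"unknown diversity score {kind!r}")


def orient_time(
    t_ann: np.ndarray,
    m: CellMatrix,
    low: float = 0.2,
    high: float = 0.8,
    score: str = "gene_count",
    flip: bool = False,
) -> np.ndarray:
    """Fix the direction of the predicted latent time.

    Cells with predicted time below ``low`` and above ``high`` are compared
    on mean transcriptional diversity; if the high-time group is the more
    diverse the time is kept, otherwise it is reversed (1 - t).  ``flip``
    inverts the decision for datasets where the diversity signal points the
    other way.
    """
    t_ann = np.asarray(t_ann, dtype=float)
    i_low = t_ann < low
    i_high = t_ann > high
    if not i_low.any() or not i_high.any():
        raise ValidationError(
            f"orientation needs cells below {low} and above {high}; "
            f"got {int(i_low.sum())} low and {int(i_high.sum())} high — "
            "adjust the thresholds"
        )
    e = diversity_scores(m, score)
    c_low = float(e[i_low].mean())
    c_high = float(e[i_high].mean())
    keep = c_high > c_low
    if flip:
        keep = not keep
    log.info(
        "orient_time: diversity low=%.2f high=%.2f -> %s",
        c_low,
        c_high,
        "keep" if keep else "reverse",
    )
    return t_ann if keep else 1.0 - t_ann


# ---------------------------------------------------------------------
# neighbor graph + clustering
# ---------------------------------------------------------------------

def knn_graph(x: np.ndarray, n_neighbors: int = 15) -> NeighborGraph:
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    if n < n_neighbors + 1:
        raise ValidationError(
            f"need at least n_neighbors+1={n_neighbors + 1} cells; got {n}"
        )
    if n <= 4000:
        # dense distances with tie-inclusive neighborhoods: every point
        # within the k-th neighbor distance counts, so exact duplicates
        # get structurally identical rows
        from scipy.spatial.distance import cdist

        d = cdist(x, x)
        np.fill_diagonal(d, np.inf)
        kth = np.partition(d, n_neighbors - 1, axis=1)[:, n_neighbors - 1]
        rows, cols = np.nonzero(d <= kth[:, None] + 1e-12)
        vals = d[rows, cols]
    else:
        nn = NearestNeighbors(n_neighbors=n_neighbors + 1).fit(x)
        dist, idx = nn.kneighbors(x)
        rows = np.repeat(np.arange(n), n_neighbors)
        cols = idx[:, 1:].ravel()
        vals = dist[:, 1:].ravel()
    # duplicate points give zero distances; floor them at a tiny positive
    # value so those edges survive sparse storage
    vals = np.maximum(vals, 1e-12)
    a = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    a = a.maximum(a.T)  # symmetrize (union of directed kNN edges)
    a.setdiag(0)
    a.eliminate_zeros()
    return NeighborGraph(n_neighbors=n_neighbors, adjacency=a)


def cluster_cells(
    emb: np.ndarray,
    n_neighbors: int = 15,
    resolution: float = 1.0,
    seed: int = 0,
) -> tuple[NeighborGraph, np.ndarray]:
    """Leiden community detection on the kNN graph of the embedding.

    Labels are integers 0..n_clusters-1 ordered by decreasing cluster size
    and are reproducible for a fixed seed.
    """
    g = knn_graph(emb, n_neighbors=n_neighbors)
    edges = g.edge_list()
    ig = igraph.Graph(n=emb.shape[0], edges=[tuple(e) for e in edges])
    part = leidenalg.find_partition(
        ig,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=seed,
    )
    raw = np.asarray(part.membership)
    # relabel by decreasing size, ties by original label for determinism
    labels, counts = np.unique(raw, return_counts=True)
    order = np.lexsort((labels, -counts))
    remap = {old: new for new, old in enumerate(labels[order])}
    return g, np.array([remap[v] for v in raw], dtype=int)


# ---------------------------------------------------------------------
# timeline / origin / end
# ---------------------------------------------------------------------

def cluster_mean_times(t: np.ndarray, labels: np.ndarray) -> dict[int, float]:
    return {int(c): float(t[labels == c].mean()) for c in np.unique(labels)}


def position_fluctuation_threshold(
    t_p: np.ndarray, labels: np.ndarray
) -> ClusterTimeline:
    """Mean gap between adjacent cluster mean times.

    Sort cluster mean oriented times ascending; with n clusters there are
    exactly n-1 adjacent gaps and the threshold is their mean.
    """
    means = cluster_mean_times(np.asarray(t_p, float), np.asarray(labels))
    if len(means) < 2:
        raise ValidationError(
            "position-fluctuation threshold needs >= 2 clusters; got "
            f"{len(means)}"
        )
    cids = np.array(sorted(means, key=lambda c: (means[c], c)))
    times = np.array([means[c] for c in cids])
    gaps = np.diff(times)
    return ClusterTimeline(
        cluster_ids=cids, times=times, gaps=gaps, mean_gap=float(gaps.mean())
    )


def _rank_fraction(t: np.ndarray, frac: float, from_top: bool) -> np.ndarray:
    n = len(t)
    k = max(1, int(np.floor(frac * n + 1e-9)))
    order = np.argsort(t, kind="stable")
    return order[-k:] if from_top else order[:k]


def assign_origin_end(
    t_p: np.ndarray,
    labels: np.ndarray,
    timeline: ClusterTimeline,
    cell_ids: np.ndarray | None = None,
    origin_frac: float = 0.10,
    end_frac: float = 0.10,
) -> StateAssignment:
    """Call origin and end cells.

    Origin clusters are those whose mean time lies within the
    position-fluctuation threshold of the earliest cluster time; the origin
    set is their cells intersected with the lowest ``origin_frac`` of cells
    by oriented-time rank (falling back to the pure rank fraction if the
    intersection is empty).  The end set is symmetric at the top.
    """
    t_p = np.asarray(t_p, dtype=float)
    labels = np.asarray(labels)
    n = len(t_p)
    if cell_ids is None:
        cell_ids = np.arange(n)
    cell_ids = np.asarray(cell_ids, dtype=object)

    gap = timeline.mean_gap
    origin_clusters = set(
        int(c)
        for c, m in zip(timeline.cluster_ids, timeline.times)
        if m <= timeline.times[0] + gap
    )
    end_clusters = set(
        int(c)
        for c, m in zip(timeline.cluster_ids, timeline.times)
        if m >= timeline.times[-1] - gap
    )

    low_idx = _rank_fraction(t_p, origin_frac, from_top=False)
    high_idx = _rank_fraction(t_p, end_frac, from_top=True)
    origin = np.array([i for i in low_idx if int(labels[i]) in origin_clusters])
    end = np.array([i for i in high_idx if int(labels[i]) in end_clusters])
    if origin.size == 0:
        origin = low_idx
    if end.size == 0:
        end = high_idx
    if set(origin) & set(end):
        raise ValidationError(
            "origin and end sets overlap; the time spread is degenerate"
        )

    state = np.full(n, "other", dtype=object)
    state[origin] = "origin"
    state[end] = "end"
    root_index = int(origin[np.argmin(t_p[origin])])
    return StateAssignment(
        cell_ids=cell_ids,
        state=state,
        cluster=labels.astype(int),
        t_p=t_p,
        timeline=timeline,
        root_cell=cell_ids[root_index],
        root_index=root_index,
    )


# ---------------------------------------------------------------------
# diffusion pseudotime
# ---------------------------------------------------------------------

def compute_dpt(
    x: np.ndarray,
    root_index: int,
    n_components: int = 10,
    n_neighbors: int = 15,
) -> np.ndarray:
    """Diffusion pseudotime from a root cell, normalized to [0, 1].

    A Gaussian kernel (width = median neighbor distance) on the kNN graph
    is symmetrically normalized; eigenvectors are scaled by
    lambda/(1-lambda) (the stationary eigenvalue is dropped) and pseudotime
    is the Euclidean distance to the root in that scaled component space,
    min-max normalized so the root sits at 0 and the farthest cell at 1.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    if n < n_components + 2:
        raise ValidationError(
            f"diffusion needs at least n_components+2={n_components + 2} cells"
        )
    if not 0 <= root_index < n:
        raise ValidationError(f"root index {root_index} out of range")
    g = knn_graph(x, n_neighbors=n_neighbors)
    a = g.adjacency.tocoo()

    n_comp, comp = connected_components(g.adjacency, directed=False)
    if n_comp > 1:
        sizes = np.bincount(comp)
        raise ValidationError(
            f"neighbor graph is disconnected ({n_comp} components, sizes "
            f"{sorted(sizes.tolist(), reverse=True)}); increase n_neighbors"
        )

    sigma = float(np.median(a.data[a.data > 0])) if (a.data > 0).any() else 1.0
    if sigma <= 0:
        sigma = 1.0
    w = sp.csr_matrix(
        (np.exp(-(a.data**2) / (2 * sigma**2)), (a.row, a.col)), shape=(n, n)
    )
    d = np.asarray(w.sum(axis=1)).ravel()
    d_inv_sqrt = 1.0 / np.sqrt(np.maximum(d, 1e-300))
    s = sp.diags(d_inv_sqrt) @ w @ sp.diags(d_inv_sqrt)

    k = n_components + 1
    if n <= 3000:
        vals, vecs = np.linalg.eigh(s.toarray())
        vals, vecs = vals[::-1][:k], vecs[:, ::-1][:, :k]
    else:
        vals, vecs = sp.linalg.eigsh(s, k=k, which="LA", v0=np.ones(n))
        order = np.argsort(vals)[::-1]
        vals, vecs = vals[order], vecs[:, order]

    # recover right eigenvectors of the transition matrix and drop the
    # stationary component (lambda = 1)
    psi = vecs[:, 1:] * d_inv_sqrt[:, None]
    lam = np.clip(vals[1:], -1 + 1e-12, 1 - 1e-12)
    coords = psi * (lam / (1 - lam))[None, :]
    dist = np.linalg.norm(coords - coords[root_index], axis=1)
    hi = dist.max()
    return dist / hi if hi > 0 else dist


def assign_middle(
    t_dpt: np.ndarray,
    states: StateAssignment,
    middle_frac: float = 0.10,
) -> StateAssignment:
    """Complete the state assignment with the middle set.

    Candidates are cells (outside origin/end) in clusters whose mean
    diffusion pseudotime lies between the origin- and end-cluster means;
    the ``middle_frac`` of cells closest to the median diffusion pseudotime
    is labeled middle.  If the cluster restriction leaves too few
    candidates it is dropped.
    """
    t_dpt = np.asarray(t_dpt, dtype=float)
    n = len(t_dpt)
    k = max(1, int(np.floor(middle_frac * n + 1e-9)))
    med = float(np.median(t_dpt))

    labels = states.cluster
    means = cluster_mean_times(t_dpt, labels)
    o_clusters = set(labels[states.origin_mask].tolist())
    e_clusters = set(labels[states.end_mask].tolist())
    bounds = sorted(
        [min(means[c] for c in o_clusters), max(means[c] for c in e_clusters)]
    )
    in_band = np.array([bounds[0] <= means[int(c)] <= bounds[1] for c in labels])
    free = states.state == "other"
    cand = np.flatnonzero(in_band & free)
    if cand.size < k:
        cand = np.flatnonzero(free)
    if cand.size == 0:
        raise ValidationError("middle set is empty; all cells are origin/end")
    pick = cand[np.argsort(np.abs(t_dpt[cand] - med), kind="stable")[:k]]
    state = states.state.copy()
    state[pick] = "middle"
    return StateAssignment(
        cell_ids=states.cell_ids,
        state=state,
        cluster=states.cluster,
        t_p=states.t_p,
        timeline=states.timeline,
        root_cell=states.root_cell,
        root_index=states.root_index,
    )
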