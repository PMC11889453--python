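"""Pseudotime-directed cluster transition graph.

Undirected kNN edges are oriented by per-cell pseudotime and kept only when
the target cell's cluster is not earlier than the source cell's cluster by
more than epsilon.  Directed inter-cluster edge counts w_ij, normalized by
the product of cluster sizes, give the transition confidence
T_ij = w_ij / (N_i N_j); a data-driven threshold retains the most confident
transitions, and a maximum-weight spanning tree can optionally prune
redundant direct edges whose confidence does not beat the bottleneck of the
indirect path.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .io import ValidationError
from .states import NeighborGraph

log = logging.getLogger(__name__)


@dataclass
class ClusterGraph:
    sizes: np.ndarray                   # N_i per cluster
    weights: np.ndarray                 # w_ij directed inter-cluster counts
    confidence: np.ndarray              # T_ij = w_ij / (N_i N_j)
    cluster_times: np.ndarray | None = None   # mean pseudotime per cluster
    threshold: float | None = None
    retained_edges: list[tuple[int, int]] = field(default_factory=list)
    names: list[str] | None = None      # optional cluster annotation labels

    @property
    def n_clusters(self) -> int:
        return len(self.sizes)


def filter_edges_by_time(
    g: NeighborGraph,
    t: np.ndarray,
    labels: np.ndarray,
    epsilon: float = 0.1,
) -> np.ndarray:
    """Orient and filter cell-level kNN edges by pseudotime.

    Each undirected edge {i, j} yields the directed edge i -> j exactly
    when t(i) < t(j) and the mean pseudotime of j's cluster exceeds that of
    i's cluster minus epsilon.  Returns an (m, 2) array of directed edges.
    """
    t = np.asarray(t, dtype=float)
    labels = np.asarray(labels)
    n = g.adjacency.shape[0]
    if len(t) != n or len(labels) != n:
        raise ValidationError("pseudotime/labels do not cover all graph cells")
    means = {int(c): float(t[labels == c].mean()) for c in np.unique(labels)}
    out = []
    for i, j in g.edge_list():
        if t[i] < t[j]:
            src, dst = int(i), int(j)
        elif t[j] < t[i]:
            src, dst = int(j), int(i)
        else:
            continue
        if means[int(labels[dst])] > means[int(labels[src])] - epsilon:
            out.append((src, dst))
    return np.array(out, dtype=int).reshape(-1, 2)


def transition_confidence(
    edges: np.ndarray,
    labels: np.ndarray,
    cluster_times: np.ndarray | None = None,
    names: list[str] | None = None,
) -> ClusterGraph:
    """Count directed inter-cluster edges and normalize by size products."""
    labels = np.asarray(labels, dtype=int)
    n_clusters = int(labels.max()) + 1 if labels.size else 0
    sizes = np.bincount(labels, minlength=n_clusters)
    w = np.zeros((n_clusters, n_clusters), dtype=float)
    for src, dst in np.asarray(edges, dtype=int).reshape(-1, 2):
        ci, cj = labels[src], labels[dst]
        if ci != cj:
            w[ci, cj] += 1
    denom = np.outer(sizes, sizes).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, w / denom, 0.0)
    return ClusterGraph(
        sizes=sizes, weights=w, confidence=t, cluster_times=cluster_times,
        names=names,
    )


def compute_threshold(t: np.ndarray, floor: float = 0.01) -> float | None:
    """max(min(columnwise positive maxima) - 1e-6, floor).

    Columns with no positive entry are skipped; an all-zero matrix has no
    threshold (None).
    """
    t = np.asarray(t, dtype=float)
    col_maxima = []
    for j in range(t.shape[1]):
        col = t[:, j]
        pos = col[col > 0]
        if pos.size:
            col_maxima.append(pos.max())
    if not col_maxima:
        return None
    return max(min(col_maxima) - 1e-6, floor)


def apply_threshold(cg: ClusterGraph, floor: float = 0.01) -> ClusterGraph:
    """Retain directed edges whose confidence reaches the threshold."""
    thr = compute_threshold(cg.confidence, floor=floor)
    if thr is None:
        log.warning("transition confidence matrix is all zero; nothing retained")
        return dataclasses.replace(cg, threshold=None, retained_edges=[])
    n = cg.n_clusters
    retained = [
        (i, j)
        for i in range(n)
        for j in range(n)
        if i != j and cg.confidence[i, j] >= thr
    ]
    return dataclasses.replace(cg, threshold=thr, retained_edges=retained)


def annotation_transition_graph(
    g: NeighborGraph,
    t: np.ndarray,
    annotation: np.ndarray,
    epsilon: float = 0.1,
    floor: float = 0.01,
) -> ClusterGraph:
    """Transition graph over annotated cell-type groups.

    For evaluation against a labeled ground truth the cell groups are the
    annotation labels themselves (the way curated cell types are fed to a
    partition-graph routine), not de-novo clusters: each label is one
    node, edges are time-filtered kNN edges, and the same confidence and
    threshold rules apply.
    """
    annotation = np.asarray(annotation, dtype=object)
    names = sorted({str(a) for a in annotation})
    code = {name: i for i, name in enumerate(names)}
    labels = np.array([code[str(a)] for a in annotation], dtype=int)
    edges = filter_edges_by_time(g, t, labels, epsilon=epsilon)
    t = np.asarray(t, dtype=float)
    times = np.array([t[labels == i].mean() for i in range(len(names))])
    cg = transition_confidence(edges, labels, cluster_times=times, names=names)
    return apply_threshold(cg, floor=floor)


def prune_mst(cg: ClusterGraph) -> ClusterGraph:
    """Prune the retained graph with a maximum-weight spanning tree.

    The tree is built on the undirected view of the retained confidences
    (a maximum tree: a minimum one would keep the least confident
    transitions).  A non-tree direct edge i -> j survives only if its
    confidence exceeds the bottleneck (minimum edge weight) along the tree
    path between i and j.  Tree edges keep the direction from lower to
    higher cluster mean pseudotime when cluster times are available.
    Disconnected retained graphs are pruned per component.
    """
    if not cg.retained_edges:
        raise ValidationError("no retained edges to prune")
    und = nx.Graph()
    und.add_nodes_from(range(cg.n_clusters))
    for i, j in cg.retained_edges:
        w = cg.confidence[i, j]
        if und.has_edge(i, j):
            und[i][j]["weight"] = max(und[i][j]["weight"], w)
        else:
            und.add_edge(i, j, weight=w)
    tree = nx.maximum_spanning_tree(und, weight="weight")
    tree_pairs = {frozenset(e) for e in tree.edges}

    kept: list[tuple[int, int]] = []
    seen: set[tuple[int, int]] = set()
    for i, j in cg.retained_edges:
        pair = frozenset((i, j))
        if pair in tree_pairs:
            if cg.cluster_times is not None:
                src, dst = (i, j) if cg.cluster_times[i] <= cg.cluster_times[j] else (j, i)
            else:
                src, dst = i, j
            if (src, dst) not in seen:
                kept.append((src, dst))
                seen.add((src, dst))
        else:
            path = nx.shortest_path(tree, i, j)
            bottleneck = min(
                tree[a][b]["weight"] for a, b in zip(path[:-1], path[1:])
            )
            if cg.confidence[i, j] > bottleneck and (i, j) not in seen:
                kept.append((i, j))
                seen.add((i, j))
    return dataclasses.replace(cg, retained_edges=kept)
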