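"""Trajectory evaluation against a ground-truth milestone network.

A milestone network is a directed weighted graph over cell-type labels.
Evaluation covers: the transitions rate (fraction of annotated transitions
with nonzero confidence), the terminal-rate probability (precision of
true terminal cells among cells with pseudotime above a cut), and the
normalized Hamming and Jaccard distances between binarized networks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import ValidationError
from .transitions import ClusterGraph


@dataclass
class MilestoneNetwork:
    """Directed weighted graph of cell-type milestones."""

    nodes: list[str]
    edges: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.nodes)) != len(self.nodes):
            raise ValidationError("milestone node labels must be unique")
        for (s, t), w in self.edges.items():
            if w < 0:
                raise ValidationError(f"negative edge weight on {s}->{t}")

    @classmethod
    def from_edge_list(cls, edges: list[tuple[str, str, float]]) -> "MilestoneNetwork":
        nodes: list[str] = []
        ed: dict[tuple[str, str], float] = {}
        for s, t, w in edges:
            for v in (s, t):
                if v not in nodes:
                    nodes.append(v)
            ed[(s, t)] = float(w)
        return cls(nodes=nodes, edges=ed)

    @classmethod
    def from_tsv(cls, path) -> "MilestoneNetwork":
        df = pd.read_csv(path, sep="\t")
        cols = list(df.columns[:3])
        return cls.from_edge_list(
            [(str(r[cols[0]]), str(r[cols[1]]), float(r[cols[2]]))
             for _, r in df.iterrows()]
        )

    def to_tsv(self, path) -> Path:
        path = Path(path)
        rows = [
            {"source": s, "target": t, "weight": w}
            for (s, t), w in self.edges.items()
        ]
        pd.DataFrame(rows, columns=["source", "target", "weight"]).to_csv(
            path, sep="\t", index=False
        )
        return path

    def edge_set(self) -> set[tuple[str, str]]:
        return {e for e, w in self.edges.items() if w > 0}


def _aligned_binary(a: MilestoneNetwork, b: MilestoneNetwork):
    nodes = sorted(set(a.nodes) | set(b.nodes))
    pos = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    ma = np.zeros((n, n), dtype=bool)
    mb = np.zeros((n, n), dtype=bool)
    for (s, t) in a.edge_set():
        ma[pos[s], pos[t]] = True
    for (s, t) in b.edge_set():
        mb[pos[s], pos[t]] = True
    return ma, mb


def hamming_distance(a: MilestoneNetwork, b: MilestoneNetwork) -> float:
    """Fraction of differing off-diagonal entries of the binarized
    adjacencies; nodes are aligned by label, missing nodes isolated."""
    ma, mb = _aligned_binary(a, b)
    n = ma.shape[0]
    if n < 2:
        return 0.0
    diff = ma != mb
    np.fill_diagonal(diff, False)
    return float(diff.sum()) / (n * (n - 1))


def jaccard_distance(a: MilestoneNetwork, b: MilestoneNetwork) -> float:
    """1 - |intersection| / |union| of the directed edge sets; two empty
    networks are at distance 0."""
    ea, eb = a.edge_set(), b.edge_set()
    union = ea | eb
    if not union:
        return 0.0
    return 1.0 - len(ea & eb) / len(union)


def transitions_rate(
    cg: ClusterGraph, annotated_pairs: list[tuple[str, str]]
) -> float:
    """Fraction of annotated (source, target) label pairs with a positive
    transition confidence between any correspondingly labeled clusters."""
    if cg.names is None:
        raise ValidationError("cluster graph carries no annotation labels")
    names = list(cg.names)
    valid = sorted(set(names))
    if not annotated_pairs:
        raise ValidationError("no annotated pairs given")
    hits = 0
    for s, t in annotated_pairs:
        if s not in valid or t not in valid:
            raise ValidationError(
                f"unknown label in pair ({s!r}, {t!r}); valid labels: {valid}"
            )
        ok = any(
            cg.confidence[i, j] > 0
            for i in range(cg.n_clusters)
            for j in range(cg.n_clusters)
            if names[i] == s and names[j] == t
        )
        hits += bool(ok)
    return hits / len(annotated_pairs)


def terminal_rate(
    t: np.ndarray, true_terminal: np.ndarray, cut: float = 0.95
) -> float:
    """Precision of true terminal cells among 'temporal terminal' cells.

    Temporal terminal cells are those with pseudotime strictly above
    ``cut`` (a value exactly at the cut is not terminal).
    """
    t = np.asarray(t, dtype=float)
    true_terminal = np.asarray(true_terminal, dtype=bool)
    temporal = t > cut
    if not temporal.any():
        raise ValidationError(f"no cell has pseudotime above {cut}")
    return float(true_terminal[temporal].mean())


def terminal_recall(
    t: np.ndarray, true_terminal: np.ndarray, cut: float = 0.95
) -> float:
    """Secondary reading of the terminal ratio: fraction of true terminal
    cells that are temporal terminal."""
    t = np.asarray(t, dtype=float)
    true_terminal = np.asarray(true_terminal, dtype=bool)
    if not true_terminal.any():
        raise ValidationError("no true terminal cells")
    return float((t[true_terminal] > cut).mean())


def majority_labels(cluster: np.ndarray, annotation: np.ndarray) -> list[str]:
    """Label each cluster by the most common per-cell annotation (ties by
    lexical order)."""
    cluster = np.asarray(cluster, dtype=int)
    annotation = np.asarray(annotation, dtype=object)
    out = []
    for c in range(cluster.max() + 1):
        vals, counts = np.unique(annotation[cluster == c].astype(str), return_counts=True)
        order = np.lexsort((vals, -counts))
        out.append(str(vals[order[0]]))
    return out


def inferred_network(cg: ClusterGraph, retained_only: bool = True) -> MilestoneNetwork:
    """Collapse a cluster graph to an annotation-label-level network.

    Edge weight between labels is the summed confidence over the
    corresponding cluster pairs (self-transitions between clusters sharing
    a label are dropped).
    """
    if cg.names is None:
        raise ValidationError("cluster graph carries no annotation labels")
    pairs = (
        cg.retained_edges
        if retained_only
        else [
            (i, j)
            for i in range(cg.n_clusters)
            for j in range(cg.n_clusters)
            if i != j and cg.confidence[i, j] > 0
        ]
    )
    edges: dict[tuple[str, str], float] = {}
    for i, j in pairs:
        s, t = cg.names[i], cg.names[j]
        if s == t:
            continue
        edges[(s, t)] = edges.get((s, t), 0.0) + float(cg.confidence[i, j])
    nodes = sorted(set(cg.names))
    return MilestoneNetwork(nodes=nodes, edges=edges)
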