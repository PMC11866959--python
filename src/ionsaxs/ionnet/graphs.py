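"""Packing neighborhood graphs into disjoint-union batches.

Training and inference operate on a batch of graphs packed into one large
disjoint graph: node features are concatenated, edge indices are offset, and
constant sparse operators (the GCN-normalized adjacency and the mean-pool
matrix) are assembled once per batch.  Edges are stored directed (both
orientations of every undirected pair) plus one self-loop per node.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.sparse as sp

from ..probes import EDGE_CUTOFF, NeighborhoodGraph

__all__ = ["PreparedGraph", "GraphBatch", "prepare_graph", "pack"]


@dataclass(frozen=True)
class PreparedGraph:
    """Per-graph arrays ready for concatenation into a batch."""

    X: np.ndarray          # (n, F)
    src: np.ndarray        # directed edges incl. self-loops
    dst: np.ndarray
    dist: np.ndarray       # edge distances / EDGE_CUTOFF (0 for self-loops)
    gcn_w: np.ndarray      # symmetric normalization 1/sqrt(deg_u deg_v)
    label: int | None


def prepare_graph(graph: NeighborhoodGraph) -> PreparedGraph:
    n = graph.n_nodes
    e = graph.edges
    if e.size:
        src = np.concatenate([e[:, 0], e[:, 1], np.arange(n)])
        dst = np.concatenate([e[:, 1], e[:, 0], np.arange(n)])
        dist = np.concatenate([graph.edge_distances, graph.edge_distances,
                               np.zeros(n)]) / EDGE_CUTOFF
    else:
        src = dst = np.arange(n)
        dist = np.zeros(n)
    deg = np.bincount(dst, minlength=n).astype(float)  # includes self-loop
    gcn_w = 1.0 / np.sqrt(deg[src] * deg[dst])
    return PreparedGraph(X=graph.node_features.astype(float), src=src.astype(int),
                         dst=dst.astype(int), dist=dist.astype(float),
                         gcn_w=gcn_w, label=graph.label)


@dataclass
class GraphBatch:
    """A disjoint union of graphs with its constant sparse operators."""

    X: np.ndarray              # (N, F)
    src: np.ndarray            # (E,)
    dst: np.ndarray            # (E,)
    dist: np.ndarray           # (E,)
    A_hat: sp.csr_matrix       # (N, N) GCN-normalized adjacency
    pool: sp.csr_matrix        # (G, N) mean pooling
    labels: np.ndarray | None  # (G,) float, when all graphs are labeled

    @property
    def n_nodes(self) -> int:
        return self.X.shape[0]

    @property
    def n_graphs(self) -> int:
        return self.pool.shape[0]


def pack(graphs: Sequence[NeighborhoodGraph | PreparedGraph]) -> GraphBatch:
    prepared = [g if isinstance(g, PreparedGraph) else prepare_graph(g)
                for g in graphs]
    if not prepared:
        raise ValueError("cannot pack an empty graph list")
    sizes = np.array([p.X.shape[0] for p in prepared])
    offsets = np.concatenate([[0], np.cumsum(sizes)[:-1]])
    N = int(sizes.sum())
    G = len(prepared)

    X = np.concatenate([p.X for p in prepared])
    src = np.concatenate([p.src + o for p, o in zip(prepared, offsets)])
    dst = np.concatenate([p.dst + o for p, o in zip(prepared, offsets)])
    dist = np.concatenate([p.dist for p in prepared])
    gcn_w = np.concatenate([p.gcn_w for p in prepared])

    A_hat = sp.csr_matrix((gcn_w, (dst, src)), shape=(N, N))
    node_graph = np.repeat(np.arange(G), sizes)
    pool = sp.csr_matrix((1.0 / sizes[node_graph], (node_graph, np.arange(N))),
                         shape=(G, N))
    labels = None
    if all(p.label is not None for p in prepared):
        labels = np.array([float(p.label) for p in prepared])
    return GraphBatch(X=X, src=src, dst=dst, dist=dist, A_hat=A_hat,
                      pool=pool, labels=labels)
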