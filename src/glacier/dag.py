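"""Spatial DAG construction and per-lag ancestor aggregation.

Cells become vertices; edges are spatial k-nearest-neighbour pairs oriented
from higher to lower spatial potential (isodepth), which guarantees
acyclicity.  Lag-ℓ features aggregate expression from ℓ-step ancestors via
row-normalized powers of the adjacency matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field
from typing import Optional

import numpy as np
import scipy.sparse as sp

from .data import DataValidationError
from .isodepth import IsodepthField, invert_isodepth

logger = logging.getLogger("glacier")


def build_knn_graph(
    coords: np.ndarray, k: int, mutual: bool = False
) -> set[tuple[int, int]]:
    """Union-symmetrized k-NN pairs under Euclidean distance.

    Returns undirected pairs ``(i, j)`` with ``i < j`` where i is among j's k
    nearest neighbours or vice versa (``mutual=True`` requires both).
    Distance ties are broken deterministically by vertex index.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if n < 2:
        raise DataValidationError("need at least 2 cells for a k-NN graph")
    if not 1 <= k < n:
        raise DataValidationError(f"k={k} must satisfy 1 <= k < N={n}")
    if np.unique(coords, axis=0).shape[0] < n:
        raise DataValidationError(
            "duplicate coordinates; jitter or deduplicate before graph construction"
        )
    if n <= 4096:
        # Dense path: lexicographic (distance, index) ordering makes tie
        # handling exactly reproducible.
        d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1)
        np.fill_diagonal(d2, np.inf)
        idx = np.arange(n)
        neighbors = np.empty((n, k), dtype=int)
        for i in range(n):
            order = np.lexsort((idx, d2[i]))
            neighbors[i] = order[:k]
    else:
        from sklearn.neighbors import NearestNeighbors

        nn = NearestNeighbors(n_neighbors=k + 1).fit(coords)
        _, ind = nn.kneighbors(coords)
        neighbors = np.array(
            [[j for j in row if j != i][:k] for i, row in enumerate(ind)]
        )
    directed = {(i, j) for i in range(n) for j in neighbors[i]}
    if mutual:
        pairs = {(min(i, j), max(i, j)) for (i, j) in directed if (j, i) in directed}
    else:
        pairs = {(min(i, j), max(i, j)) for (i, j) in directed}
    return pairs


@dataclass
class SpatialDAG:
    """Directed acyclic graph over cells, oriented by a spatial potential.

    ``edges`` is an (E, 2) array of (parent, child) with strictly decreasing
    potential along every edge.
    """

    n_vertices: int
    edges: np.ndarray
    source_field: Optional[IsodepthField] = None
    k: Optional[int] = None
    n_dropped_ties: int = 0

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=int).reshape(-1, 2)

    @property
    def n_edges(self) -> int:
        return self.edges.shape[0]

    def adjacency(self) -> sp.csr_matrix:
        """0/1 adjacency with A[u, v] = 1 for edge u -> v."""
        if self.n_edges == 0:
            return sp.csr_matrix((self.n_vertices, self.n_vertices))
        data = np.ones(self.n_edges)
        return sp.csr_matrix(
            (data, (self.edges[:, 0], self.edges[:, 1])),
            shape=(self.n_vertices, self.n_vertices),
        )

    def edge_set(self) -> set[tuple[int, int]]:
        return {(int(u), int(v)) for u, v in self.edges}


def orient_edges(
    pairs: set[tuple[int, int]], field: IsodepthField, k: Optional[int] = None
) -> SpatialDAG:
    """Orient undirected pairs from higher to lower isodepth.

    Edge i -> j is created iff d_i > d_j; equal-potential pairs are dropped
    (their count is recorded), preserving strict descent and hence
    acyclicity.
    """
    d = field.values
    edges = []
    dropped = 0
    for i, j in sorted(pairs):
        if d[i] > d[j]:
            edges.append((i, j))
        elif d[j] > d[i]:
            edges.append((j, i))
        else:
            dropped += 1
    dag = SpatialDAG(
        n_vertices=d.size,
        edges=np.array(edges, dtype=int).reshape(-1, 2),
        source_field=field,
        k=k,
        n_dropped_ties=dropped,
    )
    _check_acyclic(dag)
    if dropped:
        logger.info("dropped %d equal-isodepth ties while orienting", dropped)
    return dag


def _check_acyclic(dag: SpatialDAG) -> None:
    # Strict descent along the potential already implies acyclicity; this
    # independent check guards attach paths that bypass orientation.
    if dag.source_field is not None:
        d = dag.source_field.values
        if dag.n_edges and not (d[dag.edges[:, 0]] > d[dag.edges[:, 1]]).all():
            raise DataValidationError("edge violates strict potential descent")
        return
    import networkx as nx

    g = nx.DiGraph()
    g.add_nodes_from(range(dag.n_vertices))
    g.add_edges_from(map(tuple, dag.edges))
    if not nx.is_directed_acyclic_graph(g):
        raise DataValidationError("graph contains a directed cycle")


def reverse_dag(dag: SpatialDAG) -> SpatialDAG:
    """Reverse every edge; equals re-orienting under inverted isodepth."""
    fld = None
    if dag.source_field is not None:
        fld = invert_isodepth(dag.source_field)
    return SpatialDAG(
        n_vertices=dag.n_vertices,
        edges=dag.edges[:, ::-1].copy(),
        source_field=fld,
        k=dag.k,
        n_dropped_ties=dag.n_dropped_ties,
    )


@dataclass
class LagOperators:
    """Row-substochastic ancestor-aggregation matrices, one per lag.

    ``ops[l-1][v, u] > 0`` iff a directed walk u -> ... -> v of length l
    exists; each nonzero row sums to 1 (walk-count-weighted average over
    l-step ancestors), and rows of vertices with no l-step ancestor are
    exactly zero.
    """

    ops: list[sp.csr_matrix]
    max_lag: int

    def apply(self, lag: int, X: np.ndarray) -> np.ndarray:
        """Aggregate columns of X from lag-step ancestors (lag is 1-based)."""
        return np.asarray(self.ops[lag - 1] @ X)


def build_lag_operators(dag: SpatialDAG, max_lag: int) -> LagOperators:
    """Normalized powers of the transposed adjacency.

    The l-th operator is the row-normalization of ``(A^T)^l`` where A is the
    0/1 adjacency (A[u, v] = 1 for u -> v), so features flow parent ->
    child and the lag-l feature of a vertex is the walk-weighted average of
    its l-step ancestors' values.
    """
    if max_lag < 1:
        raise ValueError("max_lag must be >= 1")
    At = sp.csr_matrix(dag.adjacency().T)
    ops = []
    power = sp.identity(dag.n_vertices, format="csr")
    for _ in range(max_lag):
        power = sp.csr_matrix(power @ At)
        rs = np.asarray(power.sum(axis=1)).ravel()
        inv = np.divide(1.0, rs, out=np.zeros_like(rs), where=rs > 0)
        ops.append(sp.csr_matrix(sp.diags(inv) @ power))
    return LagOperators(ops=ops, max_lag=max_lag)


def write_dag(dag: SpatialDAG, path) -> None:
    """Edge-list TSV (parent, child)."""
    import pandas as pd

    pd.DataFrame(dag.edges, columns=["parent", "child"]).to_csv(
        path, sep="\t", index=False
    )


def read_dag(path, n_vertices: int) -> SpatialDAG:
    import pandas as pd

    edges = pd.read_csv(path, sep="\t").to_numpy(int)
    dag = SpatialDAG(n_vertices=n_vertices, edges=edges)
    _check_acyclic(dag)
    return dag
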