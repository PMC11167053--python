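"""Pruned Delaunay cell graph and hop-distance statistics between categories.

Cells become nodes at their centroids; edges come from the Delaunay
triangulation, pruned of edges longer than a physical interaction range
(default 40 µm).  The mean hop distance from category g to category g' is

    D(g, g') = mean over cells i with C_i = g of  min_{j : C'_j = g'} d_ij,

with d_ij the hop distance (edge count) in the pruned graph.  For each g'
a single multi-source breadth-first traversal from all g' nodes yields the
per-node minima, so the whole matrix costs |G'| traversals.  The matrix is
asymmetric in general because of the minimum.  Cells with no finite path
to any g' node are excluded from the mean and counted separately.
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import Delaunay, QhullError

from .core import CellCollection, ValidationError

MAX_EDGE_LENGTH = 40.0  # µm; longer edges cannot be physical cell-cell contacts
NETWORK_EPSILON = 0.5   # hops; clamp for inverse-distance network weights


@dataclass
class SpatialGraph:
    """Undirected cell graph with retained Delaunay simplices.

    ``nodes`` are cell ids, ``positions`` their centroids (µm).  ``simplices``
    holds index triples (positions into ``nodes``) of triangles whose three
    edges all survived pruning; niche polygonization consumes them.
    """

    nodes: np.ndarray
    positions: np.ndarray
    graph: nx.Graph
    simplices: np.ndarray = field(default_factory=lambda: np.empty((0, 3), int))

    def __len__(self) -> int:
        return len(self.nodes)

    @property
    def node_index(self) -> dict:
        return {int(n): i for i, n in enumerate(self.nodes)}


def build_graph(cells: CellCollection | np.ndarray,
                max_edge_length: float = MAX_EDGE_LENGTH,
                node_ids: np.ndarray | None = None) -> SpatialGraph:
    """Delaunay-triangulate cell centroids and prune non-physical edges.

    Accepts a CellCollection or an (N, 2) centroid array.  Edges longer than
    ``max_edge_length`` are dropped, as are simplices containing a dropped
    edge.  Degenerate inputs (fewer than 3 points, collinear points) yield
    an edge-only graph connecting pairs within range; duplicate centroids
    are jittered by 1e-9 µm with a fixed seed.
    """
    if isinstance(cells, CellCollection):
        pos = cells.centroids
        ids = cells.cell_ids
    else:
        pos = np.asarray(cells, float)
        ids = np.arange(len(pos)) if node_ids is None else np.asarray(node_ids)
    g = nx.Graph()
    g.add_nodes_from(int(i) for i in ids)
    n = len(pos)
    if n == 0:
        return SpatialGraph(np.asarray(ids), pos.reshape(0, 2), g)

    uniq, inverse = np.unique(pos, axis=0, return_inverse=True)
    if len(uniq) < n:
        warnings.warn("duplicate centroids jittered by 1e-9 µm")
        rng = np.random.default_rng(0)
        pos = pos + rng.uniform(-1e-9, 1e-9, size=pos.shape)

    edges: set[tuple[int, int]] = set()
    simplices = np.empty((0, 3), int)
    if n >= 3:
        try:
            tri = Delaunay(pos)
            raw_simplices = tri.simplices
            for s in raw_simplices:
                for a, b in ((s[0], s[1]), (s[1], s[2]), (s[0], s[2])):
                    edges.add((min(a, b), max(a, b)))
        except QhullError:
            raw_simplices = None
    else:
        raw_simplices = None
    if raw_simplices is None:  # degenerate: all pairs within range
        edges = {(i, j) for i in range(n) for j in range(i + 1, n)}

    def length(i: int, j: int) -> float:
        return float(np.hypot(*(pos[i] - pos[j])))

    kept = {(i, j) for i, j in edges if length(i, j) <= max_edge_length}
    for i, j in kept:
        g.add_edge(int(ids[i]), int(ids[j]), length=length(i, j))
    if raw_simplices is not None:
        ok = [s for s in raw_simplices
              if all((min(a, b), max(a, b)) in kept
                     for a, b in ((s[0], s[1]), (s[1], s[2]), (s[0], s[2])))]
        simplices = np.array(sorted(tuple(sorted(s)) for s in ok), int).reshape(-1, 3)
    return SpatialGraph(np.asarray(ids), pos, g, simplices)


def _multi_source_hops(sg: SpatialGraph, sources: np.ndarray) -> np.ndarray:
    """Min hop distance from every node to the nearest source, -1 if unreachable.

    Hand-rolled multi-source BFS over index-based adjacency.
    """
    n = len(sg.nodes)
    index = sg.node_index
    adj: list[list[int]] = [[] for _ in range(n)]
    for u, v in sg.graph.edges:
        iu, iv = index[int(u)], index[int(v)]
        adj[iu].append(iv)
        adj[iv].append(iu)
    dist = np.full(n, -1, dtype=np.int64)
    queue = deque()
    for s in sources:
        dist[s] = 0
        queue.append(int(s))
    while queue:
        u = queue.popleft()
        for v in adj[u]:
            if dist[v] < 0:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


@dataclass
class DistanceResult:
    D: pd.DataFrame         # mean hop distance, rows G, cols G'
    excluded: pd.DataFrame  # cells with no finite path, same shape


def hop_distance_matrix(sg: SpatialGraph, C, C_prime=None) -> DistanceResult:
    """Mean hop-distance matrix between two category assignments.

    ``C`` and ``C_prime`` are per-cell labels aligned with ``sg.nodes``
    (``C_prime`` defaults to ``C``).  Entry (g, g') averages, over cells of
    category g, the hop distance to the nearest cell of category g'; a g'
    cell is at distance 0 from itself.  Unreachable cells are excluded from
    the mean and reported in ``excluded``; an entry with no reachable cell
    at all is NaN.
    """
    C = np.asarray(list(C))
    C_prime = C if C_prime is None else np.asarray(list(C_prime))
    if len(C) != len(sg.nodes) or len(C_prime) != len(sg.nodes):
        raise ValidationError("category assignments must cover all graph nodes")
    G = sorted(set(C))
    Gp = sorted(set(C_prime))
    D = pd.DataFrame(np.nan, index=G, columns=Gp, dtype=float)
    excl = pd.DataFrame(0, index=G, columns=Gp, dtype=int)
    members = {g: np.nonzero(C == g)[0] for g in G}
    for gp in Gp:
        sources = np.nonzero(C_prime == gp)[0]
        hops = _multi_source_hops(sg, sources)
        for g in G:
            d = hops[members[g]]
            finite = d[d >= 0]
            excl.loc[g, gp] = int((d < 0).sum())
            if finite.size:
                D.loc[g, gp] = float(finite.mean())
    return DistanceResult(D, excl)


def build_network(matrices: dict[tuple[str, str], pd.DataFrame],
                  epsilon: float = NETWORK_EPSILON) -> nx.Graph:
    """Combine directed distance matrices into an inverse-distance network.

    ``matrices`` maps (row_set, col_set) names — e.g. ("type", "niche") —
    to distance DataFrames.  For each unordered label pair the finite
    directed entries are averaged and the edge weight is
    ``1 / max(D_mean, epsilon)``; label pairs with no finite distance get
    no edge.  The lower the mean distance, the higher the weight.
    """
    net = nx.Graph()
    pair_values: dict[tuple, list[float]] = {}
    for (row_set, col_set), D in matrices.items():
        for u in D.index:
            net.add_node(u, kind=row_set)
        for v in D.columns:
            net.add_node(v, kind=col_set)
        for u in D.index:
            for v in D.columns:
                if u == v:
                    continue
                val = D.loc[u, v]
                if np.isfinite(val):
                    key = (u, v) if str(u) <= str(v) else (v, u)
                    pair_values.setdefault(key, []).append(float(val))
    for (u, v), vals in pair_values.items():
        d_mean = float(np.mean(vals))
        net.add_edge(u, v, distance=d_mean, weight=1.0 / max(d_mean, epsilon))
    return net
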