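"""Niche polygonization and geometry statistics.

Per-cell niche labels are turned into polygons through the pruned Delaunay
graph: edges joining cells of different niches are removed, each remaining
connected component is one *occurrence* of a niche, and the component's
shape is the union of its retained Delaunay triangles.  That region's
boundary is recovered combinatorially: border edges are the edges belonging
to exactly one retained triangle of the component; linking them produces
one or more closed rings.  A single ring is the polygon outline; with
several rings the largest-area ring is the exterior and the others are
holes (a component fully surrounded by another niche).

Per niche we then report occurrence count and mean area A, perimeter L and
roundness R = 4πA/L² ∈ (0, 1] (1 for a disc), after dropping components
smaller than 5% of the niche's largest component, and the cell density
(total retained cells / total retained area).
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import Polygon
from shapely.ops import unary_union

from .core import ValidationError
from .graph import SpatialGraph

MIN_AREA_FRACTION = 0.05  # drop occurrences below 5% of the niche's largest


@dataclass
class NicheComponent:
    """One polygonal occurrence of a niche."""

    niche: str
    # exterior ring with optional holes, world µm; a MultiPolygon for the
    # rare pinch-vertex components whose lobes touch at a single cell
    polygon: Polygon
    n_cells: int
    triangle_area: float  # Σ areas of the retained Delaunay triangles

    @property
    def area(self) -> float:
        """Net area (exterior minus holes), µm²."""
        return self.polygon.area

    @property
    def perimeter(self) -> float:
        """Exterior plus hole-ring perimeter, µm."""
        return self.polygon.length

    @property
    def roundness(self) -> float:
        return 4 * math.pi * self.area / self.perimeter**2


def _ring_area(coords: np.ndarray) -> float:
    """Absolute shoelace area of a closed ring given as (k, 2) vertices."""
    x, y = coords[:, 0], coords[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def _link_rings(border_edges: list[tuple[int, int]], pos: np.ndarray,
                ) -> list[list[int]]:
    """Link border edges into closed vertex rings.

    Vertices normally have exactly two incident border edges; at
    non-manifold junctions (more than two) the walk takes the leftmost
    continuation (smallest clockwise turn from the incoming direction),
    which deterministically splits the junction into simple rings.
    """
    unused = set(border_edges)
    incident: dict[int, list[tuple[int, int]]] = {}
    for e in border_edges:
        incident.setdefault(e[0], []).append(e)
        incident.setdefault(e[1], []).append(e)
    if any(len(v) > 2 for v in incident.values()):
        warnings.warn("non-manifold niche border; splitting rings by turn rule")

    def turn(u: int, v: int, w: int) -> float:
        d = pos[v] - pos[u]
        e = pos[w] - pos[v]
        return math.atan2(d[0] * e[1] - d[1] * e[0], d[0] * e[0] + d[1] * e[1])

    rings: list[list[int]] = []
    while unused:
        start = min(unused)
        unused.discard(start)
        ring = [start[0], start[1]]
        while ring[-1] != ring[0]:
            u, v = ring[-2], ring[-1]
            candidates = []
            for e in incident[v]:
                if e in unused:
                    w = e[1] if e[0] == v else e[0]
                    candidates.append((e, w))
            if not candidates:
                break  # open chain; dropped below
            if len(candidates) == 1:
                e, w = candidates[0]
            else:
                e, w = max(candidates, key=lambda cw: (turn(u, v, cw[1]), -cw[1]))
            unused.discard(e)
            ring.append(w)
        if len(ring) >= 4 and ring[-1] == ring[0]:
            rings.append(ring[:-1])
    return rings


def _assemble_rings(coords: list[np.ndarray]):
    """Build the component geometry from its border rings.

    The largest ring is the exterior; each further ring becomes a hole of
    the exterior (or of an earlier lobe) that covers it, otherwise it is a
    separate lobe of the same component (a figure-eight touching at a pinch
    vertex).  Lobes are unioned into one geometry.
    """
    order = np.argsort([-_ring_area(c) for c in coords], kind="stable")
    exteriors: list[dict] = []
    for i in order:
        ring = Polygon(coords[i])
        placed = False
        for ext in exteriors:
            if ext["shell"].covers(ring):
                ext["holes"].append(coords[i])
                placed = True
                break
        if not placed:
            exteriors.append({"shell": ring, "holes": []})
    polys = [Polygon(np.asarray(e["shell"].exterior.coords), e["holes"])
             for e in exteriors]
    geom = polys[0] if len(polys) == 1 else unary_union(polys)
    if not geom.is_valid:
        geom = geom.buffer(0)
    return geom


def extract_niche_polygons(sg: SpatialGraph, niche) -> list[NicheComponent]:
    """Convert per-cell niche labels into polygon components.

    ``niche`` is a per-cell label sequence aligned with ``sg.nodes``.
    Components with fewer than 3 cells carry no triangle and are skipped
    with a warning.
    """
    labels = np.asarray(list(niche))
    if len(labels) != len(sg.nodes):
        raise ValidationError("niche labels must cover all graph nodes")
    index = sg.node_index
    n = len(sg.nodes)

    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for u, v in sg.graph.edges:
        iu, iv = index[int(u)], index[int(v)]
        if labels[iu] == labels[iv]:
            ri, rj = find(iu), find(iv)
            if ri != rj:
                parent[max(ri, rj)] = min(ri, rj)

    comp_nodes: dict[int, list[int]] = {}
    for i in range(n):
        comp_nodes.setdefault(find(i), []).append(i)

    comp_simplices: dict[int, list[np.ndarray]] = {}
    for s in sg.simplices:
        a, b, c = (int(v) for v in s)
        if labels[a] == labels[b] == labels[c]:
            root = find(a)
            if find(b) == root and find(c) == root:
                comp_simplices.setdefault(root, []).append(s)

    components: list[NicheComponent] = []
    skipped = 0
    for root in sorted(comp_nodes):
        nodes = comp_nodes[root]
        simplices = comp_simplices.get(root, [])
        if not simplices:
            skipped += 1
            continue
        edge_count: Counter = Counter()
        tri_area = 0.0
        for s in simplices:
            a, b, c = (int(v) for v in s)
            tri_area += _ring_area(sg.positions[[a, b, c]])
            for e in ((a, b), (b, c), (a, c)):
                edge_count[(min(e), max(e))] += 1
        border = [e for e, cnt in edge_count.items() if cnt == 1]
        rings = _link_rings(border, sg.positions)
        if not rings:
            skipped += 1
            continue
        poly = _assemble_rings([sg.positions[r] for r in rings])
        components.append(NicheComponent(str(labels[nodes[0]]), poly,
                                         len(nodes), tri_area))
    if skipped:
        warnings.warn(f"skipped {skipped} niche component(s) with no triangle")
    return components


def niche_stats(components: list[NicheComponent],
                min_area_fraction: float = MIN_AREA_FRACTION) -> pd.DataFrame:
    """Per-niche geometry table after the relative-area filter.

    For each niche, occurrences smaller than ``min_area_fraction`` of that
    niche's largest component are dropped; the table then reports the
    occurrence count, mean area/perimeter/roundness (net of holes), total
    retained cells, and density = cells / total area.  A niche whose
    components were all filtered out gets a zero row flagged ``empty``.
    """
    niches = sorted({c.niche for c in components})
    rows = []
    for g in niches:
        occ = [c for c in components if c.niche == g]
        largest = max(c.area for c in occ)
        kept = [c for c in occ if c.area >= min_area_fraction * largest]
        if not kept:
            rows.append((g, 0, 0.0, 0.0, 0.0, 0, 0.0, True))
            continue
        total_area = sum(c.area for c in kept)
        total_cells = sum(c.n_cells for c in kept)
        rows.append((g, len(kept),
                     float(np.mean([c.area for c in kept])),
                     float(np.mean([c.perimeter for c in kept])),
                     float(np.mean([c.roundness for c in kept])),
                     total_cells, total_cells / total_area, False))
    return pd.DataFrame(rows, columns=["niche", "occurrences", "mean_area",
                                       "mean_perimeter", "mean_roundness",
                                       "n_cells", "density", "empty"]
                        ).set_index("niche")
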