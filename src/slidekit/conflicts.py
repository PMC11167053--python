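"""Cross-patch conflict resolution by intersection-over-min-area (IOMA).

Because patches overlap, a cell near a patch border can be segmented in
several patches.  For every candidate pair of cells from *different*
patches whose bounding boxes intersect, the IOMA score
``area(a ∩ b) / min(area(a), area(b))`` decides the outcome: pairs scoring
above the merge threshold (default 0.5, i.e. the intersection exceeds half
the smaller cell) are the same cell and are unioned; lower-scoring pairs
are distinct cells and both are kept.  Chains of merges are closed
transitively with a union-find, so the result does not depend on patch
order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.ops import unary_union
from shapely.strtree import STRtree

from .core import CellCollection, ValidationError, repair_polygon

MERGE_THRESHOLD = 0.5      # "intersection exceeds half the area of the smaller cell"
QC_DISTINCT_CUTOFF = 0.07  # below: clearly two distinct, barely-touching cells
QC_DUPLICATE_CUTOFF = 0.8  # above: clearly the same cell segmented twice


def ioma(a, b) -> float:
    """Intersection area over the smaller polygon's area, in [0, 1]."""
    if a.area <= 0 or b.area <= 0:
        raise ValidationError("IOMA requires polygons with positive area")
    inter = a.intersection(b).area
    return min(inter / min(a.area, b.area), 1.0)


def classify_conflict(score: float) -> str:
    """QC class of a conflict score: clearly-distinct and clearly-duplicate
    scores indicate the resolution is unambiguous; in-between is ambiguous."""
    if not (0.0 <= score <= 1.0):
        raise ValidationError(f"IOMA score out of range: {score}")
    if score < QC_DISTINCT_CUTOFF:
        return "good_distinct"
    if score > QC_DUPLICATE_CUTOFF:
        return "good_duplicate"
    return "ambiguous"


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


@dataclass
class ResolutionResult:
    cells: CellCollection
    conflicts: pd.DataFrame  # columns: a, b, ioma, decision, qc_class


def find_conflicts(per_patch: list[CellCollection],
                   merge_threshold: float = MERGE_THRESHOLD,
                   ) -> tuple[list, list[frozenset[int]], pd.DataFrame]:
    """Pool per-patch cells and score every cross-patch candidate pair.

    Returns (pooled polygons, pooled provenance, conflict table indexed by
    pooled position).
    """
    polys, prov = [], []
    for coll in per_patch:
        for poly, pv in zip(coll.polygons, coll.provenance):
            polys.append(poly)
            prov.append(pv)
    rows = []
    if polys:
        tree = STRtree(polys)
        pairs = tree.query(polys, predicate="intersects")
        for i, j in pairs.T:
            if i >= j:
                continue
            if prov[i] and prov[i] == prov[j]:
                continue  # same-patch instances are trusted
            score = ioma(polys[i], polys[j])
            rows.append((int(i), int(j), score,
                         "merge" if score > merge_threshold else "keep",
                         classify_conflict(score)))
    table = pd.DataFrame(rows, columns=["a", "b", "ioma", "decision", "qc_class"])
    return polys, prov, table


def resolve_conflicts(per_patch: list[CellCollection],
                      merge_threshold: float = MERGE_THRESHOLD,
                      ) -> ResolutionResult:
    """Merge per-patch segmentations into one non-redundant cell set.

    Candidate pairs come from a spatial index over bounding boxes; pairs
    with IOMA above the threshold are joined in a union-find and each group
    is replaced by the geometric union of its members (repaired; largest
    part if multi-part).  Output ids are assigned by position, provenance is
    the union of the sources' patches.
    """
    polys, prov, table = find_conflicts(per_patch, merge_threshold)
    if not polys:
        return ResolutionResult(CellCollection(np.empty(0, np.int64), []), table)
    uf = _UnionFind(len(polys))
    for _, row in table.iterrows():
        if row["decision"] == "merge":
            uf.union(int(row["a"]), int(row["b"]))
    groups: dict[int, list[int]] = {}
    for i in range(len(polys)):
        groups.setdefault(uf.find(i), []).append(i)
    out_polys, out_prov = [], []
    for root in sorted(groups):
        members = groups[root]
        if len(members) == 1:
            merged = polys[members[0]]
        else:
            merged = repair_polygon(unary_union([polys[m] for m in members]))
        out_polys.append(merged)
        out_prov.append(frozenset().union(*(prov[m] for m in members)))
    cells = CellCollection(np.arange(len(out_polys), dtype=np.int64),
                           out_polys, out_prov)
    return ResolutionResult(cells, table)


def max_cross_patch_ioma(cells: CellCollection) -> float:
    """Largest IOMA among remaining pairs with different provenance; 0 if none.

    After resolution this must not exceed the merge threshold.
    """
    best = 0.0
    if len(cells) < 2:
        return best
    tree = STRtree(cells.polygons)
    pairs = tree.query(cells.polygons, predicate="intersects")
    for i, j in pairs.T:
        if i >= j:
            continue
        if cells.provenance[i] and cells.provenance[i] == cells.provenance[j]:
            continue
        best = max(best, ioma(cells.polygons[i], cells.polygons[j]))
    return best
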