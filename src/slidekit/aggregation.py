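"""Per-cell aggregation: chunked channel averaging and partitioned transcript counting.

Channel averaging never rasterizes full-image cell masks.  The image is
visited chunk by chunk: for each chunk we find the cell polygons whose
bounds intersect it, restrict each cell to its bounding box clipped to the
chunk window, read only that sub-array, rasterize the polygon over the
pixel centers and accumulate per-cell (sum, count) pairs.  A cell spanning
several chunks accumulates each pixel exactly once because windows never
overlap.

Transcript counting joins points against polygons at the level of spatial
partitions (default 100 µm squares) so each join touches a bounded number
of rows; the result is exactly the global point-in-polygon join.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import sparse
from shapely.geometry import box
from shapely.strtree import STRtree

from .core import (CellCollection, ChannelMatrix, CountsMatrix, RasterImage,
                   TranscriptTable, ValidationError, raster_membership)

DEFAULT_PARTITION_SIZE = 100.0  # µm; keeps each partition-level join small


def average_channels(image: RasterImage, cells: CellCollection) -> ChannelMatrix:
    """Mean intensity of every image channel over each cell's covered pixels.

    Pixels are counted by the pixel-center membership rule; cells partially
    outside the image are implicitly clipped to the extent.  Cells covering
    no pixel center get mean 0 and a warning.
    """
    n_cells = len(cells)
    n_ch = image.n_channels
    sums = np.zeros((n_cells, n_ch))
    counts = np.zeros(n_cells)
    if n_cells:
        tree = STRtree(cells.polygons)
        ps = image.pixel_size
        for r0, r1, c0, c1 in image.iter_chunks():
            chunk_box = box(c0 * ps, r0 * ps, c1 * ps, r1 * ps)
            hits = tree.query(chunk_box, predicate="intersects")
            if len(hits) == 0:
                continue
            window = image.read_window(r0, r1, c0, c1)
            for ci in sorted(hits):
                poly = cells.polygons[ci]
                xmin, ymin, xmax, ymax = poly.bounds
                pr0 = max(int(np.floor(ymin / ps)), r0)
                pc0 = max(int(np.floor(xmin / ps)), c0)
                pr1 = min(int(np.ceil(ymax / ps)) + 1, r1)
                pc1 = min(int(np.ceil(xmax / ps)) + 1, c1)
                if pr1 <= pr0 or pc1 <= pc0:
                    continue
                mask = raster_membership(poly, pr0, pr1, pc0, pc1, ps)
                if not mask.any():
                    continue
                sub = window[:, pr0 - r0:pr1 - r0, pc0 - c0:pc1 - c0]
                sums[ci] += sub[:, mask].astype(np.float64).sum(axis=1)
                counts[ci] += mask.sum()
    empty = counts == 0
    if empty.any():
        warnings.warn(f"{int(empty.sum())} cell(s) cover no pixel center; mean set to 0")
    means = np.divide(sums, counts[:, None], out=np.zeros_like(sums),
                      where=counts[:, None] > 0)
    return ChannelMatrix(means, list(image.channel_names), cells.cell_ids)


def average_channels_naive(image: RasterImage, cells: CellCollection) -> ChannelMatrix:
    """Reference implementation: whole-image, per-cell bounding-box
    rasterization without chunking.  Used as an oracle in tests."""
    _, h, w = image.shape
    ps = image.pixel_size
    data = image.read_window(0, h, 0, w)
    X = np.zeros((len(cells), image.n_channels))
    for i, poly in enumerate(cells.polygons):
        xmin, ymin, xmax, ymax = poly.bounds
        r0 = max(int(np.floor(ymin / ps)), 0)
        c0 = max(int(np.floor(xmin / ps)), 0)
        r1 = min(int(np.ceil(ymax / ps)) + 1, h)
        c1 = min(int(np.ceil(xmax / ps)) + 1, w)
        if r1 <= r0 or c1 <= c0:
            continue
        mask = raster_membership(poly, r0, r1, c0, c1, ps)
        if mask.any():
            X[i] = data[:, r0:r1, c0:c1][:, mask].astype(np.float64).mean(axis=1)
    return ChannelMatrix(X, list(image.channel_names), cells.cell_ids)


def _assign_points(t: TranscriptTable, cells: CellCollection,
                   partition_size: float | None) -> np.ndarray:
    """Per-transcript index of the owning cell (position in `cells`), -1 if none.

    A point covered by several cells (shared borders) goes to the cell with
    the smallest id — a deterministic tie rule.
    """
    n = len(t)
    owner = np.full(n, -1, dtype=np.int64)
    if n == 0 or len(cells) == 0:
        return owner
    tree = STRtree(cells.polygons)
    order = np.argsort(cells.cell_ids, kind="stable")  # tie rule: smallest cell id
    rank = np.empty(len(cells), dtype=np.int64)
    rank[order] = np.arange(len(cells))
    x, y = t.x, t.y
    if partition_size is None or partition_size <= 0:
        part_ids = np.zeros(n, dtype=np.int64)
    else:
        px = np.floor((x - x.min()) / partition_size).astype(np.int64)
        py = np.floor((y - y.min()) / partition_size).astype(np.int64)
        part_ids = px * (py.max() + 1) + py
    import shapely

    for part in np.unique(part_ids):
        idx = np.nonzero(part_ids == part)[0]
        pts = shapely.points(x[idx], y[idx])
        hits = tree.query(pts, predicate="covered_by")  # (point_pos, cell_pos)
        if hits.size == 0:
            continue
        pt_pos, cell_pos = hits
        # keep, per point, the covering cell with the smallest id
        best_rank = np.full(len(idx), np.iinfo(np.int64).max)
        np.minimum.at(best_rank, pt_pos, rank[cell_pos])
        matched = best_rank < np.iinfo(np.int64).max
        owner[idx[matched]] = order[best_rank[matched]]
    return owner


def count_transcripts(t: TranscriptTable, cells: CellCollection,
                      partition_size: float | None = DEFAULT_PARTITION_SIZE,
                      ) -> tuple[CountsMatrix, int]:
    """Count transcripts of each gene inside each cell.

    Returns (counts, n_unassigned); the matrix total plus the unassigned
    count always equals the number of transcripts, for every partition size.
    """
    codes = t.gene_codes
    if len(t) and codes.min() < 0:
        raise ValidationError("transcript table contains gene labels outside vocabulary")
    owner = _assign_points(t, cells, partition_size)
    genes = t.genes
    assigned = owner >= 0
    mat = sparse.coo_matrix(
        (np.ones(int(assigned.sum()), dtype=np.int64),
         (owner[assigned], codes[assigned])),
        shape=(len(cells), len(genes))).tocsr()
    counts = CountsMatrix(mat, genes, cells.cell_ids)
    return counts, int((~assigned).sum())


def count_transcripts_bruteforce(t: TranscriptTable, cells: CellCollection,
                                 ) -> tuple[CountsMatrix, int]:
    """Oracle: direct loop over all (point, cell) pairs with the same tie rule."""
    import shapely

    genes = t.genes
    mat = np.zeros((len(cells), len(genes)), dtype=np.int64)
    unassigned = 0
    codes = t.gene_codes
    for k in range(len(t)):
        pt = shapely.Point(t.x[k], t.y[k])
        covering = [i for i, poly in enumerate(cells.polygons) if poly.covers(pt)]
        if covering:
            winner = min(covering, key=lambda i: cells.cell_ids[i])
            mat[winner, codes[k]] += 1
        else:
            unassigned += 1
    return CountsMatrix(sparse.csr_matrix(mat), genes, cells.cell_ids), unassigned
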