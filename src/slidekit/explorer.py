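"""Open visualizer bundle: tiled image pyramid, pyramidal subsampled
transcripts, fixed-width cell boundaries, sparse tables and metadata.

The bundle re-implements, on open Zarr containers, the file scheme used by
pyramidal slide viewers: images are stored per level with 1024x1024 px
tiles, each level a 2x2 mean-downsample of the previous until both
dimensions fit one tile; transcripts are binned into 250 µm tiles at full
resolution, with tile width doubling and three of every four points dropped
per level until a single tile covers the slide; cell boundaries are stored
as an N x 13 x 2 array of padded/simplified rings; count and category
tables use a compressed sparse (data / index / pointer) layout.  Level-0
image, level-0 transcripts and the tables round-trip losslessly.
"""

from __future__ import annotations

import json
import math
import warnings
from pathlib import Path

import numpy as np
import zarr
from shapely.geometry import Polygon

from .core import (CellCollection, CountsMatrix, RasterImage, TranscriptTable,
                   ValidationError)

TILE_PX = 1024           # image tile side, pixels
BASE_TILE_UM = 250.0     # level-0 transcript tile side, µm
N_VERTICES = 13          # fixed boundary vertex count
SIMPLIFY_TOL0 = 0.1      # µm, initial simplification tolerance
SIMPLIFY_MAX_ATTEMPTS = 20
SCHEMA_VERSION = 1


def block_mean_2x2(arr: np.ndarray) -> np.ndarray:
    """2x2 block mean of a (C, H, W) array; odd edges average the available
    pixels, so output dims are ceil(H/2) x ceil(W/2)."""
    c, h, w = arr.shape
    rows = np.arange(0, h, 2)
    cols = np.arange(0, w, 2)
    summed = np.add.reduceat(np.add.reduceat(arr.astype(np.float64), rows, axis=1),
                             cols, axis=2)
    nr = np.minimum(rows + 2, h) - rows
    nc = np.minimum(cols + 2, w) - cols
    return (summed / np.outer(nr, nc)[None]).astype(np.float32)


def pyramid_level_shapes(h: int, w: int, tile_px: int = TILE_PX,
                         ) -> list[tuple[int, int]]:
    """Level (H, W) schedule: halve (ceil) until both dims fit one tile."""
    shapes = [(h, w)]
    while shapes[-1][0] > tile_px or shapes[-1][1] > tile_px:
        ph, pw = shapes[-1]
        shapes.append((math.ceil(ph / 2), math.ceil(pw / 2)))
    return shapes


def export_image_pyramid(image: RasterImage, bundle: str | Path) -> int:
    """Write the tiled image pyramid to ``<bundle>/images.zarr``; returns the
    number of levels.

    Each level-0 tile is produced from only the source blocks it overlaps;
    higher levels are computed tile by tile from the previous level, so the
    working set per tile never exceeds the source pixels it covers.
    """
    c, h, w = image.shape
    shapes = pyramid_level_shapes(h, w)
    root = zarr.open_group(str(Path(bundle) / "images.zarr"), mode="w")
    root.attrs["channel_names"] = list(image.channel_names)
    root.attrs["pixel_size"] = image.pixel_size
    prev = None
    for level, (lh, lw) in enumerate(shapes):
        arr = root.create_array(str(level), shape=(c, lh, lw), dtype="float32",
                                chunks=(1, TILE_PX, TILE_PX))
        for r0 in range(0, lh, TILE_PX):
            for c0 in range(0, lw, TILE_PX):
                r1, c1 = min(r0 + TILE_PX, lh), min(c0 + TILE_PX, lw)
                if level == 0:
                    tile = image.read_window(r0, r1, c0, c1).astype(np.float32)
                else:
                    src = np.asarray(prev[:, 2 * r0:min(2 * r1, shapes[level - 1][0]),
                                          2 * c0:min(2 * c1, shapes[level - 1][1])])
                    tile = block_mean_2x2(src)
                arr[:, r0:r1, c0:c1] = tile
        prev = arr
    return len(shapes)


def transcript_level_schedule(extent: tuple[float, float],
                              base_tile_um: float = BASE_TILE_UM) -> list[float]:
    """Tile widths per level: doubling from the base width; the last level is
    the first whose single tile covers the whole extent."""
    widths = [base_tile_um]
    while widths[-1] < max(extent):
        widths.append(widths[-1] * 2)
    return widths


def export_transcript_pyramid(t: TranscriptTable, bundle: str | Path,
                              extent: tuple[float, float]) -> int:
    """Write the transcript pyramid to ``<bundle>/transcripts.zarr``.

    Level 0 holds all transcripts binned into 250 µm tiles (x, y,
    gene_index and original row id stored per tile); every further level
    keeps each 4th transcript of the previous one (stride 4, offset 0, in
    stable input order).  Returns the number of levels.
    """
    root = zarr.open_group(str(Path(bundle) / "transcripts.zarr"), mode="w")
    widths = transcript_level_schedule(extent)
    root.attrs["base_tile_um"] = BASE_TILE_UM
    root.attrs["extent"] = list(extent)
    root.attrs["gene_vocabulary"] = t.genes
    keep = np.arange(len(t))
    for level, width in enumerate(widths):
        grp = root.create_group(f"level_{level}")
        grp.attrs["tile_width_um"] = width
        nx = max(math.ceil(extent[0] / width), 1)
        ny = max(math.ceil(extent[1] / width), 1)
        grp.attrs["grid"] = [ny, nx]
        x, y = t.x[keep], t.y[keep]
        codes = t.gene_codes[keep]
        tx = np.minimum(np.floor(x / width).astype(int), nx - 1) if len(x) else np.empty(0, int)
        ty = np.minimum(np.floor(y / width).astype(int), ny - 1) if len(y) else np.empty(0, int)
        for i in range(ny):
            for j in range(nx):
                sel = (ty == i) & (tx == j)
                tile = grp.create_group(f"tile_{i}_{j}")
                for name, values, dt in (("x", x[sel], "float64"),
                                         ("y", y[sel], "float64"),
                                         ("gene_index", codes[sel], "int32"),
                                         ("id", keep[sel], "int64")):
                    arr = tile.create_array(name, shape=(int(sel.sum()),), dtype=dt)
                    if len(values):
                        arr[:] = values.astype(dt)
        keep = keep[::4]
    root.attrs["n_levels"] = len(widths)
    return len(widths)


def pad_boundary(polygon: Polygon, n_vertices: int = N_VERTICES) -> np.ndarray:
    """Fixed-width (n_vertices, 2) ring for one cell boundary.

    Polygons with more vertices are simplified with a geometrically
    increasing tolerance until they fit; padding repeats the last vertex.
    The closing duplicate is dropped — the ring is implicitly closed.
    """
    coords = np.asarray(polygon.exterior.coords)[:-1]
    if len(coords) > n_vertices:
        tol = SIMPLIFY_TOL0
        simplified = polygon
        for _ in range(SIMPLIFY_MAX_ATTEMPTS):
            simplified = polygon.simplify(tol, preserve_topology=True)
            if len(simplified.exterior.coords) - 1 <= n_vertices:
                break
            tol *= 2
        coords = np.asarray(simplified.exterior.coords)[:-1]
        if len(coords) > n_vertices:
            warnings.warn("simplification failed; subsampling boundary vertices")
            step = math.ceil(len(coords) / n_vertices)
            coords = coords[::step]
    pad = np.repeat(coords[-1:], n_vertices - len(coords), axis=0)
    return np.vstack([coords, pad])


def export_boundaries(cells: CellCollection, bundle: str | Path) -> np.ndarray:
    """Write the N x 13 x 2 boundary array to ``<bundle>/cells.zarr``."""
    boundaries = (np.stack([pad_boundary(p) for p in cells.polygons])
                  if len(cells) else np.empty((0, N_VERTICES, 2)))
    root = zarr.open_group(str(Path(bundle) / "cells.zarr"), mode="w")
    arr = root.create_array("boundaries", shape=boundaries.shape
                            if len(cells) else (0, N_VERTICES, 2), dtype="float64")
    if len(cells):
        arr[:] = boundaries
    ids = root.create_array("cell_ids", shape=(len(cells),), dtype="int64")
    if len(cells):
        ids[:] = cells.cell_ids
    return boundaries


def export_tables(counts: CountsMatrix | None, categories: dict[str, list] | None,
                  bundle: str | Path, n_cells: int | None = None) -> None:
    """Write sparse count and category stores to ``<bundle>/tables.zarr``.

    Counts use a gene-major compressed layout: ``data`` (non-zero counts),
    ``cell_index`` (ascending within a gene) and ``gene_pointer`` of length
    G+1.  Each category field stores sorted unique ``values`` plus cell
    positions grouped by label (``indices``) and ``pointers`` of length K+1.
    """
    root = zarr.open_group(str(Path(bundle) / "tables.zarr"), mode="w")
    if counts is not None:
        csc = counts.matrix.tocsc()
        csc.sort_indices()
        grp = root.create_group("counts")
        grp.attrs["genes"] = counts.genes
        grp.attrs["n_cells"] = len(counts.cell_ids)
        for name, values, dt in (("data", csc.data, "int64"),
                                 ("cell_index", csc.indices, "int64"),
                                 ("gene_pointer", csc.indptr, "int64")):
            arr = grp.create_array(name, shape=(len(values),), dtype=dt)
            if len(values):
                arr[:] = np.asarray(values, dtype=np.int64)
        n_cells = len(counts.cell_ids)
    if categories:
        cat_root = root.create_group("categories")
        for field_name, labels in categories.items():
            labels = list(labels)
            if n_cells is not None and len(labels) != n_cells:
                raise ValidationError(
                    f"category field {field_name!r} labels {len(labels)} cells, "
                    f"expected {n_cells}")
            if any(lab is None or (isinstance(lab, float) and np.isnan(lab))
                   for lab in labels):
                raise ValidationError(f"category field {field_name!r} has unlabeled cells")
            values = sorted(set(labels))
            grp = cat_root.create_group(field_name)
            grp.attrs["values"] = values
            indices = np.concatenate([
                np.nonzero(np.asarray(labels, object) == v)[0] for v in values]
            ) if labels else np.empty(0, int)
            pointers = np.cumsum([0] + [labels.count(v) for v in values])
            a = grp.create_array("indices", shape=(len(indices),), dtype="int64")
            if len(indices):
                a[:] = indices
            p = grp.create_array("pointers", shape=(len(pointers),), dtype="int64")
            p[:] = pointers


def read_counts_dense(bundle: str | Path) -> np.ndarray:
    """Densify the sparse count store back into an (N, G) array."""
    grp = zarr.open_group(str(Path(bundle) / "tables.zarr"), mode="r")["counts"]
    genes = grp.attrs["genes"]
    n_cells = grp.attrs["n_cells"]
    data = np.asarray(grp["data"])
    cell_index = np.asarray(grp["cell_index"])
    pointer = np.asarray(grp["gene_pointer"])
    dense = np.zeros((n_cells, len(genes)), dtype=np.int64)
    for g in range(len(genes)):
        sl = slice(pointer[g], pointer[g + 1])
        dense[cell_index[sl], g] = data[sl]
    return dense


def write_bundle(bundle: str | Path, image: RasterImage | None = None,
                 transcripts: TranscriptTable | None = None,
                 cells: CellCollection | None = None,
                 counts: CountsMatrix | None = None,
                 categories: dict[str, list] | None = None,
                 name: str = "slidekit-export") -> dict:
    """Assemble the full bundle; returns the metadata written to
    experiment.json.

    At least an image or a cell set must be present; the transcript part is
    omitted for imaging-only datasets.
    """
    if image is None and cells is None:
        raise ValidationError("nothing to export: need an image or a cell set")
    bundle = Path(bundle)
    bundle.mkdir(parents=True, exist_ok=True)
    meta: dict = {"schema_version": SCHEMA_VERSION, "name": name,
                  "parts": {"images": image is not None,
                            "transcripts": transcripts is not None,
                            "cells": cells is not None,
                            "tables": counts is not None or bool(categories)}}
    if image is not None:
        meta["pixel_size"] = image.pixel_size
        meta["extent"] = list(image.extent)
        meta["image_levels"] = export_image_pyramid(image, bundle)
        meta["channel_names"] = list(image.channel_names)
    if transcripts is not None:
        if image is not None:
            ext = (image.extent[2], image.extent[3])
        else:
            ext = (float(transcripts.x.max(initial=BASE_TILE_UM)),
                   float(transcripts.y.max(initial=BASE_TILE_UM)))
        meta["transcript_levels"] = export_transcript_pyramid(transcripts, bundle, ext)
        meta["n_transcripts"] = len(transcripts)
    if cells is not None:
        export_boundaries(cells, bundle)
        meta["n_cells"] = len(cells)
    if counts is not None or categories:
        export_tables(counts, categories, bundle,
                      n_cells=len(cells) if cells is not None else None)
        if counts is not None:
            meta["n_genes"] = len(counts.genes)
    (bundle / "experiment.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
    return meta
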