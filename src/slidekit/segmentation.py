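"""Per-patch segmentation: pluggable contract plus a built-in intensity segmenter.

A segmenter is any callable ``(patch_image, transcripts_subset, params) ->
LabelMask | list[Polygon]``: *patch_image* is the (C, h, w) window of the
staining image, *transcripts_subset* the transcripts falling in the patch
(or None), and the return value either an integer label mask over the
window (0 = background) or polygons already in world µm, confined to the
window.  External tools (Cellpose-style image segmenters, transcript-based
segmenters) plug in through this contract; the built-in segmenter keeps the
pipeline testable without them.

Label masks are polygonized along outer pixel edges, so a label of n pixels
maps to a polygon of area exactly ``n * pixel_size**2``.
"""

from __future__ import annotations

from typing import Callable, Protocol

import numpy as np
import shapely
from scipy import ndimage as ndi
from shapely.geometry import Polygon, box
from shapely.ops import unary_union

from .core import CellCollection, RasterImage, TranscriptTable, repair_polygon
from .patching import PatchGrid

SegmenterContract = Callable[[np.ndarray, "TranscriptTable | None", dict],
                             "np.ndarray | list[Polygon]"]


def builtin_segment_patch(patch_image: np.ndarray, params: dict | None = None,
                          ) -> np.ndarray:
    """Threshold-based instance segmentation of one patch window.

    Gaussian smooth -> threshold (fixed value or Otsu) -> 4-connected
    components -> drop components below ``min_area_px``; with
    ``split_touching`` a distance-transform watershed separates merged
    blobs.  Deterministic for fixed input.

    params: ``channel`` (int, default 0), ``sigma`` (px, default 1.0),
    ``threshold`` (float or "otsu"), ``min_area_px`` (default 20),
    ``split_touching`` (bool, default False), ``min_distance_px``
    (watershed seed separation, default 5).
    """
    from skimage.feature import peak_local_max
    from skimage.filters import gaussian, threshold_otsu
    from skimage.measure import label as cc_label
    from skimage.segmentation import watershed

    params = dict(params or {})
    channel = int(params.get("channel", 0))
    sigma = float(params.get("sigma", 1.0))
    threshold = params.get("threshold", "otsu")
    min_area_px = int(params.get("min_area_px", 20))
    img = np.asarray(patch_image[channel], dtype=float)
    if img.size == 0 or not np.any(img):
        return np.zeros(img.shape, dtype=np.int32)
    smooth = gaussian(img, sigma=sigma, preserve_range=True) if sigma > 0 else img
    if threshold == "otsu":
        if smooth.max() == smooth.min():
            return np.zeros(img.shape, dtype=np.int32)
        threshold = threshold_otsu(smooth)
    binary = smooth > float(threshold)
    if not binary.any():
        return np.zeros(img.shape, dtype=np.int32)

    if params.get("split_touching", False):
        distance = ndi.distance_transform_edt(binary)
        min_distance = int(params.get("min_distance_px", 5))
        peaks = peak_local_max(distance, min_distance=min_distance, labels=binary,
                               exclude_border=False)
        markers = np.zeros(binary.shape, dtype=np.int32)
        markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
        labels = watershed(-distance, markers, mask=binary, connectivity=1)
    else:
        labels = cc_label(binary, connectivity=1)
    if min_area_px > 1 and labels.max() > 0:
        sizes = np.bincount(labels.ravel())
        small = np.nonzero(sizes < min_area_px)[0]
        labels[np.isin(labels, small[small > 0])] = 0
    # relabel to a contiguous 1..K range for stable downstream ids
    out = np.zeros_like(labels, dtype=np.int32)
    for new, old in enumerate(np.unique(labels[labels > 0]), start=1):
        out[labels == old] = new
    return out


def mask_to_polygons(mask: np.ndarray, window_origin: tuple[float, float] = (0.0, 0.0),
                     pixel_size: float = 1.0) -> CellCollection:
    """Trace each label of a mask into a world-µm polygon.

    The boundary follows outer pixel edges (union of unit pixel squares), so
    the polygon area equals the label's pixel count times ``pixel_size**2``
    exactly.  Holes inside a label are filled; invalid traces are repaired,
    keeping the largest part.
    """
    mask = np.asarray(mask)
    ox, oy = window_origin
    polygons = []
    for lab in np.unique(mask[mask > 0]):
        rows, cols = np.nonzero(mask == lab)
        squares = [box(c, r, c + 1, r + 1) for r, c in zip(rows, cols)]
        merged = unary_union(squares)
        if merged.geom_type != "Polygon":
            merged = max(merged.geoms, key=lambda g: g.area)
        poly = Polygon(merged.exterior).simplify(0)  # fill holes, drop collinear pts
        poly = repair_polygon(poly)
        poly = shapely.transform(
            poly, lambda pts: pts * pixel_size + np.array([ox, oy]))
        polygons.append(poly)
    return CellCollection.from_polygons(polygons)


def patch_pixel_window(patch: tuple[float, float, float, float], pixel_size: float,
                       image_shape: tuple[int, int, int]) -> tuple[int, int, int, int]:
    """(row0, row1, col0, col1) pixel window covering a world-µm patch rectangle."""
    xmin, ymin, xmax, ymax = patch
    _, h, w = image_shape
    r0 = max(int(np.floor(ymin / pixel_size)), 0)
    c0 = max(int(np.floor(xmin / pixel_size)), 0)
    r1 = min(int(np.ceil(ymax / pixel_size)), h)
    c1 = min(int(np.ceil(xmax / pixel_size)), w)
    return r0, r1, c0, c1


def run_segmentation(image: RasterImage, grid: PatchGrid,
                     segmenter: SegmenterContract | None = None,
                     params: dict | None = None,
                     transcripts: TranscriptTable | None = None,
                     patch_indices: list[int] | None = None,
                     ) -> list[CellCollection]:
    """Run a segmenter independently on every patch of the grid.

    Returns one CellCollection per requested patch, each polygon tagged with
    its patch index via provenance.  Patch results are order-independent;
    a segmenter exception is re-raised with the patch index in its message.
    """
    if segmenter is None:
        segmenter = lambda img, tx, p: builtin_segment_patch(img, p)  # noqa: E731
    indices = list(range(len(grid))) if patch_indices is None else list(patch_indices)
    results = []
    for idx in indices:
        patch = grid.patches[idx]
        r0, r1, c0, c1 = patch_pixel_window(patch, image.pixel_size, image.shape)
        window = image.read_window(r0, r1, c0, c1)
        subset = None
        if transcripts is not None and len(transcripts):
            keep = grid.contains(idx, transcripts.x, transcripts.y)
            subset = TranscriptTable(transcripts.df.loc[keep].reset_index(drop=True))
        try:
            out = segmenter(window, subset, dict(params or {}))
        except Exception as exc:  # pragma: no cover - error path
            raise RuntimeError(f"segmenter failed on patch {idx}: {exc}") from exc
        if isinstance(out, np.ndarray):
            cells = mask_to_polygons(
                out, (c0 * image.pixel_size, r0 * image.pixel_size), image.pixel_size)
        else:
            cells = CellCollection.from_polygons(list(out))
        cells.provenance = [frozenset({idx}) for _ in cells.polygons]
        results.append(cells)
    return results
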