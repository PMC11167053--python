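"""Overlapping patch grids over the slide extent.

Segmentation runs per patch; the overlap is chosen at least twice the
average cell diameter so every cell is complete in at least one patch.
Patch rectangles are closed on their min edges and open on their max edges,
except the last patch per axis which is closed, so a point in an overlap
zone is deterministically assigned to every patch containing it while the
grid still covers the extent exactly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .core import TranscriptTable, ValidationError

DEFAULT_PATCH_WIDTH = 200.0  # µm
DEFAULT_OVERLAP = 40.0       # µm, twice a typical 20 µm cell diameter


def _axis_starts(length: float, patch_width: float, overlap: float) -> list[float]:
    if length <= patch_width:
        return [0.0]
    step = patch_width - overlap
    n = math.ceil((length - patch_width) / step) + 1
    return [k * step for k in range(n)]


@dataclass
class PatchGrid:
    """Ordered axis-aligned patch rectangles (xmin, ymin, xmax, ymax), world µm."""

    extent: tuple[float, float, float, float]
    patch_width: float
    overlap: float
    patches: list[tuple[float, float, float, float]]
    shape: tuple[int, int]  # (n_rows, n_cols)

    def __len__(self) -> int:
        return len(self.patches)

    def contains(self, patch_index: int, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Membership of points in one patch under the half-open convention."""
        xmin, ymin, xmax, ymax = self.patches[patch_index]
        ex_xmax, ex_ymax = self.extent[2], self.extent[3]
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        in_x = (x >= xmin) & ((x <= xmax) if xmax >= ex_xmax else (x < xmax))
        in_y = (y >= ymin) & ((y <= ymax) if ymax >= ex_ymax else (y < ymax))
        return in_x & in_y

    def to_geojson(self, path: str | Path) -> None:
        features = [{"type": "Feature",
                     "geometry": {"type": "Polygon",
                                  "coordinates": [[(xmin, ymin), (xmax, ymin),
                                                   (xmax, ymax), (xmin, ymax),
                                                   (xmin, ymin)]]},
                     "properties": {"patch_index": i}}
                    for i, (xmin, ymin, xmax, ymax) in enumerate(self.patches)]
        Path(path).write_text(json.dumps(
            {"type": "FeatureCollection", "features": features,
             "patch_width": self.patch_width, "overlap": self.overlap,
             "extent": list(self.extent), "shape": list(self.shape)}))

    @classmethod
    def from_geojson(cls, path: str | Path) -> "PatchGrid":
        doc = json.loads(Path(path).read_text())
        patches = []
        for feat in doc["features"]:
            ring = np.asarray(feat["geometry"]["coordinates"][0])
            patches.append((ring[:, 0].min(), ring[:, 1].min(),
                            ring[:, 0].max(), ring[:, 1].max()))
        return cls(tuple(doc["extent"]), doc["patch_width"], doc["overlap"],
                   patches, tuple(doc["shape"]))


def make_patches(extent: tuple[float, float, float, float],
                 patch_width: float = DEFAULT_PATCH_WIDTH,
                 overlap: float = DEFAULT_OVERLAP) -> PatchGrid:
    """Build the overlapping patch grid over a world extent.

    Per axis, patch k starts at ``k * (patch_width - overlap)``; the last
    patch is clamped to end at the extent boundary.  Row-major ordering.
    """
    xmin, ymin, xmax, ymax = extent
    if not (patch_width > overlap >= 0):
        raise ValidationError(
            f"need patch_width > overlap >= 0, got {patch_width}, {overlap}")
    if xmax <= xmin or ymax <= ymin:
        raise ValidationError("extent is degenerate")
    xs = _axis_starts(xmax - xmin, patch_width, overlap)
    ys = _axis_starts(ymax - ymin, patch_width, overlap)
    patches = []
    for y0 in ys:
        for x0 in xs:
            patches.append((xmin + x0, ymin + y0,
                            min(xmin + x0 + patch_width, xmax),
                            min(ymin + y0 + patch_width, ymax)))
    return PatchGrid(tuple(extent), patch_width, overlap, patches,
                     (len(ys), len(xs)))


def assign_transcripts(t: TranscriptTable, grid: PatchGrid) -> list[np.ndarray]:
    """Per-patch arrays of transcript row indices.

    A transcript appears in every patch whose rectangle contains it, so
    points in overlap zones are duplicated across patches; the union of all
    lists covers the whole table.
    """
    x, y = t.x, t.y
    return [np.nonzero(grid.contains(i, x, y))[0] for i in range(len(grid))]
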