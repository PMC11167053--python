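"""Shared data model for image-based spatial omics.

All spatial quantities live in a single world coordinate frame measured in
micrometres (µm): the origin is the image's top-left corner, x increases
rightward (columns) and y increases downward (rows).  A pixel with array
index ``(row, col)`` occupies the world square
``[col*pixel_size, (col+1)*pixel_size) x [row*pixel_size, (row+1)*pixel_size)``
and its center sits at ``((col+0.5)*pixel_size, (row+0.5)*pixel_size)``.

A pixel belongs to a polygon iff its center point is covered, with a
half-open convention (boundary on the left/top counts) so rasterization is
deterministic even when polygon edges pass exactly through pixel centers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
import shapely
from scipy import sparse
from shapely.geometry import Polygon
from shapely.geometry.base import BaseGeometry


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


# fraction of a pixel used to nudge center points when testing membership;
# implements the half-open (closed on left/top) boundary convention
MEMBERSHIP_NUDGE = 1e-6


def pixel_centers(row0: int, row1: int, col0: int, col1: int, pixel_size: float,
                  ) -> tuple[np.ndarray, np.ndarray]:
    """World coordinates of the pixel centers of a window, as (xs, ys) 1-D arrays."""
    xs = (np.arange(col0, col1) + 0.5) * pixel_size
    ys = (np.arange(row0, row1) + 0.5) * pixel_size
    return xs, ys


def raster_membership(polygon: BaseGeometry, row0: int, row1: int, col0: int,
                      col1: int, pixel_size: float) -> np.ndarray:
    """Boolean mask of shape (row1-row0, col1-col0): which pixel centers the
    polygon covers under the half-open convention."""
    xs, ys = pixel_centers(row0, row1, col0, col1, pixel_size)
    eps = MEMBERSHIP_NUDGE * pixel_size
    xg, yg = np.meshgrid(xs + eps, ys + eps)
    return shapely.contains_xy(polygon, xg, yg)


def repair_polygon(geom: BaseGeometry) -> Polygon:
    """Make a polygon valid; multi-part results keep the largest part.

    Noisy masks occasionally trace self-intersecting rings; a zero-width
    buffer resolves them.
    """
    if geom.is_valid and geom.geom_type == "Polygon":
        return geom
    fixed = geom.buffer(0)
    if fixed.geom_type == "Polygon":
        return fixed
    parts = [g for g in getattr(fixed, "geoms", [fixed]) if g.geom_type == "Polygon"]
    if not parts:
        raise ValidationError(f"cannot repair geometry of type {geom.geom_type}")
    return max(parts, key=lambda g: g.area)


@dataclass
class RasterImage:
    """Chunked multi-channel image with a physical pixel scale.

    Parameters
    ----------
    data
        Array-like of shape (C, H, W) supporting numpy basic slicing; numpy
        arrays and zarr arrays both qualify.  Blocks are only materialised
        when a window is read.
    channel_names
        One name per channel.
    pixel_size
        Micrometres per pixel, > 0.
    chunk_shape
        (rows, cols) of the processing block grid.
    """

    data: np.ndarray
    channel_names: list[str]
    pixel_size: float
    chunk_shape: tuple[int, int] = (1024, 1024)

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValidationError("image data must be (channels, height, width)")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValidationError(
                f"{len(self.channel_names)} channel names for {self.data.shape[0]} channels")
        if not np.isfinite(self.pixel_size) or self.pixel_size <= 0:
            raise ValidationError(f"pixel_size must be finite and > 0, got {self.pixel_size}")
        if min(self.data.shape) < 1 or min(self.chunk_shape) < 1:
            raise ValidationError("all dimensions and block sizes must be >= 1")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape)

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the image in world µm."""
        _, h, w = self.data.shape
        return (0.0, 0.0, w * self.pixel_size, h * self.pixel_size)

    def read_window(self, row0: int, row1: int, col0: int, col1: int) -> np.ndarray:
        """Materialise the (C, row1-row0, col1-col0) window as a numpy array."""
        return np.asarray(self.data[:, row0:row1, col0:col1])

    def iter_chunks(self) -> Iterator[tuple[int, int, int, int]]:
        """Yield (row0, row1, col0, col1) pixel windows of the chunk grid."""
        _, h, w = self.data.shape
        ch, cw = self.chunk_shape
        for r0 in range(0, h, ch):
            for c0 in range(0, w, cw):
                yield r0, min(r0 + ch, h), c0, min(c0 + cw, w)

    def world_to_pixel(self, x: float, y: float) -> tuple[int, int]:
        """(row, col) of the pixel whose square contains world point (x, y)."""
        return int(np.floor(y / self.pixel_size)), int(np.floor(x / self.pixel_size))


@dataclass
class TranscriptTable:
    """Detected transcripts: world coordinates (µm) plus a categorical gene label."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = {"x", "y", "gene"} - set(self.df.columns)
        if missing:
            raise ValidationError(f"transcript table missing columns: {sorted(missing)}")
        if len(self.df) and not np.all(np.isfinite(self.df[["x", "y"]].to_numpy(float))):
            raise ValidationError("transcript coordinates must be finite")
        if not isinstance(self.df["gene"].dtype, pd.CategoricalDtype):
            self.df = self.df.assign(gene=self.df["gene"].astype("category"))

    @classmethod
    def from_arrays(cls, x, y, gene, vocabulary: Sequence[str] | None = None,
                    ) -> "TranscriptTable":
        gene = pd.Categorical(gene, categories=vocabulary)
        if gene.isna().any():
            raise ValidationError("gene labels outside the declared vocabulary")
        return cls(pd.DataFrame({"x": np.asarray(x, float), "y": np.asarray(y, float),
                                 "gene": gene}))

    @property
    def x(self) -> np.ndarray:
        return self.df["x"].to_numpy(float)

    @property
    def y(self) -> np.ndarray:
        return self.df["y"].to_numpy(float)

    @property
    def gene_codes(self) -> np.ndarray:
        return self.df["gene"].cat.codes.to_numpy()

    @property
    def genes(self) -> list[str]:
        """The gene vocabulary (categorical levels)."""
        return list(self.df["gene"].cat.categories)

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class CellCollection:
    """Polygonal cell boundaries in world µm with stable ids and patch provenance."""

    cell_ids: np.ndarray
    polygons: list[Polygon]
    provenance: list[frozenset[int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.cell_ids = np.asarray(self.cell_ids, dtype=np.int64)
        if len(self.cell_ids) != len(self.polygons):
            raise ValidationError("cell_ids and polygons must have equal length")
        if len(np.unique(self.cell_ids)) != len(self.cell_ids):
            raise ValidationError("cell_ids must be unique")
        if not self.provenance:
            self.provenance = [frozenset() for _ in self.polygons]
        self.polygons = [repair_polygon(p) for p in self.polygons]
        for cid, p in zip(self.cell_ids, self.polygons):
            if p.area <= 0:
                raise ValidationError(f"cell {cid} has zero area")

    @classmethod
    def from_polygons(cls, polygons: Sequence[Polygon],
                      patch_index: int | None = None) -> "CellCollection":
        prov = [frozenset() if patch_index is None else frozenset({patch_index})
                for _ in polygons]
        return cls(np.arange(len(polygons)), list(polygons), prov)

    def __len__(self) -> int:
        return len(self.polygons)

    @property
    def areas(self) -> np.ndarray:
        return np.array([p.area for p in self.polygons])

    @property
    def centroids(self) -> np.ndarray:
        """(N, 2) array of centroid (x, y) in µm."""
        if not self.polygons:
            return np.empty((0, 2))
        return np.array([[p.centroid.x, p.centroid.y] for p in self.polygons])


@dataclass
class AffineTransform:
    """Homogeneous 3x3 transform mapping world coordinates between layers."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, float)
        if self.matrix.shape != (3, 3):
            raise ValidationError("affine matrix must be 3x3")
        if abs(np.linalg.det(self.matrix)) < 1e-300:
            raise ValidationError("affine matrix is singular")

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.eye(3))

    @classmethod
    def translation(cls, dx: float, dy: float) -> "AffineTransform":
        m = np.eye(3)
        m[0, 2], m[1, 2] = dx, dy
        return cls(m)

    def inverse(self) -> "AffineTransform":
        return AffineTransform(np.linalg.inv(self.matrix))

    def apply_points(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, float)
        homo = np.column_stack([pts, np.ones(len(pts))])
        out = homo @ self.matrix.T
        return out[:, :2] / out[:, 2:3]

    def apply_geometry(self, geom: BaseGeometry) -> BaseGeometry:
        return shapely.transform(geom, self.apply_points)


def apply_affine(obj, transform: AffineTransform):
    """Map points (array (N,2)) or shapely geometry through an affine transform."""
    if isinstance(obj, BaseGeometry):
        return transform.apply_geometry(obj)
    return transform.apply_points(np.asarray(obj, float))


@dataclass
class ChannelMatrix:
    """Per-cell mean channel intensities, N cells x P channels."""

    X: np.ndarray
    channels: list[str]
    cell_ids: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, float)
        self.cell_ids = np.asarray(self.cell_ids, dtype=np.int64)
        if self.X.ndim != 2 or self.X.shape != (len(self.cell_ids), len(self.channels)):
            raise ValidationError("ChannelMatrix shape inconsistent with labels")
        if np.any(self.X < 0):
            raise ValidationError("raw channel means must be non-negative")


@dataclass
class CountsMatrix:
    """Per-cell gene counts, N cells x G genes, sparse non-negative integers."""

    matrix: sparse.csr_matrix
    genes: list[str]
    cell_ids: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = sparse.csr_matrix(self.matrix)
        self.cell_ids = np.asarray(self.cell_ids, dtype=np.int64)
        if self.matrix.shape != (len(self.cell_ids), len(self.genes)):
            raise ValidationError("CountsMatrix shape inconsistent with labels")
        if self.matrix.nnz and self.matrix.data.min() < 0:
            raise ValidationError("counts must be non-negative")

    def toarray(self) -> np.ndarray:
        return self.matrix.toarray()
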