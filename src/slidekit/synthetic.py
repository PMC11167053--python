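"""Deterministic synthetic tissue generator.

Emulates an image-based spatial omics run at desk scale: disc-like cells
(regular 24-gons) scattered without overlap on a multi-channel staining
image, each cell carrying a type-specific marker signal and a Poisson
number of transcripts placed uniformly inside its boundary, plus uniform
background transcripts.  Niche labels are assigned by a known spatial
partition so downstream graph statistics have a ground truth.

A single global seed fans out to independent substreams (placement, image
noise, transcripts, background) so each stage is individually reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Point, Polygon

from .core import CellCollection, RasterImage, TranscriptTable

# Default study conditions: a 200 µm square tile imaged at 0.5 µm/px with
# ~10 µm diameter cells, three populations with one marker channel each plus
# a nuclear channel, 50 transcripts per cell and sparse background noise.
DEFAULT_CHANNELS = ["DAPI", "CD3", "CD20", "PanCK"]
DEFAULT_TYPES = {
    # type -> per-channel mean intensity inside the cell (DAPI, CD3, CD20, PanCK)
    "T cell": (150.0, 200.0, 10.0, 10.0),
    "B cell": (150.0, 10.0, 200.0, 10.0),
    "Tumor": (150.0, 10.0, 10.0, 200.0),
}
DEFAULT_MARKER_MAP = {"CD3": "T cell", "CD20": "B cell", "PanCK": "Tumor"}
DEFAULT_GENES = ["CD3E", "MS4A1", "EPCAM", "ACTB"]
DEFAULT_GENE_PROFILES = {
    "T cell": (0.60, 0.05, 0.05, 0.30),
    "B cell": (0.05, 0.60, 0.05, 0.30),
    "Tumor": (0.05, 0.05, 0.60, 0.30),
}

N_GON_SIDES = 24  # regular 24-gon ~ disc, with closed-form area/perimeter


class GenerationError(RuntimeError):
    """Raised when cells cannot be packed into the requested area."""


def regular_polygon(cx: float, cy: float, radius: float, n_sides: int = N_GON_SIDES,
                    rotation: float = 0.0) -> Polygon:
    """Regular n-gon of given circumradius centred at (cx, cy)."""
    angles = rotation + 2 * math.pi * np.arange(n_sides) / n_sides
    return Polygon(np.column_stack([cx + radius * np.cos(angles),
                                    cy + radius * np.sin(angles)]))


def regular_polygon_area(radius: float, n_sides: int = N_GON_SIDES) -> float:
    return 0.5 * n_sides * radius**2 * math.sin(2 * math.pi / n_sides)


@dataclass
class SyntheticGroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    true_cells: CellCollection
    cell_type: list[str]
    niche: list[str]
    transcript_cell: np.ndarray  # per transcript: source cell index, -1 = background
    channel_profiles: dict[str, tuple]
    gene_profiles: dict[str, tuple] = field(default_factory=dict)


def _place_centers(rng: np.random.Generator, n_cells: int, size: float,
                   radius: float, min_spacing: float) -> np.ndarray:
    """Rejection-sample centers with pairwise distance >= min_spacing, kept at
    least one radius away from the borders."""
    lo, hi = radius, size - radius
    if hi <= lo:
        raise GenerationError("image too small for the requested cell radius")
    centers: list[np.ndarray] = []
    max_tries = 2000 * max(n_cells, 1)
    tries = 0
    while len(centers) < n_cells:
        if tries >= max_tries:
            raise GenerationError(
                f"could only place {len(centers)}/{n_cells} cells after {max_tries} tries")
        tries += 1
        cand = rng.uniform(lo, hi, size=2)
        if all(np.hypot(*(cand - c)) >= min_spacing for c in centers):
            centers.append(cand)
    return np.array(centers) if centers else np.empty((0, 2))


def _uniform_in_polygon(rng: np.random.Generator, poly: Polygon, n: int) -> np.ndarray:
    """Uniform points inside a polygon by bounding-box rejection sampling."""
    xmin, ymin, xmax, ymax = poly.bounds
    out = np.empty((n, 2))
    got = 0
    while got < n:
        cand = rng.uniform((xmin, ymin), (xmax, ymax), size=(max(2 * (n - got), 8), 2))
        import shapely

        keep = cand[shapely.contains_xy(poly, cand[:, 0], cand[:, 1])]
        take = min(len(keep), n - got)
        out[got:got + take] = keep[:take]
        got += take
    return out


def _niche_label(center: np.ndarray, size: float, mode: str) -> str:
    if mode == "halves":
        return "niche_0" if center[0] < size / 2 else "niche_1"
    if mode == "rings":
        r = np.hypot(center[0] - size / 2, center[1] - size / 2)
        return "niche_0" if r < size / 4 else "niche_1"
    raise ValueError(f"unknown niche mode {mode!r}")


def generate_tissue(
    n_cells: int = 120,
    cell_radius_um: float = 5.0,
    image_size_um: float = 200.0,
    pixel_size: float = 0.5,
    types: dict[str, tuple] | None = None,
    channels: list[str] | None = None,
    gene_profiles: dict[str, tuple] | None = None,
    genes: list[str] | None = None,
    niche_mode: str = "halves",
    transcripts_per_cell: float = 50.0,
    background_rate: float = 0.001,
    background_level: float = 5.0,
    noise_sd: float = 3.0,
    min_spacing_factor: float = 2.0,
    seed: int = 0,
    chunk_shape: tuple[int, int] = (1024, 1024),
) -> tuple[RasterImage, TranscriptTable, SyntheticGroundTruth]:
    """Generate a synthetic tissue tile.

    Parameters
    ----------
    n_cells
        Number of cells to place; rejection sampling enforces center spacing
        of ``min_spacing_factor * cell_radius_um`` so cells never overlap.
    background_rate
        Expected background transcripts per µm² (uniform over the tile).
    seed
        Global seed; substreams are spawned per component.

    Returns the staining image, the transcript table (cell transcripts first,
    background last) and the ground truth.
    """
    types = dict(DEFAULT_TYPES if types is None else types)
    channels = list(DEFAULT_CHANNELS if channels is None else channels)
    gene_profiles = dict(DEFAULT_GENE_PROFILES if gene_profiles is None else gene_profiles)
    genes = list(DEFAULT_GENES if genes is None else genes)
    if n_cells < 0 or cell_radius_um <= 0 or image_size_um <= 0 or pixel_size <= 0:
        raise ValueError("generator parameters must be positive")

    ss = np.random.SeedSequence(seed)
    rng_place, rng_type, rng_img, rng_tx, rng_bg = (
        np.random.default_rng(s) for s in ss.spawn(5))

    n_px = int(round(image_size_um / pixel_size))
    type_names = list(types)

    if n_cells > 0:
        centers = _place_centers(rng_place, n_cells, image_size_um, cell_radius_um,
                                 min_spacing_factor * cell_radius_um)
        rotations = rng_place.uniform(0, 2 * math.pi / N_GON_SIDES, size=n_cells)
        cell_types = [type_names[i] for i in rng_type.integers(0, len(type_names),
                                                               size=n_cells)]
    else:
        centers = np.empty((0, 2))
        rotations = np.empty(0)
        cell_types = []

    polygons = [regular_polygon(cx, cy, cell_radius_um, rotation=rot)
                for (cx, cy), rot in zip(centers, rotations)]
    true_cells = CellCollection.from_polygons(polygons)
    niches = [_niche_label(c, image_size_um, niche_mode) for c in centers]

    # render the staining image: background + per-cell type profile, noisy
    data = np.clip(
        background_level + rng_img.normal(0, noise_sd, size=(len(channels), n_px, n_px)),
        0, None).astype(np.float32)
    from .core import raster_membership

    for poly, ctype in zip(polygons, cell_types):
        xmin, ymin, xmax, ymax = poly.bounds
        c0, c1 = int(xmin / pixel_size), min(int(xmax / pixel_size) + 2, n_px)
        r0, r1 = int(ymin / pixel_size), min(int(ymax / pixel_size) + 2, n_px)
        mask = raster_membership(poly, r0, r1, c0, c1, pixel_size)
        profile = types[ctype]
        for ch in range(len(channels)):
            window = data[ch, r0:r1, c0:c1]
            noise = rng_img.normal(0, noise_sd, size=window.shape)
            window[mask] = np.clip(profile[ch] + noise, 0, None)[mask]

    image = RasterImage(data, channels, pixel_size, chunk_shape)

    # transcripts: Poisson(lambda) per cell, uniform inside the polygon
    xs, ys, codes, owner = [], [], [], []
    for i, (poly, ctype) in enumerate(zip(polygons, cell_types)):
        k = rng_tx.poisson(transcripts_per_cell)
        if k == 0:
            continue
        pts = _uniform_in_polygon(rng_tx, poly, k)
        probs = np.asarray(gene_profiles[ctype], float)
        drawn = rng_tx.choice(len(genes), size=k, p=probs / probs.sum())
        xs.append(pts[:, 0]); ys.append(pts[:, 1])
        codes.append(drawn); owner.append(np.full(k, i))
    n_bg = rng_bg.poisson(background_rate * image_size_um**2)
    if n_bg:
        pts = rng_bg.uniform(0, image_size_um, size=(n_bg, 2))
        xs.append(pts[:, 0]); ys.append(pts[:, 1])
        codes.append(rng_bg.integers(0, len(genes), size=n_bg))
        owner.append(np.full(n_bg, -1))

    if xs:
        x = np.concatenate(xs); y = np.concatenate(ys)
        gcodes = np.concatenate(codes); owner_arr = np.concatenate(owner)
    else:
        x = y = np.empty(0)
        gcodes = np.empty(0, int); owner_arr = np.empty(0, int)
    transcripts = TranscriptTable.from_arrays(
        x, y, [genes[int(c)] for c in gcodes], vocabulary=genes)

    truth = SyntheticGroundTruth(true_cells, cell_types, niches,
                                 owner_arr.astype(np.int64),
                                 {t: tuple(p) for t, p in types.items()},
                                 {t: tuple(p) for t, p in gene_profiles.items()})
    return image, transcripts, truth
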