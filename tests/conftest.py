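import numpy as np
import pytest

import slidekit as sk

# built-in segmenter settings used across tests: the nuclear channel is far
# above the background level, watershed separates touching cells
SEG_PARAMS = {"channel": 0, "threshold": 50, "min_area_px": 30,
              "split_touching": True}

MARKER_MAP = {"CD3": "T cell", "CD20": "B cell", "PanCK": "Tumor"}


@pytest.fixture(scope="session")
def tissue():
    """Small synthetic tissue: 40 cells on a 120 µm tile, 64 px chunks."""
    return sk.generate_tissue(n_cells=40, image_size_um=120.0, seed=11,
                              chunk_shape=(64, 64))


@pytest.fixture(scope="session")
def grid22(tissue):
    """2x2 patch grid; the 40 µm overlap is well above twice the 10 µm cell diameter."""
    image, _, _ = tissue
    return sk.make_patches(image.extent, 80.0, 40.0)


@pytest.fixture(scope="session")
def per_patch(tissue, grid22):
    image, _, _ = tissue
    return sk.run_segmentation(image, grid22, params=SEG_PARAMS)


@pytest.fixture(scope="session")
def resolved(per_patch):
    return sk.resolve_conflicts(per_patch)


def random_cells(rng: np.random.Generator, n: int, size: float,
                 rmin: float = 3.0, rmax: float = 7.0) -> sk.CellCollection:
    """Random disc-like cells (possibly overlapping) inside a square tile."""
    from slidekit.synthetic import regular_polygon

    centers = rng.uniform(rmax, size - rmax, size=(n, 2))
    radii = rng.uniform(rmin, rmax, size=n)
    rots = rng.uniform(0, 2 * np.pi, size=n)
    return sk.CellCollection.from_polygons(
        [regular_polygon(cx, cy, r, rotation=rot)
         for (cx, cy), r, rot in zip(centers, radii, rots)])
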