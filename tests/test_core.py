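"""Data model: coordinate conventions, transforms, and lossless round trips."""

import numpy as np
import pytest
from scipy import sparse
from shapely.geometry import Polygon, box

import slidekit as sk
from slidekit import io as skio
from slidekit.core import repair_polygon


class TestRasterImage:
    def test_extent_and_pixel_mapping(self):
        img = sk.RasterImage(np.zeros((2, 64, 64), np.float32),
                             ["a", "b"], 0.5)
        assert img.extent == (0.0, 0.0, 32.0, 32.0)
        # pixel -> world center -> pixel is the identity on pixel indices
        for r, c in [(0, 0), (10, 3), (63, 63)]:
            x, y = (c + 0.5) * 0.5, (r + 0.5) * 0.5
            assert img.world_to_pixel(x, y) == (r, c)

    def test_chunks_tile_the_image(self):
        img = sk.RasterImage(np.zeros((1, 100, 70)), ["a"], 1.0, chunk_shape=(64, 64))
        windows = list(img.iter_chunks())
        covered = np.zeros((100, 70), int)
        for r0, r1, c0, c1 in windows:
            covered[r0:r1, c0:c1] += 1
        assert (covered == 1).all()

    @pytest.mark.parametrize("bad", [
        dict(pixel_size=0.0), dict(pixel_size=-1.0), dict(pixel_size=np.inf),
        dict(channel_names=["only_one"]),
    ])
    def test_validation(self, bad):
        kwargs = dict(data=np.zeros((2, 8, 8)), channel_names=["a", "b"],
                      pixel_size=0.5)
        kwargs.update(bad)
        with pytest.raises(sk.ValidationError):
            sk.RasterImage(**kwargs)


class TestAffine:
    def test_identity_and_translation(self):
        p = np.array([[0.0, 0.0]])
        assert np.allclose(sk.apply_affine(p, sk.AffineTransform.identity()), p)
        t = sk.AffineTransform.translation(10, -5)
        assert np.allclose(sk.apply_affine(p, t), [[10.0, -5.0]])
        sq = box(0, 0, 1, 1)
        moved = sk.apply_affine(sq, t)
        assert moved.bounds == (10.0, -5.0, 11.0, -4.0)

    def test_inverse_restores_points(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            m = rng.normal(size=(3, 3))
            m[2] = [0, 0, 1]
            if abs(np.linalg.det(m)) < 1e-3:
                continue
            t = sk.AffineTransform(m)
            pts = rng.uniform(-100, 100, size=(100, 2))
            back = sk.apply_affine(sk.apply_affine(pts, t), t.inverse())
            assert np.allclose(back, pts, atol=1e-9)

    def test_singular_matrix_rejected(self):
        with pytest.raises(sk.ValidationError):
            sk.AffineTransform(np.zeros((3, 3)))


class TestRoundTrips:
    def test_cells_geojson(self, tmp_path):
        cells = sk.CellCollection(
            np.array([3, 7]), [box(0, 0, 5, 5), box(10, 0, 15, 5)],
            [frozenset({0}), frozenset({0, 1})])
        path = tmp_path / "cells.geojson"
        skio.write_cells(cells, path)
        back = skio.read_cells(path)
        assert list(back.cell_ids) == [3, 7]
        assert back.provenance == [frozenset({0}), frozenset({0, 1})]
        for a, b in zip(cells.polygons, back.polygons):
            assert a.equals_exact(b, 1e-9)

    def test_empty_cells_geojson(self, tmp_path):
        skio.write_cells(sk.CellCollection(np.empty(0, int), []),
                         tmp_path / "e.geojson")
        assert len(skio.read_cells(tmp_path / "e.geojson")) == 0

    def test_counts_mtx(self, tmp_path):
        rng = np.random.default_rng(0)
        for seed in range(5):
            dense = (np.random.default_rng(seed).random((7, 5)) < 0.3) * \
                np.random.default_rng(seed + 100).integers(1, 9, (7, 5))
            counts = sk.CountsMatrix(sparse.csr_matrix(dense),
                                     [f"g{i}" for i in range(5)], np.arange(7))
            skio.write_counts(counts, tmp_path / f"c{seed}.mtx")
            back = skio.read_counts(tmp_path / f"c{seed}.mtx")
            assert (back.toarray() == dense).all()
            assert back.genes == counts.genes
        del rng

    def test_transcripts_csv(self, tmp_path):
        t = sk.TranscriptTable.from_arrays([1.0, 2.0, 3.0], [4.0, 5.0, 6.0],
                                           ["a", "b", "a"], ["a", "b"])
        skio.write_transcripts(t, tmp_path / "t.csv")
        back = skio.read_transcripts(tmp_path / "t.csv")
        assert len(back) == 3
        assert list(back.df["gene"]) == ["a", "b", "a"]

    def test_image_roundtrip_tiff_and_zarr(self, tmp_path):
        data = np.random.default_rng(1).random((2, 64, 64)).astype(np.float32)
        img = sk.RasterImage(data, ["c0", "c1"], 0.5)
        for name in ("img.tif", "img.zarr"):
            skio.write_image(img, tmp_path / name)
            back = skio.read_image(tmp_path / name, 0.5, ["c0", "c1"])
            assert back.shape == (2, 64, 64)
            assert np.array_equal(back.read_window(0, 64, 0, 64), data)

    def test_random_geojson_roundtrip_many_seeds(self, tmp_path):
        from tests.conftest import random_cells

        for seed in range(50):
            cells = random_cells(np.random.default_rng(seed), 5, 50.0)
            skio.write_cells(cells, tmp_path / "r.geojson")
            back = skio.read_cells(tmp_path / "r.geojson")
            for a, b in zip(cells.polygons, back.polygons):
                assert a.equals_exact(b, 1e-9)


class TestLoadDataset:
    def test_minimal_image_only(self, tmp_path):
        img = sk.RasterImage(np.zeros((2, 64, 64), np.float32), ["a", "b"], 0.5)
        skio.write_image(img, tmp_path / "image.tif")
        image, transcripts, cells = skio.load_dataset(
            {"image": str(tmp_path / "image.tif"), "pixel_size": 0.5})
        assert image.shape == (2, 64, 64)
        assert transcripts is None and cells is None

    def test_missing_file_names_path(self):
        with pytest.raises(skio.LoadError, match="nope.tif"):
            skio.load_dataset({"image": "nope.tif", "pixel_size": 0.5})

    def test_bad_pixel_size(self, tmp_path):
        with pytest.raises(sk.ValidationError):
            skio.load_dataset({"image": str(tmp_path), "pixel_size": 0})

    def test_transcripts_preserved(self, tmp_path):
        img = sk.RasterImage(np.zeros((1, 8, 8), np.float32), ["a"], 1.0)
        skio.write_image(img, tmp_path / "image.tif")
        t = sk.TranscriptTable.from_arrays([1, 2, 3], [1, 2, 3], ["x", "y", "x"])
        skio.write_transcripts(t, tmp_path / "t.csv")
        _, back, _ = skio.load_dataset({"image": str(tmp_path / "image.tif"),
                                        "pixel_size": 1.0,
                                        "transcripts": str(tmp_path / "t.csv")})
        assert len(back) == 3 and list(back.df["gene"]) == ["x", "y", "x"]


def test_repair_keeps_largest_part():
    bowtie = Polygon([(0, 0), (2, 2), (2, 0), (0, 2)])  # self-intersecting
    fixed = repair_polygon(bowtie)
    assert fixed.is_valid and fixed.area > 0
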