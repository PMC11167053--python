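"""Visualizer bundle: pyramid schedules, fixed-width boundaries, sparse tables."""

import json
from pathlib import Path

import numpy as np
import pytest
import zarr
from scipy import sparse

import slidekit as sk
from slidekit.explorer import (BASE_TILE_UM, N_VERTICES, TILE_PX, block_mean_2x2,
                               pad_boundary, pyramid_level_shapes,
                               read_counts_dense, transcript_level_schedule,
                               write_bundle)
from slidekit.synthetic import regular_polygon


def _tree_bytes(root: Path) -> dict:
    return {str(p.relative_to(root)): p.read_bytes()
            for p in sorted(root.rglob("*")) if p.is_file()}


class TestImagePyramid:
    def test_level_schedule(self):
        assert pyramid_level_shapes(512, 512) == [(512, 512)]
        assert pyramid_level_shapes(4096, 4096) == [(4096, 4096), (2048, 2048),
                                                    (1024, 1024)]
        assert pyramid_level_shapes(1025, 100) == [(1025, 100), (513, 50)]

    def test_level0_lossless_and_level1_block_mean(self, tmp_path, tissue):
        image, _, _ = tissue
        # force a multi-level pyramid by shrinking the tile size via block_mean oracle
        bundle = tmp_path / "b"
        write_bundle(bundle, image=image)
        g = zarr.open_group(str(bundle / "images.zarr"), mode="r")
        lvl0 = np.asarray(g["0"])
        assert np.array_equal(lvl0, np.asarray(image.data, dtype=np.float32))

    def test_downsample_matches_independent_oracle(self):
        rng = np.random.default_rng(0)
        arr = rng.random((2, 8, 8)).astype(np.float32)
        down = block_mean_2x2(arr)
        oracle = arr.reshape(2, 4, 2, 4, 2).mean(axis=(2, 4))
        np.testing.assert_allclose(down, oracle, rtol=1e-6)

    def test_odd_dimensions(self):
        arr = np.arange(15, dtype=np.float32).reshape(1, 3, 5)
        down = block_mean_2x2(arr)
        assert down.shape == (1, 2, 3)
        assert down[0, 0, 0] == pytest.approx((0 + 1 + 5 + 6) / 4)
        assert down[0, 1, 2] == pytest.approx(14.0)  # single corner pixel

    def test_tiles_are_1024(self, tmp_path, tissue):
        image, _, _ = tissue
        write_bundle(tmp_path / "b", image=image)
        g = zarr.open_group(str(tmp_path / "b" / "images.zarr"), mode="r")
        assert g["0"].chunks == (1, TILE_PX, TILE_PX)


class TestTranscriptPyramid:
    def test_level_width_schedule(self):
        assert transcript_level_schedule((400.0, 400.0)) == [250.0, 500.0]
        assert transcript_level_schedule((200.0, 200.0)) == [250.0]
        assert transcript_level_schedule((1100.0, 300.0)) == [250.0, 500.0,
                                                              1000.0, 2000.0]

    def test_level_sizes_quartered(self, tmp_path):
        rng = np.random.default_rng(1)
        n = 1000
        t = sk.TranscriptTable.from_arrays(rng.uniform(0, 600, n),
                                           rng.uniform(0, 600, n),
                                           ["g"] * n, ["g"])
        img = sk.RasterImage(np.zeros((1, 1200, 1200), np.float32), ["c"], 0.5)
        write_bundle(tmp_path / "b", image=img, transcripts=t)
        g = zarr.open_group(str(tmp_path / "b" / "transcripts.zarr"), mode="r")
        sizes = []
        level = 0
        while f"level_{level}" in g:
            lvl = g[f"level_{level}"]
            sizes.append(sum(lvl[tile]["x"].shape[0] for tile in lvl.keys()))
            level += 1
        assert sizes[0] == 1000
        for prev, cur in zip(sizes, sizes[1:]):
            assert cur == -(-prev // 4)  # every 4th kept, offset 0

    def test_base_tiles_are_250um(self, tmp_path, tissue):
        image, transcripts, _ = tissue
        write_bundle(tmp_path / "b", image=image, transcripts=transcripts)
        g = zarr.open_group(str(tmp_path / "b" / "transcripts.zarr"), mode="r")
        assert g["level_0"].attrs["tile_width_um"] == BASE_TILE_UM == 250.0

    def test_level0_partition_reproduces_input(self, tmp_path, tissue):
        image, transcripts, _ = tissue
        write_bundle(tmp_path / "b", image=image, transcripts=transcripts)
        g = zarr.open_group(str(tmp_path / "b" / "transcripts.zarr"), mode="r")
        lvl = g["level_0"]
        ids, xs = [], []
        for tile in lvl.keys():
            ids.append(np.asarray(lvl[tile]["id"]))
            xs.append(np.asarray(lvl[tile]["x"]))
        ids = np.concatenate(ids)
        xs = np.concatenate(xs)
        order = np.argsort(ids)
        assert np.array_equal(ids[order], np.arange(len(transcripts)))
        np.testing.assert_array_equal(xs[order], transcripts.x)


class TestBoundaries:
    def test_triangle_padded(self):
        tri = regular_polygon(0, 0, 5.0, n_sides=3)
        arr = pad_boundary(tri)
        assert arr.shape == (N_VERTICES, 2)
        assert np.array_equal(arr[2], arr[12])  # last vertex repeated

    def test_thirteen_vertices_unchanged(self):
        poly = regular_polygon(0, 0, 5.0, n_sides=13)
        arr = pad_boundary(poly)
        np.testing.assert_allclose(arr, np.asarray(poly.exterior.coords)[:-1])

    def test_near_circle_simplified_within_area_tolerance(self):
        poly = regular_polygon(0, 0, 10.0, n_sides=60)
        arr = pad_boundary(poly)
        from shapely.geometry import Polygon

        assert len(np.unique(arr, axis=0)) <= N_VERTICES
        simplified = Polygon(arr).convex_hull
        assert abs(simplified.area - poly.area) / poly.area < 0.10

    def test_bundle_array_shape(self, tmp_path, resolved):
        write_bundle(tmp_path / "b", cells=resolved.cells)
        g = zarr.open_group(str(tmp_path / "b" / "cells.zarr"), mode="r")
        assert g["boundaries"].shape == (len(resolved.cells), 13, 2)


class TestTables:
    def test_hand_compressed_layout(self, tmp_path):
        counts = sk.CountsMatrix(sparse.csr_matrix(np.array([[1, 0], [0, 2]])),
                                 ["g0", "g1"], np.array([0, 1]))
        from slidekit.explorer import export_tables

        export_tables(counts, None, tmp_path)
        g = zarr.open_group(str(tmp_path / "tables.zarr"), mode="r")["counts"]
        assert np.asarray(g["data"]).tolist() == [1, 2]
        assert np.asarray(g["cell_index"]).tolist() == [0, 1]
        assert np.asarray(g["gene_pointer"]).tolist() == [0, 1, 2]

    def test_all_zero_counts(self, tmp_path):
        counts = sk.CountsMatrix(sparse.csr_matrix((3, 2), dtype=int),
                                 ["g0", "g1"], np.arange(3))
        from slidekit.explorer import export_tables

        export_tables(counts, None, tmp_path)
        g = zarr.open_group(str(tmp_path / "tables.zarr"), mode="r")["counts"]
        assert np.asarray(g["data"]).size == 0
        assert np.asarray(g["gene_pointer"]).tolist() == [0, 0, 0]

    @pytest.mark.parametrize("seed", range(10))
    def test_random_sparse_roundtrip(self, tmp_path, seed):
        rng = np.random.default_rng(seed)
        dense = (rng.random((12, 8)) < 0.25) * rng.integers(1, 20, (12, 8))
        counts = sk.CountsMatrix(sparse.csr_matrix(dense),
                                 [f"g{i}" for i in range(8)], np.arange(12))
        from slidekit.explorer import export_tables

        export_tables(counts, None, tmp_path / str(seed))
        assert (read_counts_dense(tmp_path / str(seed)) == dense).all()

    def test_categories_grouped_by_label(self, tmp_path):
        from slidekit.explorer import export_tables

        export_tables(None, {"kind": ["b", "a", "b", "a", "a"]}, tmp_path)
        g = zarr.open_group(str(tmp_path / "tables.zarr"), mode="r")
        cat = g["categories"]["kind"]
        assert cat.attrs["values"] == ["a", "b"]
        assert np.asarray(cat["indices"]).tolist() == [1, 3, 4, 0, 2]
        assert np.asarray(cat["pointers"]).tolist() == [0, 3, 5]

    def test_unlabeled_cells_rejected(self, tmp_path):
        from slidekit.explorer import export_tables

        with pytest.raises(sk.ValidationError):
            export_tables(None, {"kind": ["a", None]}, tmp_path)


class TestWriteBundle:
    def test_imaging_only_omits_transcripts(self, tmp_path, tissue):
        image, _, _ = tissue
        meta = write_bundle(tmp_path / "b", image=image)
        assert meta["parts"]["transcripts"] is False
        assert not (tmp_path / "b" / "transcripts.zarr").exists()

    def test_full_bundle_metadata(self, tmp_path, tissue, resolved):
        image, transcripts, _ = tissue
        counts, _ = sk.count_transcripts(transcripts, resolved.cells)
        meta = write_bundle(tmp_path / "b", image=image, transcripts=transcripts,
                            cells=resolved.cells, counts=counts,
                            categories={"cell_type": ["A"] * len(resolved.cells)})
        doc = json.loads((tmp_path / "b" / "experiment.json").read_text())
        assert doc == meta
        assert all(doc["parts"].values())
        assert doc["n_cells"] == len(resolved.cells)

    def test_nothing_to_export_rejected(self, tmp_path):
        with pytest.raises(sk.ValidationError):
            write_bundle(tmp_path / "b")

    def test_reexport_is_byte_identical(self, tmp_path, tissue, resolved):
        image, transcripts, _ = tissue
        write_bundle(tmp_path / "one", image=image, transcripts=transcripts,
                     cells=resolved.cells)
        write_bundle(tmp_path / "two", image=image, transcripts=transcripts,
                     cells=resolved.cells)
        a, b = _tree_bytes(tmp_path / "one"), _tree_bytes(tmp_path / "two")
        assert a.keys() == b.keys()
        assert all(a[k] == b[k] for k in a)
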