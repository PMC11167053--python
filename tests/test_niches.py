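"""Niche polygonization: ring extraction, holes, filtering and roundness."""

import math

import numpy as np
import pytest

import slidekit as sk
from slidekit.niches import NicheComponent, _ring_area, extract_niche_polygons, niche_stats
from shapely.geometry import Polygon


def _grid_points(nx, ny, spacing=10.0, origin=(0.0, 0.0)):
    xs, ys = np.meshgrid(np.arange(nx) * spacing + origin[0],
                         np.arange(ny) * spacing + origin[1])
    return np.column_stack([xs.ravel(), ys.ravel()])


class TestExtract:
    def test_uniform_grid_single_component_no_holes(self):
        pts = _grid_points(10, 10)
        sg = sk.build_graph(pts, 40.0)
        comps = extract_niche_polygons(sg, ["g"] * 100)
        assert len(comps) == 1
        comp = comps[0]
        assert len(comp.polygon.interiors) == 0
        assert comp.n_cells == 100
        # polygon area equals the sum of retained triangle areas
        assert comp.area == pytest.approx(comp.triangle_area, rel=1e-9)
        assert comp.area == pytest.approx(90.0 * 90.0, rel=1e-9)

    def test_annulus_surrounding_core_has_one_hole(self):
        rng_angles = np.linspace(0, 2 * math.pi, 36, endpoint=False)
        ring1 = np.column_stack([60 + 20 * np.cos(rng_angles),
                                 60 + 20 * np.sin(rng_angles)])
        ring2 = np.column_stack([60 + 28 * np.cos(rng_angles),
                                 60 + 28 * np.sin(rng_angles)])
        core = _grid_points(3, 3, 6.0, origin=(54.0, 54.0))
        pts = np.vstack([ring1, ring2, core])
        labels = ["A"] * 72 + ["B"] * 9
        sg = sk.build_graph(pts, 40.0)
        comps = extract_niche_polygons(sg, labels)
        by_niche = {c.niche: c for c in comps}
        assert len(by_niche["A"].polygon.interiors) == 1
        assert len(by_niche["B"].polygon.interiors) == 0
        # hole-aware area conservation still holds
        assert by_niche["A"].area == pytest.approx(by_niche["A"].triangle_area,
                                                   rel=1e-6)

    def test_two_isolated_clusters_count_two_occurrences(self):
        a = _grid_points(3, 3, 10.0, origin=(0.0, 0.0))
        b = _grid_points(3, 3, 10.0, origin=(200.0, 0.0))
        sg = sk.build_graph(np.vstack([a, b]), 40.0)
        comps = extract_niche_polygons(sg, ["g"] * 18)
        assert len(comps) == 2
        assert all(c.niche == "g" for c in comps)

    def test_cross_niche_edges_pruned(self):
        pts = _grid_points(6, 3, 10.0)
        labels = ["L" if x < 25 else "R" for x, _ in pts]
        sg = sk.build_graph(pts, 40.0)
        comps = extract_niche_polygons(sg, labels)
        assert sorted(c.niche for c in comps) == ["L", "R"]
        total = sum(c.n_cells for c in comps)
        assert total == 18

    def test_tiny_component_skipped_with_warning(self):
        pts = np.array([[0.0, 0.0], [10.0, 0.0],  # 2-node component: no simplex
                        [100.0, 0.0], [110.0, 0.0], [100.0, 10.0], [110.0, 10.0]])
        sg = sk.build_graph(pts, 20.0)
        with pytest.warns(UserWarning, match="no triangle"):
            comps = extract_niche_polygons(sg, ["g"] * 6)
        assert len(comps) == 1 and comps[0].n_cells == 4

    def test_border_edges_form_closed_rings(self):
        rng = np.random.default_rng(8)
        pts = rng.uniform(0, 100, (60, 2))
        sg = sk.build_graph(pts, 30.0)
        labels = ["A" if x < 50 else "B" for x, _ in pts]
        for comp in extract_niche_polygons(sg, labels):
            parts = getattr(comp.polygon, "geoms", [comp.polygon])
            for part in parts:
                ext = np.asarray(part.exterior.coords)
                assert np.array_equal(ext[0], ext[-1])  # ring closed
            assert comp.polygon.area > 0


def _component(niche, area_target, n_cells=10):
    # square of given area as a stand-in component
    s = math.sqrt(area_target)
    poly = Polygon([(0, 0), (s, 0), (s, s), (0, s)])
    return NicheComponent(niche, poly, n_cells, poly.area)


class TestStats:
    def test_regular_64gon_roundness_near_one(self):
        from slidekit.synthetic import regular_polygon

        poly = regular_polygon(0, 0, 10.0, n_sides=64)
        comp = NicheComponent("g", poly, 1, poly.area)
        assert comp.roundness <= 1.0
        assert comp.roundness > 0.998  # within 0.2% of the disc limit

    def test_roundness_increases_with_vertex_count(self):
        from slidekit.synthetic import regular_polygon

        values = []
        for n in (3, 4, 8, 16, 32, 64, 128):
            poly = regular_polygon(0, 0, 10.0, n_sides=n)
            values.append(NicheComponent("g", poly, 1, poly.area).roundness)
        assert all(b > a for a, b in zip(values, values[1:]))
        assert all(0 < v <= 1 for v in values)

    def test_single_component_no_filtering(self):
        table = niche_stats([_component("g", 100.0)])
        assert table.loc["g", "occurrences"] == 1

    def test_five_percent_filter(self):
        comps = [_component("g", 100.0), _component("g", 6.0), _component("g", 4.0)]
        table = niche_stats(comps)
        assert table.loc["g", "occurrences"] == 2  # area-4 (4% of 100) dropped

    def test_density_is_cells_over_retained_area(self):
        comps = [_component("g", 100.0, n_cells=20),
                 _component("g", 50.0, n_cells=5)]
        table = niche_stats(comps)
        assert table.loc["g", "density"] == pytest.approx(25 / 150.0)

    def test_mean_statistics(self):
        comps = [_component("g", 100.0), _component("g", 64.0)]
        table = niche_stats(comps)
        assert table.loc["g", "mean_area"] == pytest.approx(82.0)
        assert table.loc["g", "mean_perimeter"] == pytest.approx((40 + 32) / 2)


def test_ring_area_shoelace():
    square = np.array([[0.0, 0.0], [4.0, 0.0], [4.0, 4.0], [0.0, 4.0]])
    assert _ring_area(square) == 16.0
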