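import math

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Point, box

import hexconn as hc
from hexconn.multiscale import build_adjacency
from hexconn.rasters import Raster

from conftest import make_focal_grid

CELL_HA = 5_000.0
EXTENT = (0.0, 0.0, 40_000.0, 36_000.0)


@pytest.fixture(scope="module")
def grid():
    return hc.tessellate(EXTENT, cell_area_ha=CELL_HA)


class TestTessellation:
    def test_edge_length_closed_form(self):
        s = hc.hexagon_edge_length(CELL_HA)
        assert s == pytest.approx(math.sqrt(2 * 5e7 / (3 * math.sqrt(3))))
        assert s == pytest.approx(4_386.91, abs=0.01)

    def test_interior_cells_have_exact_area(self, grid):
        interior = ~grid.cells["clipped"].to_numpy()
        assert interior.any()
        for poly, inside in zip(grid.polygons, interior):
            if inside:
                assert poly.area == pytest.approx(CELL_HA * 1e4, rel=1e-6)

    def test_interior_cells_have_six_neighbors(self, grid):
        # interior here means: every surrounding cell exists in the grid
        deg = grid.neighbor_counts()
        axial = set(zip(grid.cells["q"], grid.cells["r"]))
        for cid, q, r in zip(grid.cells["cell_id"], grid.cells["q"],
                             grid.cells["r"]):
            ring = [(q + dq, r + dr) for dq, dr in
                    ((1, 0), (-1, 0), (0, 1), (0, -1), (1, -1), (-1, 1))]
            if all(n in axial for n in ring):
                assert deg.loc[cid] == 6

    def test_cells_tile_extent_without_overlap(self, grid):
        extent_box = box(*EXTENT)
        covered = sum(p.intersection(extent_box).area for p in grid.polygons)
        assert covered == pytest.approx(extent_box.area, rel=1e-9)
        # pairwise interior overlaps have zero area (adjacent cells only touch)
        for i, j in grid.adjacency:
            inter = grid.polygons[i].intersection(grid.polygons[j])
            assert inter.area <= 1e-6

    def test_tiny_extent_yields_single_clipped_cell(self):
        with pytest.warns(UserWarning, match="single"):
            g = hc.tessellate((0, 0, 1_000.0, 1_000.0), cell_area_ha=CELL_HA)
        assert g.n_cells == 1
        assert bool(g.cells["clipped"].iloc[0])

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            hc.tessellate((0, 0, -10, 10), cell_area_ha=CELL_HA)
        with pytest.raises(ValueError):
            hc.hexagon_edge_length(0.0)


def test_flower_adjacency_degrees(flower_grid):
    deg = flower_grid.neighbor_counts()
    assert deg.loc[1] == 6            # center touches every ring cell
    assert (deg.loc[2:] == 3).all()   # ring cells: center + two ring neighbors


def test_assign_cells_agrees_with_polygons(grid, rng):
    res = 250.0
    h = int((EXTENT[3] - EXTENT[1]) / res)
    w = int((EXTENT[2] - EXTENT[0]) / res)
    raster = Raster(np.zeros((h, w)), res, origin=(EXTENT[0], EXTENT[3]))
    assignment = hc.assign_cells(grid, raster)
    xs, ys = raster.pixel_centers()
    # spot-check a sample of pixels against exact polygon containment
    for _ in range(200):
        r = int(rng.integers(h))
        c = int(rng.integers(w))
        k = assignment[r, c]
        assert k >= 0
        assert grid.polygons[k].distance(Point(xs[c], ys[r])) < 1e-6


class TestLocalConnectivity:
    def single_cell_grid(self, raster):
        x0, y0, x1, y1 = raster.bounds
        with pytest.warns(UserWarning):
            return hc.tessellate((x0, y0, x1, y1), cell_area_ha=1e6)

    def test_cell_without_habitat_scores_zero(self):
        hab = Raster(np.zeros((10, 10), dtype=np.uint8), 50.0, (0.0, 500.0))
        pm = hc.label_patches(hab)
        grid = self.single_cell_grid(hab)
        kernel = hc.calibrate_kernel(0.1, 2_000.0)
        hc.local_connectivity(grid, pm, Raster(np.ones((10, 10)), 50.0, (0.0, 500.0)), kernel)
        assert grid.local_values["value"].iloc[0] == 0.0

    def test_single_patch_gives_attribute_squared(self):
        hab = np.zeros((10, 10), dtype=np.uint8)
        hab[4:6, 4:6] = 1
        suit = np.full((10, 10), 0.5)
        r = Raster(hab, 50.0, (0.0, 500.0))
        grid = self.single_cell_grid(r)
        hc.local_connectivity(grid, hc.label_patches(r),
                              Raster(suit, 50.0, (0.0, 500.0)),
                              hc.calibrate_kernel(0.1, 2_000.0))
        # 4 pixels at suitability 0.5 -> a = 2, numerator = a^2
        assert grid.local_values["value"].iloc[0] == pytest.approx(4.0)

    def test_two_patches_hand_enumeration(self):
        # a1=2 and a2=3 at 500 m; kernel anchored so p(500)=0.5
        hab = np.zeros((3, 16), dtype=np.uint8)
        hab[0, 0:2] = 1
        hab[0, 11:14] = 1  # nearest pixels 10 apart -> 500 m at 50 m/px
        suit = hab.astype(float)
        r = Raster(hab, 50.0, (0.0, 150.0))
        grid = self.single_cell_grid(r)
        hc.local_connectivity(grid, hc.label_patches(r),
                              Raster(suit, 50.0, (0.0, 150.0)),
                              hc.calibrate_kernel(0.5, 500.0))
        # 4 + 9 + 2 * (2 * 3 * 0.5) = 19
        assert grid.local_values["value"].iloc[0] == pytest.approx(19.0)

    def test_clipping_conserves_habitat_pixels(self, small_scenario):
        hab = hc.generate_habitat(small_scenario)
        pm = hc.label_patches(hab)
        grid = hc.tessellate(hab.bounds, cell_area_ha=300.0)
        hc.local_connectivity(grid, pm,
                              hc.generate_suitability(small_scenario, 0),
                              hc.calibrate_kernel(0.1, 2_000.0))
        total = sum(e["pixel_count"] for e in grid.fragment_cache.values())
        assert total == hab.data.sum()

    def test_single_cell_recovers_global_pc_numerator(self, small_scenario):
        hab = hc.generate_habitat(small_scenario)
        pm = hc.label_patches(hab)
        suit = hc.generate_suitability(small_scenario, 0)
        kernel = hc.calibrate_kernel(0.1, 2_000.0)
        grid = self.single_cell_grid(hab)
        hc.local_connectivity(grid, pm, suit, kernel)
        local = grid.local_values["value"].iloc[0]

        pm2 = hc.patch_attributes(pm, suit)
        dists = hc.interpatch_distances(pm2, cutoff=2 * grid.edge_length)
        g = hc.PatchGraph.from_distances(
            pm2.table["patch_id"].to_numpy(),
            pm2.table["attribute"].to_numpy(), dists, kernel)
        expected = hc.compute_pc(g).numerator
        assert local == pytest.approx(expected, rel=1e-9)

    def test_shape_mismatch_rejected(self, small_scenario):
        hab = hc.generate_habitat(small_scenario)
        pm = hc.label_patches(hab)
        grid = hc.tessellate(hab.bounds)
        bad = Raster(np.ones((3, 3)), 50.0)
        with pytest.raises(ValueError, match="resample"):
            hc.local_connectivity(grid, pm, bad,
                                  hc.calibrate_kernel(0.1, 2_000.0))


class TestRegionalScale:
    def test_single_cell_graph(self):
        grid = make_focal_grid([(0, 0)], {"current": [4.0]})
        g = hc.regional_graph(grid, "current")
        assert g.n_nodes == 1 and g.links.nnz == 0
        imp = hc.regional_importance(grid, "current")
        assert imp.iloc[0] == pytest.approx(100.0)

    def test_zero_habitat_cells_remain_as_nodes(self):
        grid = make_focal_grid([(0, 0), (1, 0)], {"current": [2.0, 0.0]})
        g = hc.regional_graph(grid, "current")
        assert g.n_nodes == 2
        assert g.attributes[1] == 0.0

    def test_adjacent_equal_cells_have_equal_importance(self):
        grid = make_focal_grid([(0, 0), (1, 0)], {"current": [3.0, 3.0]})
        imp = hc.regional_importance(grid, "current")
        assert imp.iloc[0] == pytest.approx(imp.iloc[1])

    def test_three_cell_row_middle_dominates(self):
        grid = make_focal_grid([(0, 0), (0, 1), (0, 2)],
                               {"current": [1.0, 1.0, 1.0]})
        imp = hc.regional_importance(grid, "current")
        assert imp.iloc[1] == pytest.approx(100 * 11 / 17)
        assert imp.iloc[0] == pytest.approx(100 * 8 / 17)
        assert imp.iloc[1] > imp.iloc[0]

    def test_importance_invariant_to_attribute_scaling(self):
        vals = np.array([1.0, 4.0, 2.5, 0.0, 7.0, 3.0, 1.5])
        axial = [(0, 0), (1, 0), (-1, 0), (0, 1), (0, -1), (1, -1), (-1, 1)]
        base = hc.regional_importance(
            make_focal_grid(axial, {"p": vals}), "p")
        scaled = hc.regional_importance(
            make_focal_grid(axial, {"p": vals * 137.5}), "p")
        np.testing.assert_allclose(base.to_numpy(), scaled.to_numpy(),
                                   rtol=1e-9, atol=1e-9)

    def test_missing_period_rejected(self, flower_grid):
        with pytest.raises(KeyError):
            hc.regional_graph(flower_grid, "2080")

    def test_all_zero_attributes_warn(self):
        grid = make_focal_grid([(0, 0), (1, 0)], {"p": [0.0, 0.0]})
        with pytest.warns(UserWarning):
            imp = hc.regional_importance(grid, "p")
        assert (imp == 0).all()


@pytest.fixture(scope="module")
def analyzed():
    sc = hc.SyntheticScenario(
        extent=(0.0, 0.0, 16_000.0, 14_000.0), resolution=50.0,
        habitat_fraction=0.3, aggregation=0.6, n_periods=1, seed=7)
    hab = hc.generate_habitat(sc)
    pm = hc.label_patches(hab)
    grid = hc.tessellate(hab.bounds, cell_area_ha=500.0)
    hc.local_connectivity(grid, pm, hc.generate_suitability(sc, 0),
                          hc.calibrate_kernel(0.1, 2_000.0))
    return grid


class TestSensitivity:
    def test_correlation_matrix_shape_and_diagonal(self, analyzed):
        res = hc.sensitivity_to_dispersal(analyzed, [1_000.0, 2_000.0, 3_000.0])
        corr = res["spearman"]
        assert corr.shape == (3, 3)
        np.testing.assert_allclose(np.diag(corr), 1.0)
        np.testing.assert_allclose(corr.to_numpy(), corr.to_numpy().T)
        assert np.isfinite(corr.to_numpy()).all()

    def test_repeated_distance_correlates_perfectly(self, analyzed):
        res = hc.sensitivity_to_dispersal(analyzed, [2_000.0, 2_000.0])
        assert res["spearman"].iloc[0, 1] == pytest.approx(1.0)

    def test_rankings_stable_across_distances(self, analyzed):
        res = hc.sensitivity_to_dispersal(analyzed, [1_000.0, 2_000.0, 3_000.0])
        off = res["spearman"].to_numpy()[np.triu_indices(3, 1)]
        assert (off > 0.8).all()

    def test_too_few_distances_rejected(self, analyzed):
        with pytest.raises(ValueError):
            hc.sensitivity_to_dispersal(analyzed, [2_000.0])

    def test_constant_ranks_flagged(self):
        # mutually adjacent triangle of identical cells: fully symmetric,
        # so every cell has the same importance at every distance
        grid = make_focal_grid([(0, 0), (1, 0), (0, 1)],
                               {"p": [1.0, 1.0, 1.0]})
        grid.fragment_cache = {
            int(c): {"pixel_count": 1.0,
                     "distances": pd.DataFrame(
                         {"id_i": [], "id_j": [], "distance_m": []}),
                     "attributes": pd.DataFrame({"p": [1.0]}, index=[1])}
            for c in grid.cells["cell_id"]
        }
        with pytest.warns(UserWarning, match="constant"):
            res = hc.sensitivity_to_dispersal(grid, [1_000.0, 2_000.0])
        assert np.isnan(res["spearman"].iloc[0, 1])

    def test_fewer_than_three_cells_undefined(self):
        grid = make_focal_grid([(0, 0), (1, 0)], {"p": [1.0, 2.0]})
        grid.fragment_cache = {
            int(c): {"pixel_count": 1.0,
                     "distances": pd.DataFrame(
                         {"id_i": [], "id_j": [], "distance_m": []}),
                     "attributes": pd.DataFrame({"p": [v]}, index=[1])}
            for c, v in zip(grid.cells["cell_id"], [1.0, 2.0])
        }
        with pytest.warns(UserWarning, match="fewer than 3"):
            res = hc.sensitivity_to_dispersal(grid, [1_000.0, 2_000.0])
        assert res["spearman"].isna().all().all()


def test_build_adjacency_pairs_are_unique():
    axial = [(q, r) for q in range(-2, 3) for r in range(-2, 3)]
    pairs = build_adjacency(axial)
    assert len(pairs) == len(set(pairs))
    assert all(i < j for i, j in pairs)


def test_focal_grid_geojson_export(tmp_path, flower_grid):
    path = flower_grid.to_geojson(tmp_path / "grid.geojson")
    import json
    doc = json.loads(path.read_text())
    assert doc["type"] == "FeatureCollection"
    assert len(doc["features"]) == 7
    assert doc["features"][0]["properties"]["local_current"] == 1.0
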