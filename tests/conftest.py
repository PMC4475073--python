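import numpy as np
import pandas as pd
import pytest

import hexconn as hc


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def small_scenario():
    """A quick-to-generate fragmented landscape with southward drift."""
    return hc.SyntheticScenario(
        extent=(0.0, 0.0, 16_000.0, 14_000.0),
        resolution=50.0,
        habitat_fraction=0.3,
        aggregation=0.6,
        n_periods=3,
        drift_vector=(0.0, -4_000.0),
        seed=7,
    )


@pytest.fixture
def toy_patch_graph():
    """3-node unit-attribute chain in binary mode, A_L = 3."""
    return hc.PatchGraph.from_links(
        [1, 2, 3], [1.0, 1.0, 1.0], [(1, 2), (2, 3)], mode="binary", area=3.0
    )


def make_focal_grid(axial, attrs_by_period, cell_area_ha=5_000.0):
    """Hand-built FocalGrid for regional-scale unit tests."""
    from hexconn.multiscale import build_adjacency, hexagon_edge_length, _hex_center, _hex_polygon

    s = hexagon_edge_length(cell_area_ha)
    qs = np.array([a[0] for a in axial])
    rs = np.array([a[1] for a in axial])
    cxs, cys = _hex_center(qs, rs, s, (0.0, 0.0))
    cells = pd.DataFrame({
        "cell_id": np.arange(1, len(axial) + 1),
        "q": qs, "r": rs, "cx": cxs, "cy": cys,
        "clipped": False,
    })
    polys = [_hex_polygon(cx, cy, s) for cx, cy in zip(cxs, cys)]
    grid = hc.FocalGrid(
        cells=cells, polygons=polys, edge_length=s,
        cell_area_ha=cell_area_ha,
        extent=(min(cxs) - 2 * s, min(cys) - 2 * s,
                max(cxs) + 2 * s, max(cys) + 2 * s),
        adjacency=build_adjacency(list(axial)),
    )
    grid.local_values = pd.DataFrame(
        attrs_by_period, index=pd.Index(cells["cell_id"], name="cell_id")
    )
    grid.cell_pixel_capacity = cell_area_ha * 10_000.0 / 50.0**2
    return grid


@pytest.fixture
def flower_grid():
    """Center hexagon plus its six edge-sharing neighbors."""
    axial = [(0, 0), (1, 0), (-1, 0), (0, 1), (0, -1), (1, -1), (-1, 1)]
    return make_focal_grid(axial, {"current": np.ones(7)})
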