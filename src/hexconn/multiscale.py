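"""Two-scale connectivity: hexagonal focal landscapes and regional graph.

The study area is tessellated into equal-area regular hexagons (default
5,000 ha), the *focal landscapes* (FL). The analysis then runs at two
scales:

* **local** — inside each FL, habitat patches clipped to the cell form
  a small probabilistic graph (negative-exponential kernel on
  edge-to-edge distances) and the cell's value is the *numerator* of
  the probability-of-connectivity index. The numerator rather than the
  normalized PC is kept because suitability weighting makes the maximum
  attainable attribute differ between cells, and the raw double sum
  preserves that difference.
* **regional** — the FLs themselves become nodes of a binary graph with
  the local PC numerator as node attribute. Only edge-sharing hexagons
  are linked: with ~4.4 km edges, non-adjacent cells lie beyond a short
  -range disperser's reach. Each cell's regional importance is dIIC,
  the percent drop in the integral index of connectivity when the cell
  is removed.

Cell geometry is cached after the local step, so re-running with a
different dispersal distance (sensitivity analysis) only re-evaluates
the kernel, not the raster work.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import spearmanr
from shapely.geometry import Polygon, box, mapping

from .graph import DispersalKernel, PatchGraph, calibrate_kernel, \
    max_product_path_probabilities, node_removal_importance
from .rasters import PatchMap, Raster, interpatch_distances, _structure

__all__ = [
    "FocalGrid",
    "build_adjacency",
    "tessellate",
    "assign_cells",
    "local_connectivity",
    "regional_graph",
    "regional_importance",
    "importance_table",
    "sensitivity_to_dispersal",
    "hexagon_edge_length",
]

_SQRT3 = math.sqrt(3.0)


def hexagon_edge_length(cell_area_ha: float) -> float:
    """Edge length (m) of a regular hexagon of the given area.

    A = (3*sqrt(3)/2) s^2  =>  s = sqrt(2A / (3*sqrt(3))).
    For 5,000 ha this gives ~4,387 m (often quoted rounded as 4.3 km).
    """
    if cell_area_ha <= 0:
        raise ValueError("cell_area_ha must be positive")
    return math.sqrt(2.0 * cell_area_ha * 10_000.0 / (3.0 * _SQRT3))


@dataclass
class FocalGrid:
    """Hexagonal focal-landscape tessellation with per-cell values.

    ``cells`` has one row per cell: cell_id, axial coordinates (q, r),
    center (cx, cy) and a ``clipped`` flag for cells not fully inside
    the extent. ``adjacency`` lists unordered pairs of *row positions*
    of edge-sharing cells. ``local_values`` (cell x period) is filled by
    :func:`local_connectivity`.
    """

    cells: pd.DataFrame
    polygons: list[Polygon]
    edge_length: float
    cell_area_ha: float
    extent: tuple[float, float, float, float]
    adjacency: list[tuple[int, int]]
    local_values: pd.DataFrame | None = None
    cell_pixel_capacity: float | None = None
    fragment_cache: dict = field(default_factory=dict, repr=False)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def neighbor_counts(self) -> pd.Series:
        deg = np.zeros(self.n_cells, dtype=int)
        for i, j in self.adjacency:
            deg[i] += 1
            deg[j] += 1
        return pd.Series(deg, index=self.cells["cell_id"], name="n_neighbors")

    def to_geojson(self, path: str | Path,
                   properties: pd.DataFrame | None = None,
                   metadata: dict | None = None) -> Path:
        """Write the cells as a GeoJSON FeatureCollection."""
        feats = []
        for k, poly in enumerate(self.polygons):
            props = {
                "cell_id": int(self.cells["cell_id"].iloc[k]),
                "clipped": bool(self.cells["clipped"].iloc[k]),
            }
            if self.local_values is not None:
                cid = self.cells["cell_id"].iloc[k]
                for col in self.local_values.columns:
                    props[f"local_{col}"] = float(self.local_values.loc[cid, col])
            if properties is not None:
                cid = self.cells["cell_id"].iloc[k]
                if cid in properties.index:
                    for col in properties.columns:
                        v = properties.loc[cid, col]
                        props[col] = None if pd.isna(v) else (
                            v if isinstance(v, str) else float(v))
            feats.append({"type": "Feature", "geometry": mapping(poly),
                          "properties": props})
        doc = {"type": "FeatureCollection", "features": feats}
        if metadata:
            doc["metadata"] = metadata
        path = Path(path)
        path.write_text(json.dumps(doc))
        return path


def _hex_center(q: np.ndarray, r: np.ndarray, s: float,
                anchor: tuple[float, float]) -> tuple[np.ndarray, np.ndarray]:
    ax, ay = anchor
    return ax + 1.5 * s * q, ay + _SQRT3 * s * (r + q / 2.0)


def _hex_polygon(cx: float, cy: float, s: float) -> Polygon:
    ang = np.deg2rad(np.arange(0, 360, 60))
    return Polygon(np.column_stack([cx + s * np.cos(ang), cy + s * np.sin(ang)]))


_AXIAL_NEIGHBORS = ((1, 0), (-1, 0), (0, 1), (0, -1), (1, -1), (-1, 1))


def build_adjacency(axial: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Unordered row-position pairs of edge-sharing hexagons.

    Two cells share an edge exactly when their axial coordinates differ
    by one of the six unit offsets.
    """
    by_axial = {qr: k for k, qr in enumerate(axial)}
    pairs = []
    for (q, r), k in by_axial.items():
        for dq, dr in _AXIAL_NEIGHBORS:
            other = by_axial.get((q + dq, r + dr))
            if other is not None and other > k:
                pairs.append((k, other))
    return pairs


def tessellate(extent: tuple[float, float, float, float],
               cell_area_ha: float = 5_000.0) -> FocalGrid:
    """Tile an extent with equal-area regular hexagons (flat-top rows).

    Every cell whose polygon overlaps the extent is kept; cells not
    fully contained are flagged ``clipped``. Interior cells have area
    exactly ``cell_area_ha`` and exactly six edge-sharing neighbors.
    """
    x0, y0, x1, y1 = extent
    if x1 <= x0 or y1 <= y0:
        raise ValueError("extent must have positive width and height")
    s = hexagon_edge_length(cell_area_ha)
    anchor = ((x0 + x1) / 2.0, (y0 + y1) / 2.0)  # cell (0,0) center

    # candidate axial range with one ring of margin
    qmax = int(math.ceil((x1 - x0) / 2 / (1.5 * s))) + 1
    rows = []
    for q in range(-qmax, qmax + 1):
        # r range so that cy spans the extent
        cy_lo, cy_hi = y0 - 2 * s, y1 + 2 * s
        r_lo = int(math.floor((cy_lo - anchor[1]) / (_SQRT3 * s) - q / 2.0)) - 1
        r_hi = int(math.ceil((cy_hi - anchor[1]) / (_SQRT3 * s) - q / 2.0)) + 1
        for r in range(r_lo, r_hi + 1):
            rows.append((q, r))
    qs = np.array([qr[0] for qr in rows])
    rs = np.array([qr[1] for qr in rows])
    cxs, cys = _hex_center(qs, rs, s, anchor)

    extent_box = box(x0, y0, x1, y1)
    cell_rows = []
    polys = []
    eps = 1e-9 * s * s
    for q, r, cx, cy in zip(qs, rs, cxs, cys):
        poly = _hex_polygon(cx, cy, s)
        inter = poly.intersection(extent_box)
        if inter.area <= eps:
            continue
        cell_rows.append(
            {"q": int(q), "r": int(r), "cx": float(cx), "cy": float(cy),
             "clipped": not extent_box.covers(poly)}
        )
        polys.append(poly)
    if not cell_rows:  # degenerate: extent tiny relative to a cell
        cell_rows.append({"q": 0, "r": 0, "cx": anchor[0], "cy": anchor[1],
                          "clipped": True})
        polys.append(_hex_polygon(anchor[0], anchor[1], s))
    cells = pd.DataFrame(cell_rows)
    cells.insert(0, "cell_id", np.arange(1, len(cells) + 1))
    if len(cells) == 1:
        warnings.warn("cell area exceeds the extent; returning a single "
                      "clipped focal landscape", stacklevel=2)

    adjacency = build_adjacency(
        [(int(q), int(r)) for q, r in zip(cells["q"], cells["r"])]
    )
    return FocalGrid(cells=cells, polygons=polys, edge_length=s,
                     cell_area_ha=cell_area_ha, extent=tuple(extent),
                     adjacency=adjacency)


def assign_cells(grid: FocalGrid, raster_like) -> np.ndarray:
    """Map every pixel of a raster to the row position of its hexagon.

    Returns an int array of the raster's shape with -1 where the pixel
    center falls outside every cell of the grid. Assignment is by exact
    axial-coordinate rounding, so it is consistent with the polygons and
    loses no pixels on cell boundaries.
    """
    s = grid.edge_length
    x0e, y0e, x1e, y1e = grid.extent
    anchor = ((x0e + x1e) / 2.0, (y0e + y1e) / 2.0)
    h, w = raster_like.labels.shape if isinstance(raster_like, PatchMap) \
        else raster_like.shape
    res = raster_like.resolution
    ox, oy = raster_like.origin
    xs = ox + (np.arange(w) + 0.5) * res - anchor[0]
    ys = oy - (np.arange(h) + 0.5) * res - anchor[1]
    xx, yy = np.meshgrid(xs, ys)
    qf = (2.0 / 3.0) * xx / s
    rf = (-xx / 3.0 + _SQRT3 / 3.0 * yy) / s
    # cube rounding (x=q, z=r, y=-q-r)
    xf, zf = qf, rf
    yf = -xf - zf
    rx, ry, rz = np.round(xf), np.round(yf), np.round(zf)
    dx, dy, dz = np.abs(rx - xf), np.abs(ry - yf), np.abs(rz - zf)
    fix_x = (dx > dy) & (dx > dz)
    fix_z = ~fix_x & (dz > dy)
    rx = np.where(fix_x, -ry - rz, rx)
    rz = np.where(fix_z, -rx - ry, rz)

    by_axial = {(int(q), int(r)): k
                for k, (q, r) in enumerate(zip(grid.cells["q"], grid.cells["r"]))}
    out = np.full((h, w), -1, dtype=np.int32)
    qi = rx.astype(np.int64)
    ri = rz.astype(np.int64)
    # encode axial pairs to look them up vectorized
    keys = qi * 100_000 + ri
    lut = {q * 100_000 + r: k for (q, r), k in by_axial.items()}
    uniq, inv = np.unique(keys, return_inverse=True)
    mapped = np.array([lut.get(int(u), -1) for u in uniq], dtype=np.int32)
    out = mapped[inv].reshape(h, w)
    return out


def local_connectivity(
    grid: FocalGrid,
    patches: PatchMap,
    suitability: Raster | dict[str, Raster],
    kernel: DispersalKernel,
) -> FocalGrid:
    """Per-cell local connectivity: the PC numerator of the clipped patches.

    Patches are cut by cell edges; each within-cell fragment is a local
    node whose attribute is the sum of suitability over its pixels.
    ``suitability`` may be a single raster or a mapping
    ``{period_label: raster}``; fragment geometry (and inter-fragment
    distances) is computed once and shared across periods. The grid is
    updated in place (``local_values``, ``fragment_cache``) and returned.
    """
    suits = suitability if isinstance(suitability, dict) else {"value": suitability}
    for lab, r in suits.items():
        if r.shape != patches.labels.shape:
            raise ValueError(
                f"suitability raster {lab!r} is not on the habitat grid "
                f"({r.shape} vs {patches.labels.shape}); resample it first"
            )
    periods = list(suits)
    cell_idx = assign_cells(grid, patches)
    habitat = patches.labels > 0
    struct = _structure(patches.connectivity)
    # all in-cell pairs are within the hexagon's diameter 2s
    cache_cutoff = 2.0 * grid.edge_length

    values = pd.DataFrame(
        0.0, index=pd.Index(grid.cells["cell_id"], name="cell_id"),
        columns=periods,
    )
    cache: dict[int, dict] = {}
    suit_arrays = {lab: np.asarray(r.data, dtype=float) for lab, r in suits.items()}

    for k in range(grid.n_cells):
        cid = int(grid.cells["cell_id"].iloc[k])
        in_cell = (cell_idx == k) & habitat
        if not in_cell.any():
            cache[cid] = {"pixel_count": 0, "distances": None, "attributes": None}
            continue
        rows = np.any(in_cell, axis=1).nonzero()[0]
        cols = np.any(in_cell, axis=0).nonzero()[0]
        sl = (slice(rows[0], rows[-1] + 1), slice(cols[0], cols[-1] + 1))
        sub = in_cell[sl]
        frag_labels, n_frag = ndimage.label(sub, structure=struct)
        idx = np.arange(1, n_frag + 1)
        counts = ndimage.sum_labels(np.ones_like(sub, dtype=float),
                                    frag_labels, index=idx)
        attrs = pd.DataFrame(
            {lab: ndimage.sum_labels(arr[sl], frag_labels, index=idx)
             for lab, arr in suit_arrays.items()},
            index=idx,
        )
        sub_map = PatchMap(
            labels=frag_labels,
            table=pd.DataFrame({"patch_id": idx, "pixel_count": counts}),
            resolution=patches.resolution,
            origin=patches.origin,
            connectivity=patches.connectivity,
        )
        dists = interpatch_distances(sub_map, cutoff=cache_cutoff)
        cache[cid] = {"pixel_count": float(counts.sum()),
                      "distances": dists, "attributes": attrs}

    grid.fragment_cache = cache
    grid.cell_pixel_capacity = grid.cell_area_ha * 10_000.0 / patches.resolution**2
    grid.local_values = _values_from_cache(grid, kernel, periods)
    return grid


def _values_from_cache(grid: FocalGrid, kernel: DispersalKernel,
                       periods: list[str]) -> pd.DataFrame:
    """PC numerators per cell/period from cached fragment geometry."""
    values = pd.DataFrame(
        0.0, index=pd.Index(grid.cells["cell_id"], name="cell_id"),
        columns=periods,
    )
    for cid, entry in grid.fragment_cache.items():
        attrs = entry["attributes"]
        if attrs is None or attrs.empty:
            continue
        n = len(attrs)
        g = PatchGraph.from_distances(
            node_ids=attrs.index.to_numpy(),
            attributes=np.zeros(n),
            distances=entry["distances"],
            kernel=kernel,
        )
        pstar = max_product_path_probabilities(g)
        for lab in periods:
            a = attrs[lab].to_numpy(dtype=float)
            values.loc[cid, lab] = float(a @ pstar @ a)
    return values


def regional_graph(grid: FocalGrid, period: str) -> PatchGraph:
    """Binary regional graph: FLs as nodes, edge-sharing cells linked.

    Node attributes are the local PC numerators for ``period``. The
    landscape ceiling A_L is the number of cells times the maximum
    attainable cell attribute (the cell's pixel count), which bounds
    IIC by 1; only the removal *ratio* dIIC is used downstream and is
    invariant to this normalization.
    """
    if grid.local_values is None:
        raise ValueError("run local_connectivity before building the regional graph")
    if period not in grid.local_values.columns:
        raise KeyError(f"period {period!r} has no local connectivity values")
    attrs = grid.local_values[period].to_numpy(dtype=float)
    node_ids = grid.cells["cell_id"].to_numpy()
    pairs = [(node_ids[i], node_ids[j]) for i, j in grid.adjacency]
    capacity = grid.cell_pixel_capacity or 1.0
    return PatchGraph.from_links(
        node_ids, attrs, pairs, mode="binary",
        area=grid.n_cells * capacity,
    )


def regional_importance(grid: FocalGrid, period: str) -> pd.Series:
    """dIIC (percent) of every focal landscape for one period."""
    g = regional_graph(grid, period)
    res = node_removal_importance(g, index="IIC")
    out = res.importance.copy()
    out.name = period
    out.index.name = "cell_id"
    return out


def importance_table(grid: FocalGrid, periods: list[str] | None = None
                     ) -> pd.DataFrame:
    """dIIC per cell for every period: one column per period."""
    if grid.local_values is None:
        raise ValueError("run local_connectivity first")
    periods = periods or list(grid.local_values.columns)
    return pd.concat([regional_importance(grid, p) for p in periods], axis=1)


def sensitivity_to_dispersal(
    grid: FocalGrid,
    distances: list[float],
    p0: float = 0.10,
    period: str | None = None,
) -> dict:
    """Re-run the two-scale analysis for several dispersal distances.

    For each anchor distance d0 (kernel re-anchored at probability
    ``p0``), the local PC numerators and the regional dIIC are
    recomputed from the cached fragment geometry. Returns the per-cell
    dIIC table (cells x distances) and the Spearman rank-correlation
    matrix across distances; a robust method should show correlations
    near 1, meaning the ranking of important cells is insensitive to
    the exact dispersal distance.
    """
    if len(distances) < 2:
        raise ValueError("at least two dispersal distances are required")
    if not grid.fragment_cache:
        raise ValueError("run local_connectivity first (fragment cache empty)")
    if period is None:
        period = list(grid.local_values.columns)[0]

    cols = {}
    saved_values = grid.local_values
    try:
        for d0 in distances:
            kernel = calibrate_kernel(p0, d0)
            grid.local_values = _values_from_cache(grid, kernel, [period])
            cols[d0] = regional_importance(grid, period)
    finally:
        grid.local_values = saved_values
    imp = pd.DataFrame(cols)
    imp.columns.name = "dispersal_distance_m"

    n = len(distances)
    corr = pd.DataFrame(np.eye(n), index=distances, columns=distances)
    if grid.n_cells < 3:
        warnings.warn("fewer than 3 cells: rank correlation undefined",
                      stacklevel=2)
        corr.loc[:, :] = np.nan
    else:
        for i, di in enumerate(distances):
            for j, dj in enumerate(distances):
                if j <= i:
                    continue
                xi, xj = imp[di].to_numpy(), imp[dj].to_numpy()
                if np.allclose(xi, xi[0]) or np.allclose(xj, xj[0]):
                    rho = np.nan  # constant ranks
                elif np.array_equal(xi, xj):
                    rho = 1.0
                else:
                    rho = spearmanr(xi, xj).statistic
                corr.iloc[i, j] = corr.iloc[j, i] = rho
        if corr.isna().any().any():
            warnings.warn("constant importance ranks for at least one "
                          "distance: correlation undefined there", stacklevel=2)
    return {"importance": imp, "spearman": corr, "period": period, "p0": p0}
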