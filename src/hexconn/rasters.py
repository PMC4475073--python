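"""Raster handling and the patch (node) layer of the landscape graph.

A landscape is represented by two single-band rasters on a projected,
metric grid: a binary habitat map (habitat / non-habitat) and a habitat
suitability surface in [0, 1], typically the output of a species
distribution model. Habitat pixels are grouped into patches (connected
components), each patch becomes a graph node, and its attribute is the
sum of suitability over the patch's pixels — so a large patch in a
highly suitable region carries a larger attribute than a small patch in
a marginal one.

GeoTIFF files are written with ModelPixelScale / ModelTiepoint tags plus
a JSON sidecar carrying the CRS string, so round trips preserve the full
georeferencing without requiring a GDAL stack.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage
from scipy.spatial import cKDTree

__all__ = [
    "Raster",
    "PatchMap",
    "label_patches",
    "resample_suitability",
    "patch_attributes",
    "interpatch_distances",
    "boundary_mask",
]

# GeoTIFF tag ids (GeoTIFF 1.1)
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922


@dataclass
class Raster:
    """A single-band raster on a square-pixel, projected (metric) grid.

    ``origin`` is the (x, y) coordinate of the *top-left corner* of the
    top-left pixel; rows increase southward (decreasing y), columns
    increase eastward. ``resolution`` is the pixel edge in meters.
    """

    data: np.ndarray
    resolution: float
    origin: tuple[float, float] = (0.0, 0.0)
    crs: str = "LOCAL_METRIC"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("raster data must be 2-D")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive (meters per pixel)")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(x_min, y_min, x_max, y_max) of the raster extent."""
        h, w = self.data.shape
        x0, y0 = self.origin
        return (x0, y0 - h * self.resolution, x0 + w * self.resolution, y0)

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """x (per column) and y (per row) coordinates of pixel centers."""
        h, w = self.data.shape
        x0, y0 = self.origin
        xs = x0 + (np.arange(w) + 0.5) * self.resolution
        ys = y0 - (np.arange(h) + 0.5) * self.resolution
        return xs, ys

    # ------------------------------------------------------------------ I/O

    def write(self, path: str | Path) -> Path:
        """Write a GeoTIFF plus a ``.aux.json`` sidecar with CRS metadata."""
        path = Path(path)
        res = float(self.resolution)
        x0, y0 = (float(v) for v in self.origin)
        extratags = [
            (_TAG_MODEL_PIXEL_SCALE, "d", 3, (res, res, 0.0)),
            (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, x0, y0, 0.0)),
        ]
        tifffile.imwrite(path, self.data, extratags=extratags)
        sidecar = {
            "resolution": res,
            "origin": [x0, y0],
            "crs": self.crs,
            "dtype": str(self.data.dtype),
        }
        path.with_suffix(path.suffix + ".aux.json").write_text(
            json.dumps(sidecar, indent=1)
        )
        return path

    @classmethod
    def read(cls, path: str | Path) -> "Raster":
        path = Path(path)
        data = tifffile.imread(path)
        sidecar_path = path.with_suffix(path.suffix + ".aux.json")
        if sidecar_path.exists():
            meta = json.loads(sidecar_path.read_text())
            return cls(
                data,
                resolution=meta["resolution"],
                origin=tuple(meta["origin"]),
                crs=meta.get("crs", "LOCAL_METRIC"),
            )
        # fall back to the embedded GeoTIFF tags
        with tifffile.TiffFile(path) as tif:
            tags = tif.pages[0].tags
            scale = tags[_TAG_MODEL_PIXEL_SCALE].value
            tie = tags[_TAG_MODEL_TIEPOINT].value
        return cls(data, resolution=float(scale[0]), origin=(tie[3], tie[4]))


@dataclass
class PatchMap:
    """Labeled habitat patches with per-patch summary attributes.

    ``labels`` assigns 0 to non-habitat pixels and 1..n_patches to
    habitat pixels. ``table`` has one row per patch: pixel_count,
    area_ha, and (once :func:`patch_attributes` has run) the
    suitability-weighted attribute a_i.
    """

    labels: np.ndarray
    table: pd.DataFrame
    resolution: float
    origin: tuple[float, float] = (0.0, 0.0)
    crs: str = "LOCAL_METRIC"
    connectivity: int = 8

    @property
    def n_patches(self) -> int:
        return int(self.table.shape[0])

    def write_table(self, path: str | Path) -> Path:
        path = Path(path)
        self.table.to_csv(path, index=False)
        return path


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 8:
        return np.ones((3, 3), dtype=bool)
    if connectivity == 4:
        return ndimage.generate_binary_structure(2, 1)
    raise ValueError("pixel connectivity must be 4 or 8")


def label_patches(habitat: Raster, connectivity: int = 8) -> PatchMap:
    """Group habitat pixels into patches (connected components).

    Diagonal forest pixels are treated as contiguous by default
    (8-connectivity); pass ``connectivity=4`` for rook adjacency.
    Raises if the raster is not strictly binary.
    """
    grid = np.asarray(habitat.data)
    values = np.unique(grid)
    if not np.all(np.isin(values, (0, 1))):
        raise ValueError("habitat raster must be binary (values 0/1 only)")
    labels, n = ndimage.label(grid, structure=_structure(connectivity))
    pixel_area_ha = habitat.resolution**2 / 10_000.0
    if n:
        counts = np.bincount(labels.ravel())[1:]
    else:
        counts = np.zeros(0, dtype=int)
    table = pd.DataFrame(
        {
            "patch_id": np.arange(1, n + 1, dtype=int),
            "pixel_count": counts.astype(int),
            "area_ha": counts * pixel_area_ha,
            "attribute": np.nan,
        }
    )
    return PatchMap(
        labels=labels,
        table=table,
        resolution=habitat.resolution,
        origin=habitat.origin,
        crs=habitat.crs,
        connectivity=connectivity,
    )


def resample_suitability(
    suit: Raster,
    target_resolution: float,
    method: str = "nearest",
    like: Raster | None = None,
) -> Raster:
    """Resample a suitability surface onto a new pixel size.

    Nearest-neighbor (default) preserves the original pixel values so
    that patch-attribute sums keep their semantics; ``method="bilinear"``
    interpolates. When ``like`` is given its grid geometry is used and
    the CRS of the two rasters must agree.
    """
    if like is not None:
        if like.crs != suit.crs:
            raise ValueError(
                f"CRS mismatch: suitability is {suit.crs!r}, target grid is {like.crs!r}"
            )
        target_resolution = like.resolution
        h, w = like.shape
        x0, y0 = like.origin
    else:
        if target_resolution <= 0:
            raise ValueError("target_resolution must be positive")
        x_min, y_min, x_max, y_max = suit.bounds
        x0, y0 = suit.origin
        w = int(round((x_max - x_min) / target_resolution))
        h = int(round((y_max - y_min) / target_resolution))
        if w < 1 or h < 1:
            raise ValueError("target resolution coarser than the raster extent")

    if target_resolution == suit.resolution and (x0, y0) == suit.origin and (
        like is None or like.shape == suit.shape
    ):
        return Raster(suit.data.copy(), suit.resolution, suit.origin, suit.crs)

    xs = x0 + (np.arange(w) + 0.5) * target_resolution
    ys = y0 - (np.arange(h) + 0.5) * target_resolution
    # fractional source pixel indices of the target pixel centers
    sx0, sy0 = suit.origin
    cols = (xs - sx0) / suit.resolution - 0.5
    rows = (sy0 - ys) / suit.resolution - 0.5
    cc, rr = np.meshgrid(cols, rows)
    order = {"nearest": 0, "bilinear": 1}.get(method)
    if order is None:
        raise ValueError("method must be 'nearest' or 'bilinear'")
    out = ndimage.map_coordinates(
        suit.data.astype(float), [rr, cc], order=order, mode="nearest"
    )
    return Raster(np.clip(out, 0.0, 1.0), target_resolution, (x0, y0), suit.crs)


def patch_attributes(patches: PatchMap, suit: Raster) -> PatchMap:
    """Attach the suitability-weighted attribute a_i to every patch.

    a_i is the sum of suitability values over the patch's pixels, so it
    grows with both patch area and habitat quality. The suitability
    raster must already be on the habitat grid (same shape/resolution).
    """
    if suit.shape != patches.labels.shape:
        raise ValueError(
            f"grid shape mismatch: patches {patches.labels.shape}, suitability {suit.shape}"
        )
    vals = np.asarray(suit.data, dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ValueError("suitability raster contains non-finite values")
    if vals.min() < 0 or vals.max() > 1:
        raise ValueError("suitability values must lie in [0, 1]")
    n = patches.n_patches
    if n:
        attrs = ndimage.sum_labels(vals, patches.labels, index=np.arange(1, n + 1))
    else:
        attrs = np.zeros(0)
    table = patches.table.copy()
    table["attribute"] = np.asarray(attrs, dtype=float)
    return PatchMap(
        labels=patches.labels,
        table=table,
        resolution=patches.resolution,
        origin=patches.origin,
        crs=patches.crs,
        connectivity=patches.connectivity,
    )


def boundary_mask(labels: np.ndarray) -> np.ndarray:
    """True at labeled pixels that touch a different label (or the grid edge)."""
    lab = np.asarray(labels)
    lo = ndimage.minimum_filter(lab, size=3, mode="constant", cval=0)
    hi = ndimage.maximum_filter(lab, size=3, mode="constant", cval=0)
    return (lab > 0) & ((lo != lab) | (hi != lab))


def _boundary_points_by_patch(
    labels: np.ndarray, resolution: float
) -> dict[int, np.ndarray]:
    mask = boundary_mask(labels)
    rows, cols = np.nonzero(mask)
    ids = labels[rows, cols]
    pts = np.column_stack([cols * resolution, rows * resolution]).astype(float)
    out: dict[int, np.ndarray] = {}
    order = np.argsort(ids, kind="stable")
    ids_s, pts_s = ids[order], pts[order]
    splits = np.searchsorted(ids_s, np.unique(ids_s))
    uniq = np.unique(ids_s)
    for k, pid in enumerate(uniq):
        stop = splits[k + 1] if k + 1 < len(splits) else len(ids_s)
        out[int(pid)] = pts_s[splits[k] : stop]
    return out


def interpatch_distances(patches: PatchMap, cutoff: float) -> pd.DataFrame:
    """Edge-to-edge distances between all patch pairs closer than ``cutoff``.

    The distance between two patches is the minimum Euclidean distance
    between the *centers* of their boundary pixels, in meters. Returns a
    symmetric edge list stored once per unordered pair (id_i < id_j);
    pairs farther apart than ``cutoff`` are omitted.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    empty = pd.DataFrame(
        {"id_i": pd.Series(dtype=int), "id_j": pd.Series(dtype=int),
         "distance_m": pd.Series(dtype=float)}
    )
    if patches.n_patches < 2:
        return empty

    pts = _boundary_points_by_patch(patches.labels, patches.resolution)
    ids = sorted(pts)
    boxes = {
        pid: (p[:, 0].min(), p[:, 1].min(), p[:, 0].max(), p[:, 1].max())
        for pid, p in pts.items()
    }
    trees = {pid: cKDTree(p) for pid, p in pts.items()}

    rec_i: list[int] = []
    rec_j: list[int] = []
    rec_d: list[float] = []
    for a_idx, pid_a in enumerate(ids):
        ax0, ay0, ax1, ay1 = boxes[pid_a]
        for pid_b in ids[a_idx + 1 :]:
            bx0, by0, bx1, by1 = boxes[pid_b]
            gap_x = max(bx0 - ax1, ax0 - bx1, 0.0)
            gap_y = max(by0 - ay1, ay0 - by1, 0.0)
            if np.hypot(gap_x, gap_y) > cutoff:
                continue
            # query the smaller point set against the larger tree
            if len(pts[pid_a]) <= len(pts[pid_b]):
                q, tree = pts[pid_a], trees[pid_b]
            else:
                q, tree = pts[pid_b], trees[pid_a]
            d, _ = tree.query(q, k=1, distance_upper_bound=cutoff * 1.0000001)
            dmin = float(np.min(d))
            if np.isfinite(dmin) and dmin <= cutoff:
                rec_i.append(pid_a)
                rec_j.append(pid_b)
                rec_d.append(dmin)
    if not rec_i:
        return empty
    return pd.DataFrame({"id_i": rec_i, "id_j": rec_j, "distance_m": rec_d})
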