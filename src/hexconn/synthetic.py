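"""Synthetic fragmented landscapes and drifting suitability surfaces.

Real inputs to the connectivity pipeline are a binary habitat map
(e.g. forest remnants) and one habitat-suitability raster per time
period from a species distribution model. This module fabricates both
with known, controllable structure so every downstream stage can be
exercised and tested without external data:

* the habitat map is a smoothed Gaussian random field thresholded at
  the quantile matching the requested habitat fraction — the smoothing
  length (set by ``aggregation``) controls fragmentation: more smoothing
  gives fewer, larger patches;
* each suitability surface is a broad anisotropic Gaussian bump plus a
  small fixed smooth-noise term, with the bump's peak translated by
  ``drift_vector`` once per period. A southward drift vector reproduces,
  at desk scale, the poleward/inland suitability shifts that climate
  projections produce for tropical pollinators.

Everything is driven by a single integer seed; identical scenarios give
bit-identical rasters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .rasters import Raster

__all__ = ["SyntheticScenario", "generate_habitat", "generate_suitability",
           "write_scenario", "demo_scenario"]


@dataclass(frozen=True)
class SyntheticScenario:
    """Recipe for one synthetic landscape and its suitability series.

    Parameters
    ----------
    extent
        (x_min, y_min, x_max, y_max) of the landscape in projected
        meters. Row 0 of the rasters is the northern (max-y) edge.
    resolution
        Pixel size in meters (default 50, the working resolution of the
        connectivity analysis).
    habitat_fraction
        Target proportion of habitat pixels, in [0, 1].
    aggregation
        Clumping of the habitat in [0, 1]: 0 gives salt-and-pepper
        fragments, 1 gives few large patches.
    n_periods
        Number of suitability surfaces (time periods).
    drift_vector
        (dx, dy) displacement in meters of the suitability peak per
        period; (0, -d) moves the peak southward.
    seed
        RNG seed; fixes both the habitat field and the noise term.
    peak_start
        Optional (x, y) of the period-0 suitability peak; defaults to
        the north-center of the extent so a southward drift traverses
        the landscape.
    peak_sigma
        (sx, sy) of the suitability bump in meters; defaults to 1/4 of
        the extent's width/height.
    noise_amplitude
        Amplitude of the smooth additive noise on the suitability
        surface (kept small so the bump dominates the argmax).
    """

    extent: tuple[float, float, float, float]
    resolution: float = 50.0
    habitat_fraction: float = 0.3
    aggregation: float = 0.5
    n_periods: int = 4
    drift_vector: tuple[float, float] = (0.0, 0.0)
    seed: int = 0
    peak_start: tuple[float, float] | None = None
    peak_sigma: tuple[float, float] | None = None
    noise_amplitude: float = 0.05

    def __post_init__(self) -> None:
        x0, y0, x1, y1 = self.extent
        if x1 <= x0 or y1 <= y0:
            raise ValueError("extent must have positive width and height")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if not 0 <= self.habitat_fraction <= 1:
            raise ValueError("habitat_fraction must lie in [0, 1]")
        if not 0 <= self.aggregation <= 1:
            raise ValueError("aggregation must lie in [0, 1]")
        if self.n_periods < 1:
            raise ValueError("n_periods must be at least 1")

    @property
    def shape(self) -> tuple[int, int]:
        x0, y0, x1, y1 = self.extent
        w = int(round((x1 - x0) / self.resolution))
        h = int(round((y1 - y0) / self.resolution))
        if w < 1 or h < 1:
            raise ValueError("extent smaller than one pixel")
        return h, w

    @property
    def origin(self) -> tuple[float, float]:
        x0, _, _, y1 = self.extent
        return (x0, y1)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticScenario":
        raw = json.loads(text)
        for key in ("extent", "drift_vector", "peak_start", "peak_sigma"):
            if raw.get(key) is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _grid_coords(scenario: SyntheticScenario) -> tuple[np.ndarray, np.ndarray]:
    h, w = scenario.shape
    x0, y1 = scenario.origin
    xs = x0 + (np.arange(w) + 0.5) * scenario.resolution
    ys = y1 - (np.arange(h) + 0.5) * scenario.resolution
    return xs, ys


def generate_habitat(scenario: SyntheticScenario) -> Raster:
    """Binary habitat raster from a thresholded smoothed random field."""
    h, w = scenario.shape
    frac = scenario.habitat_fraction
    if frac <= 0:
        grid = np.zeros((h, w), dtype=np.uint8)
    elif frac >= 1:
        grid = np.ones((h, w), dtype=np.uint8)
    else:
        rng = np.random.default_rng(scenario.seed)
        fld = rng.standard_normal((h, w))
        sigma = 0.6 + 12.0 * scenario.aggregation  # pixels
        fld = gaussian_filter(fld, sigma=sigma, mode="reflect")
        thr = np.quantile(fld, 1.0 - frac)
        grid = (fld > thr).astype(np.uint8)
    return Raster(grid, scenario.resolution, scenario.origin, crs="LOCAL_METRIC")


def _noise_surface(scenario: SyntheticScenario) -> np.ndarray:
    rng = np.random.default_rng((scenario.seed * 2654435761 + 97) % (2**31))
    raw = rng.standard_normal(scenario.shape)
    smooth = gaussian_filter(raw, sigma=8.0, mode="reflect")
    span = smooth.max() - smooth.min()
    if span == 0:
        return np.zeros_like(smooth)
    return (smooth - smooth.min()) / span  # in [0, 1]


def generate_suitability(scenario: SyntheticScenario, period: int) -> Raster:
    """Suitability surface for one period, peak shifted by the drift vector.

    The same noise realization is reused for every period so that the
    only change between periods is the translation of the bump.
    """
    if not 0 <= period < scenario.n_periods:
        raise ValueError(
            f"period {period} out of range [0, {scenario.n_periods})"
        )
    x0, y0, x1, y1 = scenario.extent
    px, py = scenario.peak_start or ((x0 + x1) / 2, y0 + 0.8 * (y1 - y0))
    dx, dy = scenario.drift_vector
    px, py = px + period * dx, py + period * dy
    sx, sy = scenario.peak_sigma or ((x1 - x0) / 4, (y1 - y0) / 4)

    xs, ys = _grid_coords(scenario)
    xx, yy = np.meshgrid(xs, ys)
    bump = np.exp(-(((xx - px) / sx) ** 2 + ((yy - py) / sy) ** 2) / 2.0)
    amp = scenario.noise_amplitude
    surf = (1.0 - amp) * bump + amp * _noise_surface(scenario)
    return Raster(
        np.clip(surf, 0.0, 1.0).astype(np.float32),
        scenario.resolution,
        scenario.origin,
        crs="LOCAL_METRIC",
    )


def write_scenario(scenario: SyntheticScenario, outdir: str | Path,
                   period_labels: list[str] | None = None) -> dict[str, Path]:
    """Write habitat + per-period suitability GeoTIFFs and a provenance JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    labels = period_labels or [f"period{p}" for p in range(scenario.n_periods)]
    if len(labels) != scenario.n_periods:
        raise ValueError("one period label per period is required")
    paths: dict[str, Path] = {}
    paths["habitat"] = generate_habitat(scenario).write(outdir / "habitat.tif")
    for p, lab in enumerate(labels):
        paths[lab] = generate_suitability(scenario, p).write(
            outdir / f"suitability_{lab}.tif"
        )
    scen_path = outdir / "scenario.json"
    scen_path.write_text(scenario.to_json())
    paths["scenario"] = scen_path
    return paths


def demo_scenario(seed: int = 0) -> SyntheticScenario:
    """The packaged demonstration scenario: a 54 x 47 km fragmented
    landscape whose suitability peak starts in the north and drifts
    ~12 km southward per period over four periods, emulating a poleward
    range shift at desk scale."""
    return SyntheticScenario(
        extent=(0.0, 0.0, 54_000.0, 47_000.0),
        resolution=50.0,
        habitat_fraction=0.25,
        aggregation=0.65,
        n_periods=4,
        drift_vector=(0.0, -12_000.0),
        seed=seed,
        noise_amplitude=0.05,
    )
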