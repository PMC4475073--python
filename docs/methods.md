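# Methods

## Overview

`hexconn` estimates how much each part of a fragmented landscape
contributes to a mobile species' ability to move and persist, now and
under projected climate change, and converts the temporal trend into
conservation/restoration strategy classes. The pipeline is:

binary habitat raster + per-period suitability rasters
→ patch labeling and suitability-weighted attributes
→ hexagonal focal landscapes, local PC numerator per cell and period
→ regional graph of cells, ΔIIC removal importance per period
→ temporal change ΔΔIIC → six strategy classes.

## Indices

Both indices sum over **ordered** node pairs and include the self-pairs
(`p*_ii = 1`, `nl_ii = 0`). This is required for the single-patch limit
`PC = a²/A_L²` to hold and matches the standard definitions of the
habitat-availability family: an isolated patch still provides
within-patch availability.

* `PC = Σᵢ Σⱼ a_i a_j p*_ij / A_L²`. The maximum product-path
  probabilities `p*` are computed with Dijkstra on weights `−ln p_ij`
  (zero-probability links dropped beforehand; ties between
  equal-probability paths are value-identical and need no tie-break).
* `IIC = Σᵢ Σⱼ a_i a_j / (1 + nl_ij) / A_L²` with `nl_ij` from an
  unweighted shortest-path search; pairs in different components
  contribute 0. The IIC is implemented from its standard published
  definition as the binary counterpart of PC.
* Link probabilities marginally above 1 (up to 1 + 1e−9, floating-point
  round-off from kernel evaluation) are clipped to 1; anything larger
  is rejected as a data error.

**Removal importance.** `ΔI_k = 100 (I − I₋ₖ)/I`, recomputed after
deleting node *k* while holding `A_L` fixed: the habitat loss is
simulated in the index, not in the study area, so `ΔI_k ∈ [0, 100]`
(tiny negative round-off is clamped to 0). If `I = 0` the importance is
undefined and reported as 0 with a warning.

## Dispersal kernel

`p(d) = exp(−k d)` with `k = −ln(p0)/d0`. Defaults `p0 = 0.10`,
`d0 = 2,000 m` describe a short-range forest pollinator (a stingless
bee's flight range); `p0 = 1` degenerates to a flat kernel (`k = 0`).
Pairwise distances are **edge-to-edge**: the minimum Euclidean distance
between boundary-pixel centers of the two patches. Edge-to-edge is the
common convention of connectivity software; centroid distances would
penalize large patches whose edges almost touch. Distance tables are
truncated at a cutoff — by default the distance where the kernel falls
below 1e−4 (8 km for the default anchor), beyond which contributions to
PC are numerically negligible.

## Patches and attributes

Patch labeling uses 8-connectivity by default (diagonal 50-m forest
pixels are functionally contiguous; 4-connectivity available).
Suitability is resampled to the habitat grid with nearest-neighbor by
default so that pixel values — and therefore attribute sums — are
preserved rather than invented; bilinear is available. The attribute
`a_i` is the plain sum of suitability over the patch's pixels, hence
dimensionless, bounded by the pixel count, and invariant to patch
relabeling and raster translation.

## Two-scale analysis

**Tessellation.** Flat-top regular hexagons of exactly `cell_area`
(default 5,000 ha), edge length `s = √(2A/(3√3))` ≈ 4,386.9 m for the
default — note this is ≈ 4.39 km, slightly above the commonly quoted
rounded value of 4.3 km. Cells overlapping the extent boundary are kept
but flagged `clipped`, so users can exclude them. Orientation is fixed
(flat-top rows) purely for reproducibility; the indices are independent
of it. Pixel-to-cell assignment uses exact axial-coordinate rounding,
which is consistent with the polygon geometry and loses no pixels at
cell borders (verified by a conservation test).

**Local scale.** Patches are cut at cell edges and every within-cell
fragment is a local node (the alternative — assigning whole patches to
the cell of their centroid — would let one cell's value depend on
habitat outside it). The stored per-cell value is the **PC numerator**,
not PC: suitability weighting makes the attainable attribute ceiling
differ between cells, and the unnormalized sum deliberately keeps that
difference. Fragment geometry and inter-fragment distances are computed
once per cell (with a cutoff of one cell diameter, which bounds every
in-cell pair) and cached; switching period or dispersal distance only
re-evaluates kernel weights and attribute vectors.

**Regional scale.** Cells become nodes of a binary graph with links
exactly between edge-sharing hexagons: the cell edge (≈ 4.4 km) already
exceeds the default dispersal anchor (2 km), so longer-range links
would carry negligible probability. The regional `A_L` is set to
(number of cells) × (cell pixel capacity), the maximum attainable total
attribute, which bounds IIC by 1. No published value constrains this
choice; only the ratio ΔIIC is used downstream, and a test proves ΔIIC
is invariant to uniform rescaling of all attributes (numerator and
denominator scale identically).

## Temporal change and classification

ΔΔIIC = ΔIIC(later) − ΔIIC(earlier), in percentage points, for each
consecutive period pair plus the overall first-to-last transition. The
classifier crosses two axes per transition:

* availability: the cell's local PC numerator in the **earlier** period
  of the transition, split at the median over all cells;
* change: ΔΔIIC, split at 0 and at the median of the **strictly
  positive** changes only (so the restoration split reflects genuine
  improvement, not the bulk of declining cells).

Decision table (Mₐ = median availability, M_d = median positive change):

| availability | change ≤ 0 | 0 < change < M_d | change ≥ M_d |
|---|---|---|---|
| ≥ Mₐ | II short-term conservation | III low-priority restoration / long-term conservation | IV long-term conservation |
| < Mₐ | I no action | V intermediate restoration | VI high-priority restoration |

Numerical conventions: ties at either median resolve upward (≥),
deterministic and biased toward action; a change of exactly 0 counts as
a decrease; medians are recomputed per transition, not pooled. If no
cell improves, M_d is undefined — a warning is raised and all cells
fall into the change ≤ 0 column, which is the only consistent outcome.
These choices make the classification a true partition (every cell gets
exactly one class), monotone in the change axis, and invariant to
positive rescaling of the availability axis; all three properties are
property-tested.

## Synthetic landscapes

The generator emulates the two inputs a real study would supply:

* **Habitat**: a Gaussian random field smoothed with σ = 0.6 + 12 ·
  aggregation pixels and thresholded at the quantile matching the
  requested habitat fraction. This gives seedable, tunable
  fragmentation: realized fraction is within 2 percentage points of the
  request on grids ≥ 256², and higher aggregation produces fewer,
  larger patches.
* **Suitability**: a broad anisotropic Gaussian bump (σ = extent/4 in
  each axis) plus 5 % smooth noise held fixed across periods, the peak
  translated by `drift_vector` once per period. A southward drift
  reproduces, at desk scale, the poleward/coast-to-inland range shifts
  that climate projections produce for tropical forest pollinators.

The packaged demo covers 54 × 47 km at 50 m resolution (1080 × 940
pixels, 67 focal landscapes of 5,000 ha, four periods, 12 km southward
drift per period) — sized so the complete pipeline runs in seconds on
one core while still containing dozens of cells and hundreds of
patches. What the generator does **not** emulate: the spatial
autocorrelation structure of real species-distribution-model output,
correlated habitat/suitability patterns (real forest remnants survive
preferentially where conditions are good), land-use change over time,
and real coastline/biome geometry. Passing tests therefore demonstrate
the correctness and qualitative behavior of the method, not a
biological prediction for any real landscape.

## Degenerate inputs and edge cases

* habitat fraction 0 or 1 → empty raster (zero patches) or a single
  landscape-spanning patch;
* a cell with no habitat keeps its node with value 0 at both scales;
* single-node graphs: PC = a²/A_L², removal importance 100 %;
* an extent smaller than one cell yields a single clipped cell with a
  warning;
* fewer than three cells, or constant importance ranks, make the
  sensitivity rank correlation undefined; it is reported as NaN with a
  warning rather than silently dropped.

## Limitations

Distances are Euclidean only — no resistance surfaces or cost paths.
Regional links are adjacency-only by design; a species with dispersal
comparable to the cell size would need probabilistic regional links,
which are out of scope. The dPC flux/connector decomposition and
link-addition (restoration placement within a cell) analyses are not
implemented. Vector (polygon) habitat input is not supported; rasterize
first.
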