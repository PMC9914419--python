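# Methods

## Model

The package scores ecological risk per square assessment cell from the
structure of the land-cover mosaic inside it. Risk for cell *k* is the
area-weighted sum over the six land-cover classes of a disturbance index
times a vulnerability index:

    LERI_k = Σ_i E_ki · F_ki · (A_ki / A_k).

Disturbance `E = 0.5·C + 0.3·S + 0.2·D` aggregates fragmentation
(`C = n/A`, patches per km²), separation (`S = A_k/(2A_ki)·√(n/A_k)`) and
dominance (`D = (Q + M)/4 + L/2`). The weights express the usual judgement
that fragmentation is the primary human-disturbance signal, separation
secondary and dominance a correction; they are exposed as a parameter and
validated to be non-negative and to sum to 1.

Vulnerability `F_ki = EV_i · MN_k` starts from an empirical class ranking
(unused 6, water 5, cropland 4, grassland 3, woodland 2, urban 1 — higher =
less able to absorb disturbance) and scales it by a per-cell composite factor
`MN_k = EQ_k / mean(EQ)` built from eight standardized indicators. `MN` has
grid mean 1 by construction, so it redistributes vulnerability across space
without inflating the regional average; because it is recomputed at every
time point, vulnerability responds to socio-environmental change instead of
being a constant class lookup. That dynamic adjustment is the methodological
point of the package.

### Assumptions

* The six-class legend is exhaustive inside the boundary; a reserved code
  (0 for categorical, −9999 for continuous rasters) marks outside pixels and
  is excluded from every sum.
* Patches are delineated independently within each cell window, so a patch
  straddling a cell edge counts in both cells. This matches the strictly
  per-plot definition of the index and keeps cells independent.
* All areas are km². `C` and `S` are scale-dependent (switching to m²
  rescales them by 1e−6 and 1e−3 respectively); the pipeline pins km²
  throughout and a test documents the rescaling factors.

## Parameters

| parameter | default | units | notes |
|---|---|---|---|
| cell size | 20 | km | assessment unit edge; ~2–5× the pixel size of typical land-cover products |
| disturbance weights a, b, c | 0.5, 0.3, 0.2 | — | must sum to 1 |
| EV per class | 6/5/4/3/2/1 | — | unused/water/cropland/grassland/woodland/urban |
| weight mode | entropy | — | `fixed` uses the published set (0.2421, 0.1467, 0.1482, 0.0985, 0.0892, 0.0647, 0.1023, 0.1083; sums to 1.0000 exactly) |
| connectivity | 8 | — | patch adjacency; 4 available; 8 matches common landscape-pattern software |
| classification breaks | 0.60 / 1.18 / 1.72 / 2.40 | LERI | five levels; `jenks` mode recomputes from pooled panel values |
| key-area quantile | 0.15 | — | top-15% threshold on LERI / RRC / CV |
| sliver threshold | 0.01 | fraction of a full cell | clipped cells smaller than this are dropped |

## Numerical and convention choices

* **Grid anchor**: the fishnet snaps to the lower-left corner of the boundary
  envelope (configurable offset); cell ids are row-major from that origin and
  reproducible. A pixel belongs to the cell containing its center (half-open
  intervals, left/bottom inclusive).
* **Two cell areas**: the polygon-clipped area A_k (used for the boundary
  conservation check, Σ A_k ≈ boundary area) and the pixel-counted area
  Σ_i A_ki differ by rasterisation. LERI uses the pixel-based area so the
  composition weights partition exactly.
* **Absent-class convention**: a class with no pixels in a cell has
  n = A = C = S = D = E = 0; it cannot contribute to LERI because its area
  weight is 0.
* **Dominance grouping**: `D = (Q + M)/4 + L/2`, with `Q` a fraction of cells
  (not a raw count). This keeps `D ∈ [0, 1]` and `D = 1` exactly when a class
  is the sole occupant of every cell. Both readings are isolated in one
  function each, so an alternative grouping can be swapped in.
* **Separation leading factor**: `A_k / (2·A_ki)`; the alternative `A_k/A_ki²`
  reading would make `S` unit-inconsistent across cell sizes.
* **Standardisation**: min–max per indicator, the entropy-weight literature
  default; negatively oriented indicators (precipitation, NPP, NDVI — more
  water/productivity/greenness means less vulnerable) use `(max−x)/(max−min)`.
  Orientations are configuration, not hard-coded. A constant column is mapped
  to 0.5 with a warning (it carries no ranking information); an all-zero
  standardized column makes entropy weights undefined and is rejected.
* **Entropy weights**: natural logarithm, K = number of cells, `0·ln 0 = 0`.
  If every indicator has zero divergence the weights degenerate; the package
  falls back to equal weights with a warning.
* **Classification boundaries**: left-closed intervals from the second class;
  the top class is closed below at the last break (LERI ≥ 2.40 → high), which
  resolves the boundary value the printed bins leave unassigned.
* **Jenks natural breaks**: Fisher's optimal 1-D partition by O(k·n²) dynamic
  programming on prefix sums; interior breaks are reported as the minimum of
  each class from the second onward so the classifier's left-closed convention
  reproduces the optimal assignment exactly. Verified against an exhaustive
  partition search for n ≤ 20, k ≤ 4.
* **CV convention**: sample standard deviation (ddof = 1). RRC over
  sub-periods uses that window's endpoints with its own ΔT; the full-period
  RRC uses the first and last years.
* **Key-area threshold**: the (1−q)-quantile by linear interpolation; a cell
  is flagged when strictly greater. With all-distinct values this flags
  exactly ⌊qN⌋ cells; ties at the threshold are excluded with a warning
  rather than arbitrarily broken. "Remained high for the duration" is
  operationalized as top-quantile membership in every period, not on the mean.
  Rankings are global over the whole grid and, for RRC, over the full period.
* **Transfer matrices** count only pixels valid at both dates
  (common-footprint rule), making row/column/grand-total conservation exact
  and `T(m2, m1) = T(m1, m2)ᵀ` an identity.
* **Regional summaries** assign a cell to the region containing its centroid
  and report unweighted cell means (an area-weighted option would weight by
  A_k; unweighted is the default reporting convention here).

## Synthetic data

The generator exists so that every downstream stage is testable without
external downloads; its defaults are the study conditions used by the test
suite and the acceptance script.

* **Land cover** — modified random clusters: mark pixels i.i.d. with
  probability `0.5·clumping`, percolation-label the marks (4-neighbour),
  assign each cluster a class with probability proportional to the class's
  remaining area deficit, then fill the rest i.i.d. from the residual
  deficits. The deficit-balanced assignment keeps realized proportions within
  ~2 percentage points of the request at every clumping level, and patch
  counts fall monotonically as clumping rises (verified over 20 seeds).
  Defaults: proportions (0.30, 0.15, 0.30, 0.05, 0.10, 0.10) for cropland,
  woodland, grassland, water, urban, unused — a cropland/grassland-dominated
  mosaic; clumping 0.5.
* **Indicators** — white noise smoothed by a Gaussian kernel whose σ is the
  correlation length (default 10 km) in pixels, then shifted/scaled to
  plausible magnitudes per indicator (affine, hence irrelevant after min–max
  standardisation).
* **Change process** — at each step a fraction (default 0.3) of the cropland
  pixels 4-adjacent to urban land converts to urban, chosen uniformly at
  random: monotone urban growth fed by cropland, the dominant conversion mode
  in rapidly urbanising regions. A map with no urban nucleus stays unchanged.

What the generator does **not** emulate: real geography (mountain ranges,
river networks, administrative structure), multi-class transition dynamics,
indicator–land-cover correlation, or measurement/classification error in the
source maps. Passing tests therefore demonstrate the correctness and the
qualitative behaviour of the indices, not calibrated risk levels for any real
region.

## Problem sizes

The test suite and the acceptance script use a five-period, 500-cell study
(500 × 400 km at 1 km resolution, 20 km cells) for end-to-end checks and
smaller grids (9–100 cells) for unit-level checks; both run in seconds.
Oracle equivalences run on ≥200 random windows (patch counts), 50 random toy
cells (LERI) and exhaustive partitions up to n = 20 (Jenks).

## Limitations

* Assessment units are square fishnet cells only; no hexagons, watersheds or
  multi-resolution units.
* No additional pattern-metric families (edge density, contagion, …) and no
  spatial-autocorrelation statistics.
* Raster I/O is plain-text ASCII grid, suitable for the moderate raster sizes
  of grid-based assessments; vector outputs are CSV tables keyed by cell id.
* The 15% key-area threshold is a plain parameter; no scenario optimisation
  over thresholds is attempted.
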