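"""Synthetic landscapes: neutral land-cover maps, indicator fields, urban growth.

The land-cover generator follows the modified-random-clusters family of
neutral landscape models: a Bernoulli field is percolation-labelled into
clusters, clusters are assigned land-cover classes with probabilities
proportional to each class's remaining area deficit (so realized proportions
track the requested ones at any clumping), and the remaining pixels are
filled i.i.d. from the residual deficits. A single ``clumping`` knob in
[0, 1] scales the Bernoulli marking probability and hence patch size:
clumping 0 degenerates to i.i.d. per-pixel sampling (maximal fragmentation)
and patch counts fall monotonically as clumping rises toward 1.

Indicator surfaces are Gaussian random fields (white noise smoothed with a
Gaussian kernel whose width is the requested correlation length), shifted
and scaled to plausible magnitudes per indicator.

Urban growth converts a fixed fraction of the cropland pixels 4-adjacent to
existing urban land at each step, emulating frontier urbanisation where
cropland conversion is the dominant change mode.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy import ndimage
from shapely import contains_xy as _shp_contains_xy
from shapely.geometry.base import BaseGeometry
from skimage.measure import label as _sklabel

from .raster import CLASS_CODES, NODATA_FLOAT, NODATA_INT, Raster

#: The eight vulnerability indicators, in canonical order.
INDICATOR_NAMES: tuple[str, ...] = (
    "gdp",
    "population",
    "elevation",
    "slope",
    "temperature",
    "precipitation",
    "npp",
    "ndvi",
)

# Plausible (offset, scale) per indicator so synthetic fields have realistic
# magnitudes; downstream min-max standardisation is affine-invariant, so these
# affect presentation only.
_INDICATOR_AFFINE: dict[str, tuple[float, float]] = {
    "gdp": (500.0, 400.0),          # 1e4 yuan / km²
    "population": (200.0, 150.0),   # persons / km²
    "elevation": (2000.0, 1200.0),  # m
    "slope": (8.0, 5.0),            # %
    "temperature": (8.0, 6.0),      # °C
    "precipitation": (450.0, 250.0),  # mm
    "npp": (350.0, 150.0),          # g C / m²
    "ndvi": (0.5, 0.25),            # unitless
}

# Marking probability at clumping = 1; kept below the site-percolation
# threshold (~0.593 on a square lattice, 4-neighbourhood) so clusters stay
# large but finite and class proportions remain controllable.
_P_MAX = 0.50


@dataclass
class SynthConfig:
    """Parameters of the synthetic study."""

    seed: int = 0
    #: Target area share per class, ordered as CLASS_CODES
    #: (cropland, woodland, grassland, water, urban, unused).
    proportions: tuple[float, ...] = (0.30, 0.15, 0.30, 0.05, 0.10, 0.10)
    clumping: float = 0.5
    correlation_length: float = 10.0  # km
    urban_rate: float = 0.3  # fraction of the cropland frontier converted per step
    n_steps: int = 4

    def validate(self) -> None:
        p = np.asarray(self.proportions, dtype=float)
        if p.size != len(CLASS_CODES):
            raise ValueError(f"need {len(CLASS_CODES)} class proportions, got {p.size}")
        if (p < 0).any():
            raise ValueError("class proportions must be non-negative")
        if not np.isclose(p.sum(), 1.0, atol=1e-8):
            raise ValueError(f"class proportions must sum to 1, got {p.sum()}")
        if not 0.0 <= self.clumping <= 1.0:
            raise ValueError("clumping must be in [0, 1]")
        if self.correlation_length <= 0:
            raise ValueError("correlation length must be positive")
        if not 0.0 <= self.urban_rate <= 1.0:
            raise ValueError("urbanization rate must be in [0, 1]")


def _grid_shape(extent: tuple[float, float, float, float], resolution: float) -> tuple[int, int]:
    xmin, ymin, xmax, ymax = extent
    nx = (xmax - xmin) / resolution
    ny = (ymax - ymin) / resolution
    if not (np.isclose(nx, round(nx)) and np.isclose(ny, round(ny))):
        raise ValueError("resolution must evenly divide the extent")
    return int(round(ny)), int(round(nx))


def _boundary_mask(raster: Raster, boundary: BaseGeometry | None) -> np.ndarray:
    if boundary is None:
        return np.ones(raster.shape, dtype=bool)
    xs, ys = raster.pixel_centers()
    return _shp_contains_xy(boundary, xs, ys)


def generate_landcover(
    config: SynthConfig,
    extent: tuple[float, float, float, float],
    resolution: float,
    boundary: BaseGeometry | None = None,
) -> Raster:
    """Generate one categorical land-cover map.

    Parameters
    ----------
    config : SynthConfig
        Class proportions, clumping and seed.
    extent : (xmin, ymin, xmax, ymax)
        Map extent in km; must be an integer number of pixels.
    resolution : float
        Pixel edge length in km.
    boundary : shapely geometry, optional
        Pixels whose centers fall outside are set to the nodata code.
    """
    config.validate()
    shape = _grid_shape(extent, resolution)
    rng = np.random.default_rng(config.seed)
    props = np.asarray(config.proportions, dtype=float)
    codes = np.asarray(CLASS_CODES)

    p_mark = _P_MAX * config.clumping
    marked = rng.random(shape) < p_mark
    out = np.zeros(shape, dtype=np.int16)
    if marked.any():
        labels = _sklabel(marked, connectivity=1)
        n_clusters = int(labels.max())
        sizes = np.bincount(labels[marked])[1:]
        # assign clusters to classes in random order, sampling each class with
        # probability proportional to its remaining area deficit so realized
        # proportions track the targets at every clumping level
        deficit = props * marked.size
        cluster_class = np.zeros(n_clusters, dtype=np.int16)
        for j in rng.permutation(n_clusters):
            w = np.clip(deficit, 0.0, None)
            w = w / w.sum() if w.sum() > 0 else props
            c = rng.choice(len(codes), p=w)
            cluster_class[j] = codes[c]
            deficit[c] -= sizes[j]
        out[marked] = cluster_class[labels[marked] - 1]
    unassigned = out == 0
    if unassigned.any():
        # i.i.d. fill of the remaining pixels, weighted by what each class
        # still needs; with clumping 0 this is plain i.i.d. sampling
        assigned_per_class = np.array([(out == c).sum() for c in codes])
        remaining = np.clip(props * out.size - assigned_per_class, 0.0, None)
        w = remaining / remaining.sum() if remaining.sum() > 0 else props
        out[unassigned] = rng.choice(codes, size=int(unassigned.sum()), p=w)

    raster = Raster(out, origin=extent[:2], pixel_size=resolution, nodata=NODATA_INT)
    mask = _boundary_mask(raster, boundary)
    raster.data[~mask] = NODATA_INT
    return raster


def generate_indicators(
    config: SynthConfig,
    extent: tuple[float, float, float, float],
    resolution: float,
    boundary: BaseGeometry | None = None,
) -> list[Raster]:
    """Generate the eight indicator surfaces as smoothed Gaussian fields."""
    config.validate()
    shape = _grid_shape(extent, resolution)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    sigma = config.correlation_length / resolution
    surfaces = []
    for name in INDICATOR_NAMES:
        noise = rng.standard_normal(shape)
        smooth = ndimage.gaussian_filter(noise, sigma=sigma, mode="reflect")
        offset, scale = _INDICATOR_AFFINE[name]
        values = offset + scale * smooth
        r = Raster(
            values.astype(float),
            origin=extent[:2],
            pixel_size=resolution,
            nodata=NODATA_FLOAT,
            name=name,
        )
        mask = _boundary_mask(r, boundary)
        r.data[~mask] = NODATA_FLOAT
        surfaces.append(r)
    return surfaces


_FOUR_NEIGHBORS = ndimage.generate_binary_structure(2, 1)

CROPLAND, URBAN = 1, 5


def evolve_landcover(lc: Raster, config: SynthConfig, steps: int) -> list[Raster]:
    """Simulate frontier urbanisation for ``steps`` steps.

    At each step a fraction ``config.urban_rate`` of the cropland pixels
    4-adjacent to urban land converts to urban. A map with no urban pixels
    has no conversion nucleus and is returned unchanged. Urban area is
    non-decreasing along the returned sequence.

    Returns the list of maps *after* each step (length ``steps``).
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
    current = lc.data.copy()
    out: list[Raster] = []
    for _ in range(steps):
        if config.urban_rate > 0:
            urban = current == URBAN
            frontier = (current == CROPLAND) & ndimage.binary_dilation(
                urban, structure=_FOUR_NEIGHBORS
            )
            idx = np.flatnonzero(frontier)
            n_convert = int(round(config.urban_rate * idx.size))
            if n_convert > 0:
                chosen = rng.choice(idx, size=n_convert, replace=False)
                current = current.copy()
                current.flat[chosen] = URBAN
        out.append(Raster(current.copy(), origin=lc.origin, pixel_size=lc.pixel_size, nodata=lc.nodata))
    return out


def write_config_yaml(config: SynthConfig, path: str | Path) -> Path:
    """Record the generator configuration next to its outputs."""
    path = Path(path)
    payload = {
        "seed": int(config.seed),
        "proportions": [float(p) for p in config.proportions],
        "clumping": float(config.clumping),
        "correlation_length_km": float(config.correlation_length),
        "urban_rate": float(config.urban_rate),
        "n_steps": int(config.n_steps),
    }
    path.write_text(yaml.safe_dump(payload, sort_keys=False))
    return path
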