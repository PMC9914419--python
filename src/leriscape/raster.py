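"""Lightweight raster container and plain-text (ESRI ASCII grid) I/O.

A :class:`Raster` couples a 2-D numpy array with a georeferencing registry:
the lower-left corner of the grid and a square pixel size. Row 0 of the
array is the *top* row of the map, matching the usual raster convention.
All distances are kilometres, so pixel area is ``pixel_size ** 2`` km².
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

#: Six-category land-cover legend used throughout the toolkit.
CLASS_CODES: tuple[int, ...] = (1, 2, 3, 4, 5, 6)
CLASS_NAMES: dict[int, str] = {
    1: "cropland",
    2: "woodland",
    3: "grassland",
    4: "water",
    5: "urban",
    6: "unused",
}
NAME_TO_CODE: dict[str, int] = {v: k for k, v in CLASS_NAMES.items()}

#: Reserved code for out-of-boundary pixels in categorical rasters.
NODATA_INT = 0
#: Nodata sentinel for continuous rasters.
NODATA_FLOAT = -9999.0


@dataclass
class Raster:
    """2-D grid of values with a spatial registry.

    Parameters
    ----------
    data : ndarray, shape (nrows, ncols)
        Pixel values; row 0 is the northernmost row.
    origin : (float, float)
        (x, y) of the lower-left corner, in km.
    pixel_size : float
        Edge length of a (square) pixel, in km.
    nodata : int or float
        Sentinel marking pixels outside the study boundary.
    """

    data: np.ndarray
    origin: tuple[float, float] = (0.0, 0.0)
    pixel_size: float = 1.0
    nodata: float = NODATA_INT
    name: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("raster data must be 2-D")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def pixel_area(self) -> float:
        """Area of one pixel, km²."""
        return self.pixel_size**2

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) in km."""
        nrows, ncols = self.data.shape
        x0, y0 = self.origin
        return (x0, y0, x0 + ncols * self.pixel_size, y0 + nrows * self.pixel_size)

    @property
    def valid_mask(self) -> np.ndarray:
        """Boolean mask of in-boundary pixels."""
        if np.issubdtype(self.data.dtype, np.floating):
            return (self.data != self.nodata) & np.isfinite(self.data)
        return self.data != self.nodata

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinates of every pixel center, each shaped like ``data``."""
        nrows, ncols = self.data.shape
        x0, y0 = self.origin
        xs = x0 + (np.arange(ncols) + 0.5) * self.pixel_size
        ys = y0 + (nrows - np.arange(nrows) - 0.5) * self.pixel_size  # row 0 on top
        return np.meshgrid(xs, ys)

    def same_registry(self, other: "Raster", rtol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.pixel_size, other.pixel_size, rtol=rtol)
            and np.allclose(self.origin, other.origin, rtol=rtol, atol=1e-9)
        )

    def registry_diff(self, other: "Raster") -> str:
        return (
            f"shape {self.shape} vs {other.shape}; "
            f"pixel {self.pixel_size} vs {other.pixel_size}; "
            f"origin {self.origin} vs {other.origin}"
        )


def require_same_registry(a: Raster, b: Raster) -> None:
    if not a.same_registry(b):
        raise ValueError(f"rasters are misregistered: {a.registry_diff(b)}")


def write_ascii_grid(raster: Raster, path: str | Path) -> Path:
    """Write a raster as an ESRI ASCII grid (plain text)."""
    path = Path(path)
    nrows, ncols = raster.shape
    x0, y0 = raster.origin
    is_int = np.issubdtype(raster.data.dtype, np.integer)
    header = (
        f"ncols {ncols}\n"
        f"nrows {nrows}\n"
        f"xllcorner {x0:.6f}\n"
        f"yllcorner {y0:.6f}\n"
        f"cellsize {raster.pixel_size:.6f}\n"
        f"NODATA_value {int(raster.nodata) if is_int else raster.nodata}\n"
    )
    fmt = "%d" if is_int else "%.6f"
    with path.open("w") as fh:
        fh.write(header)
        np.savetxt(fh, raster.data, fmt=fmt)
    return path


def read_ascii_grid(path: str | Path, dtype=None, name: str = "") -> Raster:
    """Read an ESRI ASCII grid written by :func:`write_ascii_grid`."""
    path = Path(path)
    meta: dict[str, float] = {}
    with path.open() as fh:
        for _ in range(6):
            key, value = fh.readline().split()
            meta[key.lower()] = float(value)
        data = np.loadtxt(fh, dtype=dtype if dtype is not None else float)
    data = np.atleast_2d(data)
    if data.shape != (int(meta["nrows"]), int(meta["ncols"])):
        raise ValueError(f"grid shape mismatch in {path}")
    nodata = meta["nodata_value"]
    if dtype is not None and np.issubdtype(np.dtype(dtype), np.integer):
        nodata = int(nodata)
    return Raster(
        data,
        origin=(meta["xllcorner"], meta["yllcorner"]),
        pixel_size=meta["cellsize"],
        nodata=nodata,
        name=name or path.stem,
    )
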