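"""Square assessment grid (fishnet) over a study boundary, plus zonal statistics.

The assessment units are the cells of a square grid anchored at the lower-left
corner of the boundary envelope (configurable offset), clipped to the boundary.
A raster pixel belongs to the cell containing its center (half-open cell
intervals, left/bottom inclusive), so every valid pixel contributes to exactly
one cell.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import box
from shapely.geometry.base import BaseGeometry

from .raster import CLASS_CODES, CLASS_NAMES, Raster


@dataclass
class RiskGrid:
    """Fishnet cells clipped to the study boundary.

    Attributes
    ----------
    cells : DataFrame
        One row per retained cell: ``cell_id``, grid ``grow``/``gcol``
        indices, clipped ``area_km2``.
    geometries : dict
        cell_id -> clipped shapely polygon.
    origin : (float, float)
        Grid anchor (lower-left), km.
    cell_size : float
        Cell edge length, km.
    """

    cells: pd.DataFrame
    geometries: dict[int, BaseGeometry]
    origin: tuple[float, float]
    cell_size: float
    nrows: int
    ncols: int
    boundary_area: float

    def __len__(self) -> int:
        return len(self.cells)

    @property
    def cell_ids(self) -> np.ndarray:
        return self.cells["cell_id"].to_numpy()

    @property
    def areas(self) -> pd.Series:
        return self.cells.set_index("cell_id")["area_km2"]

    def cell_id_raster(self, raster: Raster) -> np.ndarray:
        """Map every pixel of ``raster`` to its cell_id (-1 if unassigned)."""
        xs, ys = raster.pixel_centers()
        gcol = np.floor((xs - self.origin[0]) / self.cell_size).astype(int)
        grow = np.floor((ys - self.origin[1]) / self.cell_size).astype(int)
        lookup = -np.ones((self.nrows, self.ncols), dtype=int)
        lookup[self.cells["grow"], self.cells["gcol"]] = self.cells["cell_id"]
        inside = (grow >= 0) & (grow < self.nrows) & (gcol >= 0) & (gcol < self.ncols)
        out = -np.ones(raster.shape, dtype=int)
        out[inside] = lookup[grow[inside], gcol[inside]]
        return out

    def centroids(self) -> pd.DataFrame:
        rows = [
            {"cell_id": cid, "x": geom.centroid.x, "y": geom.centroid.y}
            for cid, geom in self.geometries.items()
        ]
        return pd.DataFrame(rows).sort_values("cell_id").reset_index(drop=True)


def build_fishnet(
    boundary: BaseGeometry,
    cell_size: float,
    origin: tuple[float, float] | None = None,
    min_area_frac: float = 0.01,
) -> RiskGrid:
    """Build the clipped square assessment grid over ``boundary``.

    Parameters
    ----------
    boundary : shapely geometry
        Study-area polygon (km coordinates).
    cell_size : float
        Cell edge length, km (default study design uses 20 km).
    origin : (x, y), optional
        Grid anchor; defaults to the boundary envelope's lower-left corner.
    min_area_frac : float
        Cells whose clipped area is below this fraction of a full cell are
        dropped as slivers.

    Cell ids are assigned row-major from the grid origin (bottom row first,
    west to east), so they are reproducible across runs.
    """
    if boundary is None or boundary.is_empty:
        raise ValueError("boundary polygon is empty")
    if cell_size <= 0:
        raise ValueError("cell_size must be positive")
    xmin, ymin, xmax, ymax = boundary.bounds
    x0, y0 = origin if origin is not None else (xmin, ymin)
    ncols = int(np.ceil((xmax - x0) / cell_size - 1e-12))
    nrows = int(np.ceil((ymax - y0) / cell_size - 1e-12))

    full_area = cell_size**2
    rows, geoms = [], {}
    cid = 0
    for grow in range(nrows):
        for gcol in range(ncols):
            cell = box(
                x0 + gcol * cell_size,
                y0 + grow * cell_size,
                x0 + (gcol + 1) * cell_size,
                y0 + (grow + 1) * cell_size,
            )
            clipped = cell.intersection(boundary)
            if clipped.is_empty:
                continue
            area = clipped.area
            if area < min_area_frac * full_area:
                continue
            rows.append({"cell_id": cid, "grow": grow, "gcol": gcol, "area_km2": area})
            geoms[cid] = clipped
            cid += 1
    if not rows:
        raise ValueError("no grid cell intersects the boundary")
    cells = pd.DataFrame(rows)
    return RiskGrid(
        cells=cells,
        geometries=geoms,
        origin=(x0, y0),
        cell_size=cell_size,
        nrows=nrows,
        ncols=ncols,
        boundary_area=boundary.area,
    )


def zonal_composition(grid: RiskGrid, lc: Raster) -> pd.DataFrame:
    """Per-cell land-cover composition A_ki from pixel counts.

    Returns a long DataFrame (cell_id, class_code, class_name, area_km2) with
    one row per cell and class (zeros included), where
    ``area_km2 = pixel count × pixel area``. Nodata pixels and pixels outside
    every retained cell are ignored.
    """
    cellmap = grid.cell_id_raster(lc)
    valid = lc.valid_mask & (cellmap >= 0)
    codes = lc.data[valid].astype(int)
    unknown = set(np.unique(codes)) - set(CLASS_CODES)
    if unknown:
        raise ValueError(f"unknown land-cover class codes: {sorted(unknown)}")
    cids = cellmap[valid]

    n_classes = len(CLASS_CODES)
    # dense crosstab: cell x class pixel counts
    cid_index = {cid: i for i, cid in enumerate(grid.cell_ids)}
    rows_idx = np.array([cid_index[c] for c in cids])
    counts = np.zeros((len(grid), n_classes), dtype=np.int64)
    np.add.at(counts, (rows_idx, codes - 1), 1)

    area = counts * lc.pixel_area
    long = pd.DataFrame(
        {
            "cell_id": np.repeat(grid.cell_ids, n_classes),
            "class_code": np.tile(CLASS_CODES, len(grid)),
            "area_km2": area.reshape(-1),
        }
    )
    long["class_name"] = long["class_code"].map(CLASS_NAMES)
    return long[["cell_id", "class_code", "class_name", "area_km2"]]


def composition_cell_areas(composition: pd.DataFrame) -> pd.Series:
    """Pixel-based cell area A_k = Σ_i A_ki, indexed by cell_id."""
    return composition.groupby("cell_id")["area_km2"].sum()


def zonal_indicator_means(grid: RiskGrid, surfaces: list[Raster]) -> pd.DataFrame:
    """Per-cell arithmetic mean of each indicator surface (nodata excluded).

    Returns a wide DataFrame indexed by cell_id with one column per indicator.
    Cells with zero valid pixels on any surface are dropped with a warning.
    """
    out = pd.DataFrame(index=pd.Index(grid.cell_ids, name="cell_id"))
    for surf in surfaces:
        if not surf.name:
            raise ValueError("indicator surface must carry a name")
        cellmap = grid.cell_id_raster(surf)
        valid = surf.valid_mask & (cellmap >= 0)
        cids = cellmap[valid]
        vals = surf.data[valid].astype(float)
        sums = pd.Series(vals).groupby(cids).sum()
        counts = pd.Series(np.ones_like(vals)).groupby(cids).sum()
        out[surf.name] = sums / counts
    empty = out.isna().any(axis=1)
    if empty.any():
        warnings.warn(
            f"{int(empty.sum())} cell(s) have no valid pixels on some indicator; excluded",
            stacklevel=2,
        )
        out = out[~empty]
    return out
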