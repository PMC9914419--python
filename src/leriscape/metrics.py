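"""Per-cell, per-class landscape pattern metrics and the disturbance index.

For every assessment cell k and land-cover class i:

* ``n_ki`` — patches (connected components) of class i inside the cell window;
* fragmentation ``C_ki = n_ki / A_ki`` (patches per km²);
* separation ``S_ki = A_k / (2 A_ki) · sqrt(n_ki / A_k)``;
* dominance ``D_ki = (Q_i + M_ki) / 4 + L_ki / 2`` where Q_i is the fraction
  of cells in which class i occurs, M_ki the class's share of the cell's
  patches, and L_ki its share of the cell's area;
* disturbance ``E_ki = a·C_ki + b·S_ki + c·D_ki`` with defaults
  a = 0.5, b = 0.3, c = 0.2.

Patches are delineated inside each cell window independently, so a patch
spanning two cells counts in both — the per-plot reading of the index.
A class absent from a cell gets all metrics 0 (absent-class convention); its
area weight in the risk index is 0 anyway. Areas are in km² throughout; the
fragmentation and separation values are scale-dependent and pinned to that
unit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.measure import label as _sklabel

from .fishnet import RiskGrid
from .raster import CLASS_CODES, CLASS_NAMES, Raster


@dataclass(frozen=True)
class DisturbanceWeights:
    """Weights of fragmentation, separation and dominance in E."""

    a: float = 0.5
    b: float = 0.3
    c: float = 0.2

    def validate(self) -> None:
        if min(self.a, self.b, self.c) < 0:
            raise ValueError("disturbance weights must be non-negative")
        if not np.isclose(self.a + self.b + self.c, 1.0, atol=1e-9):
            raise ValueError("disturbance weights must sum to 1")


def label_patches(window: np.ndarray, class_code: int, connectivity: int = 8) -> int:
    """Count connected components of ``class_code`` in a cell window.

    ``connectivity`` is 4 (edge-adjacent) or 8 (edge- or corner-adjacent;
    the default, matching common landscape-pattern software).
    Pixels outside the cell must be masked to a non-class value beforehand.
    """
    if window.size == 0:
        raise ValueError("empty cell window")
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    if class_code not in CLASS_CODES:
        raise ValueError(f"unknown class code {class_code}")
    mask = window == class_code
    if not mask.any():
        return 0
    return int(_sklabel(mask, connectivity=1 if connectivity == 4 else 2).max())


def fragmentation(n_ki: float, a_ki: float) -> float:
    """C_ki = n_ki / A_ki, patches per km²; 0 for an absent class."""
    if a_ki == 0:
        return 0.0
    return n_ki / a_ki


def separation(n_ki: float, a_ki: float, a_k: float) -> float:
    """S_ki = (A_k / (2 A_ki)) · sqrt(n_ki / A_k); 0 for an absent class."""
    if a_ki == 0:
        return 0.0
    if a_k <= 0:
        raise ValueError("cell area must be positive")
    return a_k / (2.0 * a_ki) * np.sqrt(n_ki / a_k)


def occurrence_frequency(composition: pd.DataFrame) -> pd.Series:
    """Q_i: fraction of cells in which class i occurs, indexed by class_code."""
    n_cells = composition["cell_id"].nunique()
    if n_cells == 0:
        raise ValueError("composition holds no cells")
    present = composition[composition["area_km2"] > 0]
    counts = present.groupby("class_code")["cell_id"].nunique()
    q = counts.reindex(CLASS_CODES, fill_value=0) / n_cells
    q.name = "Q"
    return q


def dominance(q_i: float, m_ki: float, l_ki: float) -> float:
    """D_ki = (Q_i + M_ki)/4 + L_ki/2 ∈ [0, 1]; 0 for an absent class."""
    for name, v in (("Q", q_i), ("M", m_ki), ("L", l_ki)):
        if not 0.0 <= v <= 1.0 + 1e-12:
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    if l_ki == 0 and m_ki == 0:
        return 0.0  # absent-class convention
    return (q_i + m_ki) / 4.0 + l_ki / 2.0


def disturbance(c_ki: float, s_ki: float, d_ki: float,
                weights: DisturbanceWeights = DisturbanceWeights()) -> float:
    """E_ki = a·C + b·S + c·D."""
    weights.validate()
    return weights.a * c_ki + weights.b * s_ki + weights.c * d_ki


def compute_cell_metrics(
    grid: RiskGrid,
    lc: Raster,
    connectivity: int = 8,
    weights: DisturbanceWeights = DisturbanceWeights(),
) -> pd.DataFrame:
    """All Table-style metrics per (cell, class) on one land-cover map.

    Returns a long DataFrame with columns cell_id, class_code, class_name,
    n, area_km2, C, S, D, E. Cell areas A_k are pixel-based (Σ_i A_ki) so
    the composition partition is exact.
    """
    weights.validate()
    cellmap = grid.cell_id_raster(lc)
    valid = lc.valid_mask & (cellmap >= 0)
    pixel_area = lc.pixel_area

    records = []
    cell_rows = grid.cells
    for cid, grow, gcol in zip(cell_rows["cell_id"], cell_rows["grow"], cell_rows["gcol"]):
        sel = cellmap == cid
        sel &= valid
        if not sel.any():
            continue
        rr, cc = np.nonzero(sel)
        r0, r1, c0, c1 = rr.min(), rr.max() + 1, cc.min(), cc.max() + 1
        window = np.where(sel[r0:r1, c0:c1], lc.data[r0:r1, c0:c1], 0).astype(int)
        for code in CLASS_CODES:
            n = label_patches(window, code, connectivity=connectivity)
            area = float((window == code).sum()) * pixel_area
            records.append({"cell_id": cid, "class_code": code, "n": n, "area_km2": area})
    m = pd.DataFrame(records)

    a_k = m.groupby("cell_id")["area_km2"].transform("sum")
    total_patches = m.groupby("cell_id")["n"].transform("sum")
    comp_like = m.rename(columns={"area_km2": "area_km2"})
    q = occurrence_frequency(comp_like)

    m["C"] = np.where(m["area_km2"] > 0, m["n"] / m["area_km2"], 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        s = a_k / (2.0 * m["area_km2"]) * np.sqrt(m["n"] / a_k)
    m["S"] = np.where(m["area_km2"] > 0, s, 0.0)
    m_share = np.where(total_patches > 0, m["n"] / total_patches, 0.0)
    l_share = m["area_km2"] / a_k
    q_vec = m["class_code"].map(q).to_numpy()
    d = (q_vec + m_share) / 4.0 + l_share / 2.0
    m["D"] = np.where(m["area_km2"] > 0, d, 0.0)
    m["E"] = weights.a * m["C"] + weights.b * m["S"] + weights.c * m["D"]
    m["class_name"] = m["class_code"].map(CLASS_NAMES)
    return m[["cell_id", "class_code", "class_name", "n", "area_km2", "C", "S", "D", "E"]]
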