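"""Dynamic landscape vulnerability: empirical class values times a per-cell
composite adjustment factor.

Classic landscape-risk work assigns each land-cover class a fixed empirical
vulnerability rank EV (unused 6, water 5, cropland 4, grassland 3, woodland 2,
urban 1). Here that rank is modulated per assessment cell and per time point
by a composite adjustment factor MN_k built from eight standardized
socio-environmental indicators (GDP density, population density, elevation,
slope, temperature, precipitation, NPP, NDVI):

    m_jk  : min–max standardized indicator j in cell k (orientation-aware)
    EQ_k  = Σ_j w_j · m_jk          (weights from the entropy method, or fixed)
    MN_k  = EQ_k / mean_k(EQ_k)     (grid mean of MN is 1 by construction)
    F_ki  = EV_i · MN_k

Because MN is recomputed from each time point's indicator field, the
vulnerability surface is spatially and temporally dynamic rather than a
static class lookup.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .raster import CLASS_CODES, NAME_TO_CODE
from .synth import INDICATOR_NAMES

#: Empirical vulnerability rank per class name.
DEFAULT_EV: dict[str, float] = {
    "unused": 6.0,
    "water": 5.0,
    "cropland": 4.0,
    "grassland": 3.0,
    "woodland": 2.0,
    "urban": 1.0,
}

#: Published fixed indicator weights (sum exactly 1.0000), canonical order.
FIXED_WEIGHTS: dict[str, float] = {
    "gdp": 0.2421,
    "population": 0.1467,
    "elevation": 0.1482,
    "slope": 0.0985,
    "temperature": 0.0892,
    "precipitation": 0.0647,
    "npp": 0.1023,
    "ndvi": 0.1083,
}

#: True where a larger raw value means higher ecological vulnerability.
DEFAULT_ORIENTATIONS: dict[str, bool] = {
    "gdp": True,
    "population": True,
    "elevation": True,
    "slope": True,
    "temperature": True,
    "precipitation": False,
    "npp": False,
    "ndvi": False,
}


@dataclass
class VulnerabilityConfig:
    """Empirical values, indicator orientations and weighting mode."""

    ev: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_EV))
    orientations: dict[str, bool] = field(default_factory=lambda: dict(DEFAULT_ORIENTATIONS))
    weight_mode: str = "entropy"  # "entropy" | "fixed"

    def validate(self) -> None:
        missing = set(NAME_TO_CODE) - set(self.ev)
        if missing:
            raise ValueError(f"EV missing for classes: {sorted(missing)}")
        if self.weight_mode not in ("entropy", "fixed"):
            raise ValueError(f"unknown weight mode {self.weight_mode!r}")

    def ev_by_code(self) -> pd.Series:
        return pd.Series({NAME_TO_CODE[n]: v for n, v in self.ev.items()}).reindex(CLASS_CODES)


def standardize(raw: pd.DataFrame, orientations: dict[str, bool] | None = None) -> pd.DataFrame:
    """Min–max standardize each indicator column to [0, 1].

    Positively oriented indicators use (x − min)/(max − min); negatively
    oriented ones (max − x)/(max − min). A constant column carries no
    ranking information; it is set to 0.5 everywhere with a warning.
    """
    if len(raw) < 2:
        raise ValueError("need at least 2 cells to standardize")
    if not np.isfinite(raw.to_numpy(dtype=float)).all():
        raise ValueError("indicator matrix contains non-finite values")
    orientations = orientations or DEFAULT_ORIENTATIONS
    out = pd.DataFrame(index=raw.index)
    for col in raw.columns:
        x = raw[col].astype(float)
        lo, hi = x.min(), x.max()
        if hi == lo:
            warnings.warn(f"indicator {col!r} is constant; standardized to 0.5", stacklevel=2)
            out[col] = 0.5
            continue
        positive = orientations.get(col, True)
        out[col] = (x - lo) / (hi - lo) if positive else (hi - x) / (hi - lo)
    return out


def entropy_weights(m: pd.DataFrame) -> pd.Series:
    """Entropy-method weights from a standardized cells × indicators matrix.

    p_jk = m_jk / Σ_k m_jk;  e_j = −(1/ln K) Σ_k p_jk ln p_jk  (0·ln 0 = 0);
    w_j = (1 − e_j) / Σ_j (1 − e_j).
    """
    vals = m.to_numpy(dtype=float)
    if vals.min() < -1e-12 or vals.max() > 1 + 1e-12:
        raise ValueError("standardized matrix must lie in [0, 1]")
    k = vals.shape[0]
    if k < 2:
        raise ValueError("need at least 2 cells for entropy weights")
    col_sums = vals.sum(axis=0)
    if (col_sums <= 0).any():
        bad = list(m.columns[col_sums <= 0])
        raise ValueError(f"all-zero indicator column(s): {bad}; weight undefined")
    p = vals / col_sums
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    e = -plogp.sum(axis=0) / np.log(k)
    d = 1.0 - e
    if d.sum() <= 1e-12:
        warnings.warn("all indicators carry equal (zero) divergence; using equal weights",
                      stacklevel=2)
        w = np.full(vals.shape[1], 1.0 / vals.shape[1])
    else:
        w = d / d.sum()
    return pd.Series(w, index=m.columns, name="weight")


def fixed_weights(columns) -> pd.Series:
    """The published fixed weight set, aligned to ``columns``."""
    w = pd.Series(FIXED_WEIGHTS).reindex(columns)
    if w.isna().any():
        raise ValueError(f"no fixed weight for: {list(w.index[w.isna()])}")
    return w


def indicator_sum(m: pd.DataFrame, w: pd.Series) -> pd.Series:
    """EQ_k = Σ_j w_j · m_jk per cell."""
    if set(m.columns) != set(w.index):
        raise ValueError("weight index does not match indicator columns")
    eq = m.mul(w.reindex(m.columns), axis=1).sum(axis=1)
    eq.name = "EQ"
    return eq


def adjustment_factor(eq: pd.Series) -> pd.Series:
    """MN_k = EQ_k / mean(EQ); mean over cells of MN is 1 by construction."""
    mean = eq.mean()
    if mean <= 0:
        raise ValueError("mean EQ must be positive")
    mn = eq / mean
    mn.name = "MN"
    return mn


def vulnerability_index(config: VulnerabilityConfig, mn: pd.Series) -> pd.DataFrame:
    """F_ki = EV_i · MN_k for every cell and class.

    Returns a long DataFrame (cell_id, class_code, F).
    """
    config.validate()
    ev = config.ev_by_code()
    out = pd.DataFrame(
        {
            "cell_id": np.repeat(mn.index.to_numpy(), len(CLASS_CODES)),
            "class_code": np.tile(CLASS_CODES, len(mn)),
            "F": np.outer(mn.to_numpy(), ev.to_numpy()).reshape(-1),
        }
    )
    return out


def compute_vulnerability(
    indicator_means: pd.DataFrame,
    config: VulnerabilityConfig | None = None,
) -> tuple[pd.Series, pd.DataFrame]:
    """Full vulnerability stage for one time point.

    Parameters
    ----------
    indicator_means : DataFrame
        Raw cells × indicators zonal means (index cell_id).
    config : VulnerabilityConfig

    Returns
    -------
    weights : Series indexed by indicator
    table : DataFrame indexed by cell_id with columns EQ, MN
    """
    config = config or VulnerabilityConfig()
    config.validate()
    cols = [c for c in INDICATOR_NAMES if c in indicator_means.columns]
    if len(cols) != len(indicator_means.columns):
        extra = set(indicator_means.columns) - set(cols)
        raise ValueError(f"unknown indicator columns: {sorted(extra)}")
    m = standardize(indicator_means[cols], config.orientations)
    w = fixed_weights(cols) if config.weight_mode == "fixed" else entropy_weights(m)
    eq = indicator_sum(m, w)
    mn = adjustment_factor(eq)
    return w, pd.DataFrame({"EQ": eq, "MN": mn})
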