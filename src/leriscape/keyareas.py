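"""Key risk-management areas: stable high-risk, reduction-lagged, risk-unstable.

Each category flags the cells in the top ``q`` fraction (default 15%) of a
ranking variable:

* **stable high-risk** — LERI in the top q of cells in *every* period
  ("remained high for the duration of the study period");
* **reduction-lagged** — full-period RRC in the top q (largest RRC = slowest
  decline or fastest growth);
* **risk-unstable** — CV of the LERI series in the top q.

The threshold is the (1−q)-quantile (linear interpolation); a cell is flagged
when its value is strictly greater. With all-distinct values this flags
exactly floor(qN) cells; ties at the threshold are excluded with a warning.
The key-area mask is the union of the three categories.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd


def _top_quantile_flags(values: pd.Series, q: float, what: str) -> pd.Series:
    if not 0.0 < q < 1.0:
        raise ValueError("quantile threshold must be in (0, 1)")
    finite = values.dropna()
    if finite.empty:
        raise ValueError(f"no finite {what} values to rank")
    thresh = np.percentile(finite.to_numpy(dtype=float), 100.0 * (1.0 - q))
    flags = values > thresh
    n_ties = int((finite == thresh).sum())
    if flags.sum() == 0 and n_ties > 0:
        warnings.warn(
            f"{what}: {n_ties} value(s) tie at the {100 * (1 - q):.0f}th percentile; "
            "strict threshold flags none",
            stacklevel=3,
        )
    flags.name = what
    return flags.fillna(False)


def stable_high_risk(leri_panel: pd.DataFrame, q: float = 0.15) -> pd.Series:
    """Cells whose LERI is in the top ``q`` fraction in every period.

    ``leri_panel`` is wide: rows cells, one column per time point.
    """
    if leri_panel.shape[1] < 2:
        raise ValueError("need at least 2 periods")
    per_period = [
        _top_quantile_flags(leri_panel[col], q, f"LERI {col}") for col in leri_panel.columns
    ]
    flags = pd.concat(per_period, axis=1).all(axis=1)
    flags.name = "stable_high_risk"
    return flags


def reduction_lagged(rrc: pd.Series, q: float = 0.15) -> pd.Series:
    """Cells whose full-period RRC is in the top ``q`` fraction."""
    flags = _top_quantile_flags(rrc, q, "RRC")
    flags.name = "reduction_lagged"
    return flags


def risk_unstable(cv: pd.Series, q: float = 0.15) -> pd.Series:
    """Cells whose LERI coefficient of variation is in the top ``q`` fraction."""
    flags = _top_quantile_flags(cv, q, "CV")
    flags.name = "risk_unstable"
    return flags


def combine(
    stable: pd.Series, lagged: pd.Series, unstable: pd.Series
) -> tuple[pd.DataFrame, dict]:
    """Union of the three categories plus summary counts and shares.

    Returns the per-cell flag table (stable_high_risk, reduction_lagged,
    risk_unstable, key_union) and a summary dict with per-category counts,
    pairwise overlaps, the union count and its share of all cells.
    """
    if not (stable.index.equals(lagged.index) and stable.index.equals(unstable.index)):
        raise ValueError("mismatched cell ids across key-area masks")
    table = pd.DataFrame(
        {
            "stable_high_risk": stable.astype(bool),
            "reduction_lagged": lagged.astype(bool),
            "risk_unstable": unstable.astype(bool),
        }
    )
    table["key_union"] = table.any(axis=1)
    n = len(table)
    summary = {
        "n_cells": n,
        "stable_high_risk": int(table["stable_high_risk"].sum()),
        "reduction_lagged": int(table["reduction_lagged"].sum()),
        "risk_unstable": int(table["risk_unstable"].sum()),
        "overlap_stable_lagged": int((table["stable_high_risk"] & table["reduction_lagged"]).sum()),
        "overlap_stable_unstable": int((table["stable_high_risk"] & table["risk_unstable"]).sum()),
        "overlap_lagged_unstable": int((table["reduction_lagged"] & table["risk_unstable"]).sum()),
        "key_union": int(table["key_union"].sum()),
        "key_union_share_pct": float(round(100.0 * table["key_union"].sum() / n, 1)) if n else 0.0,
    }
    return table, summary
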