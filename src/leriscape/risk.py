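"""Landscape Ecological Risk Index, risk classification and temporal statistics.

Per assessment cell k the risk index is the composition-weighted sum of
disturbance × vulnerability over land-cover classes:

    LERI_k = Σ_i E_ki · F_ki · A_ki / A_k

Risk levels use five classes with default fixed breaks 0.60 / 1.18 / 1.72 /
2.40 (left-closed intervals; LERI ≥ 2.40 is high risk), or breaks recomputed
by the Jenks/Fisher natural-breaks optimal 1-D partition. Temporal change is
summarized per cell by the annualized risk rate of change

    RRC_k = (LERI_T2 − LERI_T1) / LERI_T1 · (1/ΔT) · 100   [% per year]

and temporal stability by the coefficient of variation of the cell's LERI
series, CV_k = SD_k / AV_k (sample standard deviation, n−1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

RISK_LEVELS = ("low", "medium-low", "medium", "medium-high", "high")
DEFAULT_BREAKS = (0.60, 1.18, 1.72, 2.40)


@dataclass(frozen=True)
class ClassificationScheme:
    """Ordered interior break values delimiting the risk levels."""

    breaks: tuple[float, ...] = DEFAULT_BREAKS
    method: str = "fixed"  # "fixed" | "jenks"
    labels: tuple[str, ...] = field(default=RISK_LEVELS)

    def validate(self) -> None:
        b = np.asarray(self.breaks, dtype=float)
        if len(b) != len(self.labels) - 1:
            raise ValueError("need one fewer break than labels")
        if not (np.diff(b) > 0).all():
            raise ValueError("breaks must be strictly increasing")


def leri(metrics: pd.DataFrame, f: pd.DataFrame) -> pd.Series:
    """LERI_k = Σ_i E_ki · F_ki · A_ki / A_k per cell.

    Parameters
    ----------
    metrics : DataFrame
        Long (cell_id, class_code, area_km2, E) from the metrics stage.
    f : DataFrame
        Long (cell_id, class_code, F) from the vulnerability stage.

    A_k is the pixel-based cell area Σ_i A_ki, so the composition weights
    partition exactly; LERI is then the composition-weighted mean of E·F and
    is bounded above by max_i(E_ki · F_ki).
    """
    merged = metrics.merge(f, on=["cell_id", "class_code"], how="left")
    if merged["F"].isna().any():
        missing = merged.loc[merged["F"].isna(), "cell_id"].unique()
        raise ValueError(f"vulnerability missing for cells {missing[:5]}...")
    a_k = merged.groupby("cell_id")["area_km2"].transform("sum")
    if (merged.groupby("cell_id")["area_km2"].sum() <= 0).any():
        raise ValueError("cell with non-positive area")
    merged["term"] = merged["E"] * merged["F"] * merged["area_km2"] / a_k
    out = merged.groupby("cell_id")["term"].sum()
    out.name = "LERI"
    return out


def classify(values, scheme: ClassificationScheme = ClassificationScheme()):
    """Map LERI value(s) to risk-level labels.

    Intervals are left-closed from the second class: value < b1 is the lowest
    level, b1 ≤ value < b2 the next, and value ≥ last break the highest.
    """
    scheme.validate()
    arr = np.atleast_1d(np.asarray(values, dtype=float))
    if (arr < 0).any():
        raise ValueError("LERI values must be non-negative")
    idx = np.searchsorted(np.asarray(scheme.breaks), arr, side="right")
    labels = np.asarray(scheme.labels, dtype=object)[idx]
    if np.isscalar(values) or np.asarray(values).ndim == 0:
        return labels[0]
    return labels


def jenks_breaks(values, n_classes: int) -> ClassificationScheme:
    """Jenks / Fisher optimal natural breaks for a 1-D sample.

    Finds the partition of the sorted values into ``n_classes`` contiguous
    groups minimizing the total within-class sum of squared deviations, by
    dynamic programming (O(k·n²)). Interior breaks are reported as the
    minimum of each class from the second onward, so :func:`classify` with
    its left-closed convention reproduces the optimal assignment.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    if np.unique(x).size < n_classes:
        raise ValueError("too few distinct values for the requested class count")

    cs = np.concatenate(([0.0], np.cumsum(x)))
    css = np.concatenate(([0.0], np.cumsum(x * x)))

    def ssd(a: np.ndarray, b: int) -> np.ndarray:
        # within-class SSD of x[a..b] inclusive, vectorized over start index a
        cnt = b - a + 1
        s = cs[b + 1] - cs[a]
        return css[b + 1] - css[a] - s * s / cnt

    cost = np.full((n_classes, n), np.inf)
    cut = np.zeros((n_classes, n), dtype=int)
    idx = np.arange(n)
    cost[0] = css[1:] - cs[1:] ** 2 / (idx + 1)
    for c in range(1, n_classes):
        for i in range(c, n):
            starts = np.arange(c, i + 1)  # first element of the last class
            total = cost[c - 1, starts - 1] + ssd(starts, i)
            j = int(np.argmin(total))
            cost[c, i] = total[j]
            cut[c, i] = starts[j]

    # backtrack: breaks are the minima of classes 2..k
    breaks = []
    i = n - 1
    for c in range(n_classes - 1, 0, -1):
        s = cut[c, i]
        breaks.append(x[s])
        i = s - 1
    labels = RISK_LEVELS if n_classes == len(RISK_LEVELS) else tuple(
        f"class_{i + 1}" for i in range(n_classes)
    )
    return ClassificationScheme(breaks=tuple(sorted(breaks)), method="jenks", labels=labels)


def risk_rate_of_change(leri_t1, leri_t2, delta_years: float):
    """RRC = (LERI_T2 − LERI_T1)/LERI_T1 × (1/ΔT) × 100, % per year.

    Negative values mean the risk decreased. Cells with LERI_T1 = 0 are
    undefined and returned as NaN.
    """
    if delta_years <= 0:
        raise ValueError("time span must be positive")
    t1 = np.asarray(leri_t1, dtype=float)
    t2 = np.asarray(leri_t2, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        rrc = (t2 - t1) / t1 / delta_years * 100.0
    rrc = np.where(t1 > 0, rrc, np.nan)
    if isinstance(leri_t1, pd.Series):
        return pd.Series(rrc, index=leri_t1.index, name="RRC")
    return rrc if rrc.ndim else float(rrc)


def coefficient_of_variation(series: pd.DataFrame | np.ndarray) -> pd.Series | np.ndarray | float:
    """CV_k = SD_k / AV_k of each cell's LERI time series.

    Uses the sample standard deviation (ddof = 1). For a DataFrame the rows
    are cells and the columns time points. Cells with zero mean are undefined
    (NaN).
    """
    if isinstance(series, pd.DataFrame):
        vals = series.to_numpy(dtype=float)
        index = series.index
    else:
        vals = np.atleast_2d(np.asarray(series, dtype=float))
        index = None
    if vals.shape[1] < 2:
        raise ValueError("need at least 2 time points for CV")
    sd = vals.std(axis=1, ddof=1)
    av = vals.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(av > 0, sd / av, np.nan)
    if index is not None:
        return pd.Series(cv, index=index, name="CV")
    return cv if cv.size > 1 else float(cv[0])
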