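"""Land-use transfer matrices and net-change summaries between two dates.

The transfer matrix T[i, j] is the area (km²) that is class i at the first
date and class j at the second, cross-tabulated over the pixels valid at both
dates (common-footprint rule), so row sums, column sums and the grand total
are exactly conserved.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .raster import CLASS_CODES, CLASS_NAMES, Raster, require_same_registry


def transfer_matrix(map1: Raster, map2: Raster) -> pd.DataFrame:
    """6×6 area cross-tabulation (km²) of class transitions map1 → map2.

    Rows are classes at the first date, columns at the second; only pixels
    valid on both maps are counted, so row sums equal the first date's class
    areas and column sums the second's, exactly.
    """
    require_same_registry(map1, map2)
    valid = map1.valid_mask & map2.valid_mask
    a = map1.data[valid].astype(int)
    b = map2.data[valid].astype(int)
    for arr, which in ((a, "first"), (b, "second")):
        unknown = set(np.unique(arr)) - set(CLASS_CODES)
        if unknown:
            raise ValueError(f"unknown class codes in {which} map: {sorted(unknown)}")
    n = len(CLASS_CODES)
    counts = np.zeros((n, n), dtype=np.int64)
    np.add.at(counts, (a - 1, b - 1), 1)
    names = [CLASS_NAMES[c] for c in CLASS_CODES]
    return pd.DataFrame(counts * map1.pixel_area, index=names, columns=names)


def net_change(t: pd.DataFrame) -> pd.DataFrame:
    """Per-class gain, loss and net change (km²) from a transfer matrix.

    gain = column sum − diagonal; loss = row sum − diagonal;
    net = gain − loss. Nets sum to zero by conservation.
    """
    diag = pd.Series(np.diag(t.to_numpy()), index=t.index)
    gain = t.sum(axis=0) - diag
    loss = t.sum(axis=1) - diag
    out = pd.DataFrame({"gain_km2": gain, "loss_km2": loss})
    out["net_km2"] = out["gain_km2"] - out["loss_km2"]
    out["area_t1_km2"] = t.sum(axis=1)
    out["area_t2_km2"] = t.sum(axis=0)
    return out


def to_long(t: pd.DataFrame) -> pd.DataFrame:
    """Long-format (from, to, area_km2) view of a transfer matrix."""
    long = t.stack().rename("area_km2").reset_index()
    long.columns = ["from", "to", "area_km2"]
    return long
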