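"""Independent brute-force oracles used to cross-check the implementation."""

from __future__ import annotations

from collections import deque

import numpy as np


def flood_fill_patch_count(window: np.ndarray, class_code: int, connectivity: int) -> int:
    """Connected components of ``class_code`` by explicit BFS flood fill."""
    mask = window == class_code
    seen = np.zeros_like(mask, dtype=bool)
    if connectivity == 4:
        offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        offsets = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    nrows, ncols = mask.shape
    count = 0
    for r in range(nrows):
        for c in range(ncols):
            if not mask[r, c] or seen[r, c]:
                continue
            count += 1
            queue = deque([(r, c)])
            seen[r, c] = True
            while queue:
                rr, cc = queue.popleft()
                for dr, dc in offsets:
                    nr, nc = rr + dr, cc + dc
                    if 0 <= nr < nrows and 0 <= nc < ncols and mask[nr, nc] and not seen[nr, nc]:
                        seen[nr, nc] = True
                        queue.append((nr, nc))
    return count


def exhaustive_jenks(values, n_classes: int) -> tuple[float, list[list[float]]]:
    """Optimal 1-D partition by exhaustive search over all contiguous splits."""
    from itertools import combinations

    x = sorted(values)
    n = len(x)

    def ssd(chunk):
        m = sum(chunk) / len(chunk)
        return sum((v - m) ** 2 for v in chunk)

    best_cost, best_parts = float("inf"), None
    for cuts in combinations(range(1, n), n_classes - 1):
        bounds = (0, *cuts, n)
        parts = [x[a:b] for a, b in zip(bounds[:-1], bounds[1:])]
        cost = sum(ssd(p) for p in parts)
        if cost < best_cost - 1e-12:
            best_cost, best_parts = cost, parts
    return best_cost, best_parts


def brute_force_leri(cell_rows) -> float:
    """Term-by-term evaluation of LERI_k = Σ_i E·F·A_i / A_k on one cell.

    ``cell_rows`` is an iterable of (E, F, area) triples for the cell.
    """
    rows = list(cell_rows)
    a_k = sum(a for _, _, a in rows)
    return sum(e * f * a / a_k for e, f, a in rows)
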