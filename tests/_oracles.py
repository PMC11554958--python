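"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths: plain double loops,
breadth-first flood fill, and direct counting, so agreement with the library
is a genuine cross-check.
"""

from __future__ import annotations

import math
from collections import deque

import numpy as np


def foraging_average_oracle(
    values: np.ndarray, alpha_m: float, resolution_m: float, cutoff: float = 1e-3
) -> np.ndarray:
    """Double-loop distance-weighted mean with exponential decay."""
    n, m = values.shape
    out = np.zeros((n, m), dtype=float)
    for r in range(n):
        for c in range(m):
            num = den = 0.0
            for rr in range(n):
                for cc in range(m):
                    d = resolution_m * math.hypot(r - rr, c - cc)
                    w = math.exp(-d / alpha_m)
                    if w >= cutoff:
                        num += values[rr, cc] * w
                        den += w
            out[r, c] = num / den
    return out


def abundance_oracle(
    hn: np.ndarray,
    hf: np.ndarray,
    alpha_m: float,
    resolution_m: float,
    activity: float = 1.0,
    cutoff: float = 1e-3,
) -> np.ndarray:
    """Two-pass source-then-visitation model, all by double loops."""
    source = hn * foraging_average_oracle(hf, alpha_m, resolution_m, cutoff)
    return foraging_average_oracle(source, alpha_m, resolution_m, cutoff) * activity


def flood_fill_filter_oracle(
    mask: np.ndarray, cell_area_ha: float, min_area_ha: float, connectivity: int = 8
) -> np.ndarray:
    """BFS connected-component labelling plus size filter."""
    mask = np.asarray(mask, dtype=bool)
    n, m = mask.shape
    seen = np.zeros_like(mask)
    out = np.zeros_like(mask)
    if connectivity == 8:
        nbrs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    for r in range(n):
        for c in range(m):
            if not mask[r, c] or seen[r, c]:
                continue
            comp = [(r, c)]
            seen[r, c] = True
            q = deque([(r, c)])
            while q:
                rr, cc = q.popleft()
                for dr, dc in nbrs:
                    r2, c2 = rr + dr, cc + dc
                    if 0 <= r2 < n and 0 <= c2 < m and mask[r2, c2] and not seen[r2, c2]:
                        seen[r2, c2] = True
                        comp.append((r2, c2))
                        q.append((r2, c2))
            if len(comp) * cell_area_ha >= min_area_ha - 1e-12:
                for rr, cc in comp:
                    out[rr, cc] = True
    return out.astype(np.uint8)


def natural_cover_oracle(
    mask: np.ndarray, resolution_m: float, radius_m: float
) -> np.ndarray:
    """Exhaustive circular-window percentage count."""
    mask = np.asarray(mask, dtype=float)
    n, m = mask.shape
    out = np.zeros((n, m))
    for r in range(n):
        for c in range(m):
            num = den = 0
            for rr in range(n):
                for cc in range(m):
                    d = resolution_m * math.hypot(r - rr, c - cc)
                    if d <= radius_m + 1e-9:
                        den += 1
                        num += mask[rr, cc]
            out[r, c] = 100.0 * num / den
    return out


def field_cover_oracle(
    cover: np.ndarray,
    resolution_m: float,
    origin_x: float,
    origin_y: float,
    centroid: tuple[float, float],
    radius_m: float,
) -> float:
    """Exhaustive mean of cover cells whose centers fall within the radius."""
    n, m = cover.shape
    cx, cy = centroid
    vals = []
    for r in range(n):
        for c in range(m):
            x = origin_x + (c + 0.5) * resolution_m
            y = origin_y - (r + 0.5) * resolution_m
            if (x - cx) ** 2 + (y - cy) ** 2 <= radius_m**2 + 1e-9:
                vals.append(cover[r, c])
    return float(np.mean(vals))
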