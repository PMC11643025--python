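"""Independent brute-force oracles used to cross-check the implementation.

Each oracle is written from the mathematical definition, deliberately
avoiding the library routines the implementation uses.
"""

from __future__ import annotations

import numpy as np


def point_in_polygon(px: float, py: float, vertices) -> bool:
    """Crossing-number test with explicit on-segment check (boundary counts as inside)."""
    v = np.asarray(vertices, dtype=float)
    n = len(v)
    inside = False
    for i in range(n):
        ax, ay = v[i]
        bx, by = v[(i + 1) % n]
        cross = (bx - ax) * (py - ay) - (by - ay) * (px - ax)
        if (
            abs(cross) <= 1e-12
            and min(ax, bx) - 1e-12 <= px <= max(ax, bx) + 1e-12
            and min(ay, by) - 1e-12 <= py <= max(ay, by) + 1e-12
        ):
            return True
        if (ay > py) != (by > py):
            x_int = ax + (py - ay) * (bx - ax) / (by - ay)
            if px < x_int:
                inside = not inside
    return inside


def polygon_mask_oracle(shape: tuple[int, int], vertices) -> np.ndarray:
    h, w = shape
    return np.array(
        [[point_in_polygon(x, y, vertices) for x in range(w)] for y in range(h)]
    )


def otsu_mask_oracle(values: np.ndarray, nbins: int = 256) -> np.ndarray:
    """Foreground mask from an exhaustive between-class-variance search."""
    flat = values.ravel()
    counts, edges = np.histogram(flat, bins=nbins)
    centers = (edges[:-1] + edges[1:]) / 2
    best_var, best_t = -1.0, edges[0]
    total = counts.sum()
    for k in range(1, nbins):
        w0 = counts[:k].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (counts[:k] * centers[:k]).sum() / w0
        mu1 = (counts[k:] * centers[k:]).sum() / w1
        var = w0 * w1 * (mu0 - mu1) ** 2
        if var > best_var:
            best_var, best_t = var, edges[k]
    return values >= best_t


def area_fraction_oracle(mask: np.ndarray, fraction: float, side: str) -> np.ndarray:
    """Brute-force distance ranking: per-pixel distance to the nearest background
    pixel computed by exhaustive search, then head/tail selection."""
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    bg = np.argwhere(~mask)
    fg = np.argwhere(mask)
    d = np.sqrt(((fg[:, None, :] - bg[None, :, :]) ** 2).sum(axis=2)).min(axis=1)
    flat_idx = fg[:, 0] * w + fg[:, 1]
    order = np.lexsort((flat_idx, d))
    area = len(fg)
    k = int(round(fraction * area))
    chosen = flat_idx[order[:k]] if side == "peripheral" else flat_idx[order[area - k:]]
    out = np.zeros(mask.size, dtype=bool)
    out[chosen] = True
    return out.reshape(mask.shape)


def random_star_polygon(rng: np.random.Generator, n_vertices: int, cx: float, cy: float, r_max: float):
    """A random simple (star-shaped) polygon around (cx, cy)."""
    angles = np.sort(rng.uniform(0, 2 * np.pi, n_vertices))
    radii = rng.uniform(0.3 * r_max, r_max, n_vertices)
    return np.column_stack([cx + radii * np.cos(angles), cy + radii * np.sin(angles)])
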