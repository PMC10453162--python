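"""Independent brute-force oracles for geometry operations.

Everything here is implemented from first principles (plain Python set
arithmetic, a monotone-chain convex hull, cross-product point-in-polygon)
so it shares no code path with the package's scikit-image-based
implementations.
"""

from __future__ import annotations

import numpy as np


def pixel_set(mask: np.ndarray, label: int) -> set[tuple[int, int]]:
    rows, cols = np.nonzero(mask == label)
    return set(zip(rows.tolist(), cols.tolist()))


def containment_bruteforce(dead: set[tuple[int, int]], host: set[tuple[int, int]]) -> float:
    return len(dead & host) / len(dead)


def convex_hull_polygon(points: list[tuple[float, float]]) -> list[tuple[float, float]]:
    """Monotone-chain convex hull; returns vertices in counter-clockwise order."""
    pts = sorted(set(points))
    if len(pts) <= 2:
        return pts

    def cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    lower = []
    for p in pts:
        while len(lower) >= 2 and cross(lower[-2], lower[-1], p) <= 0:
            lower.pop()
        lower.append(p)
    upper = []
    for p in reversed(pts):
        while len(upper) >= 2 and cross(upper[-2], upper[-1], p) <= 0:
            upper.pop()
        upper.append(p)
    return lower[:-1] + upper[:-1]


def point_in_polygon(point: tuple[float, float], poly: list[tuple[float, float]],
                     tol: float = 1e-9) -> bool:
    """True if the point is inside or on a convex CCW polygon (half-plane test)."""
    n = len(poly)
    if n == 1:
        return abs(point[0] - poly[0][0]) < tol and abs(point[1] - poly[0][1]) < tol
    if n == 2:
        (x1, y1), (x2, y2) = poly
        cross = (x2 - x1) * (point[1] - y1) - (y2 - y1) * (point[0] - x1)
        if abs(cross) > tol:
            return False
        dot = (point[0] - x1) * (x2 - x1) + (point[1] - y1) * (y2 - y1)
        return -tol <= dot <= (x2 - x1) ** 2 + (y2 - y1) ** 2 + tol
    for i in range(n):
        x1, y1 = poly[i]
        x2, y2 = poly[(i + 1) % n]
        if (x2 - x1) * (point[1] - y1) - (y2 - y1) * (point[0] - x1) < -tol:
            return False
    return True


def solidity_deficit_bruteforce(shape_mask: np.ndarray) -> float:
    """1 - area / rasterized-convex-hull area, enumerated pixel by pixel.

    The hull is taken over the foreground pixel centers and rasterized by
    testing every pixel center in the bounding box for membership
    (inside-or-on).
    """
    rows, cols = np.nonzero(shape_mask)
    centers = [(float(r), float(c)) for r, c in zip(rows.tolist(), cols.tolist())]
    poly = convex_hull_polygon(centers)
    hull_pixels = 0
    for r in range(rows.min(), rows.max() + 1):
        for c in range(cols.min(), cols.max() + 1):
            if point_in_polygon((float(r), float(c)), poly):
                hull_pixels += 1
    return 1.0 - len(rows) / hull_pixels


def random_blob(rng: np.random.Generator, size: int = 40) -> np.ndarray:
    """A random connected blob: union of a few overlapping disks."""
    mask = np.zeros((size, size), dtype=bool)
    cr, cc = size / 2, size / 2
    n_disks = int(rng.integers(1, 4))
    for k in range(n_disks):
        r0 = cr + (rng.uniform(-5, 5) if k else 0.0)
        c0 = cc + (rng.uniform(-5, 5) if k else 0.0)
        rad = rng.uniform(5, 10)
        rr, cc_ = np.meshgrid(np.arange(size), np.arange(size), indexing="ij")
        mask |= (rr - r0) ** 2 + (cc_ - c0) ** 2 <= rad**2
    return mask
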