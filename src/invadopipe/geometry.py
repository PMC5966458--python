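"""Crack-boundary tracing and the polygon perimeter estimator.

Digital perimeter estimation is the one step where naive choices break the
downstream circularity filter: the raw inter-pixel ("crack") boundary
overestimates the perimeter of round objects by up to 4/π, pushing the
circularity of a perfect disk down to ~0.6, while pixel-centre polygons
underestimate small objects. The estimator used here:

1. trace the outer crack boundary of the component (vertices at pixel
   corners, integer coordinates);
2. merge collinear runs into maximal straight segments;
3. at every corner where at least one adjacent segment has unit length (a
   staircase step), cut the corner by routing the polygon through the
   midpoints of both adjacent segments; corners between two longer runs
   (true right angles, e.g. rectangle corners) are kept.

On a uniform staircase (digital straight line of any slope) the midpoint
cut is exact, so digitized disks of radius ≥ 10 px measure circularity
≥ 0.9; axis-aligned rectangles keep their full crack perimeter
(2·(w + h) pixels), so a 2×20 px bar measures 4π·40/44² ≈ 0.260 and is
rejected by a 0.35 circularity floor as intended.
"""

from __future__ import annotations

import numpy as np

__all__ = ["trace_crack_boundary", "boundary_polygon", "polygon_perimeter", "smoothed_perimeter"]


def trace_crack_boundary(mask: np.ndarray) -> np.ndarray:
    """Outer boundary of a binary component as pixel-corner vertices.

    Returns an (N, 2) float array of (x, y) corners in the mask's own frame
    (corner (0, 0) is the top-left corner of pixel (0, 0)); the polygon is
    implicitly closed. Interior hole boundaries are not returned.

    At corners where two boundary edges leave the same vertex (a pair of
    diagonally touching pixels), the trace continues through the diagonal,
    keeping an 8-connected component on a single loop.
    """
    m = np.pad(np.asarray(mask, dtype=bool), 1)
    # directed boundary edges, region kept on a consistent side
    out: dict[tuple[int, int], list[tuple[int, int]]] = {}
    ys, xs = np.nonzero(m)
    for y, x in zip(ys.tolist(), xs.tolist()):
        if not m[y - 1, x]:
            out.setdefault((x, y), []).append((x + 1, y))
        if not m[y + 1, x]:
            out.setdefault((x + 1, y + 1), []).append((x, y + 1))
        if not m[y, x - 1]:
            out.setdefault((x, y + 1), []).append((x, y))
        if not m[y, x + 1]:
            out.setdefault((x + 1, y), []).append((x + 1, y + 1))

    if not out:
        return np.empty((0, 2))

    def _next(cur: tuple[int, int], incoming: tuple[int, int]) -> tuple[int, int]:
        options = out[cur]
        if len(options) == 1:
            return options[0]
        # two outgoing edges: continue through the diagonal (negative cross
        # product with the incoming direction in image coordinates)
        best = None
        for opt in options:
            d2 = (opt[0] - cur[0], opt[1] - cur[1])
            cross = incoming[0] * d2[1] - incoming[1] * d2[0]
            if cross < 0:
                best = opt
        return best if best is not None else options[0]

    loops: list[list[tuple[int, int]]] = []
    used: set[tuple[tuple[int, int], tuple[int, int]]] = set()
    for start, heads in out.items():
        for head in heads:
            if (start, head) in used:
                continue
            loop = [start]
            used.add((start, head))
            prev, cur = start, head
            while cur != start:
                loop.append(cur)
                nxt = _next(cur, (cur[0] - prev[0], cur[1] - prev[1]))
                used.add((cur, nxt))
                prev, cur = cur, nxt
            loops.append(loop)

    # the outer loop contains the lexicographically smallest corner
    outer = min(loops, key=lambda lp: min((y, x) for x, y in lp))
    poly = np.asarray(outer, dtype=float)
    poly -= 1.0  # undo padding offset
    return poly


def _collapse_collinear(poly: np.ndarray) -> np.ndarray:
    """Drop vertices interior to straight runs."""
    n = len(poly)
    if n < 3:
        return poly
    keep = []
    for i in range(n):
        a, b, c = poly[i - 1], poly[i], poly[(i + 1) % n]
        # crack edges are unit axis-aligned steps: collinear iff directions equal
        if not np.array_equal(b - a, c - b):
            keep.append(b)
    return np.asarray(keep)


def boundary_polygon(mask: np.ndarray) -> np.ndarray:
    """Outer crack boundary with collinear runs merged; (N, 2) (x, y) corners."""
    return _collapse_collinear(trace_crack_boundary(mask))


def polygon_perimeter(poly: np.ndarray) -> float:
    """Length of a closed polygon given as (N, 2) vertices."""
    if len(poly) < 2:
        return 0.0
    return float(np.linalg.norm(np.roll(poly, -1, axis=0) - poly, axis=1).sum())


def smoothed_perimeter(mask: np.ndarray) -> float:
    """Perimeter (in pixels) of a binary component by the corner-cut estimator."""
    poly = boundary_polygon(mask)
    n = len(poly)
    if n < 3:
        return 0.0
    seg = np.linalg.norm(np.roll(poly, -1, axis=0) - poly, axis=1)
    pts = []
    for i in range(n):
        l_prev, l_next = seg[i - 1], seg[i]
        b = poly[i]
        if min(l_prev, l_next) <= 1.0 + 1e-9:
            a, c = poly[i - 1], poly[(i + 1) % n]
            pts.append(b + (a - b) * 0.5)
            pts.append(b + (c - b) * 0.5)
        else:
            pts.append(b)
    return polygon_perimeter(np.asarray(pts))
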