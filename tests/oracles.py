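"""Independent brute-force reference implementations.

Deliberately written as plain per-triangle scalar loops with a different
closest-point formulation (plane projection + edge clamping) than the
package's vectorised barycentric-region kernel, so agreement is a real
cross-check rather than a tautology.
"""

from __future__ import annotations

import math

import numpy as np


def _closest_on_segment(p, a, b):
    d = b - a
    L2 = float(d @ d)
    if L2 == 0.0:
        return a
    t = float((p - a) @ d) / L2
    t = min(1.0, max(0.0, t))
    return a + t * d


def _closest_on_triangle(p, a, b, c):
    """Plane projection; if the foot falls outside, clamp to the edges."""
    n = np.cross(b - a, c - a)
    nn = float(n @ n)
    if nn == 0.0:
        # degenerate: best point on the longest edge chain
        candidates = [_closest_on_segment(p, a, b),
                      _closest_on_segment(p, b, c),
                      _closest_on_segment(p, c, a)]
        return min(candidates, key=lambda q: float((q - p) @ (q - p)))
    foot = p - (float((p - a) @ n) / nn) * n
    # inside test via same-side signed volumes
    inside = True
    for u, v in ((a, b), (b, c), (c, a)):
        if float(np.cross(v - u, foot - u) @ n) < 0.0:
            inside = False
            break
    if inside:
        return foot
    candidates = [_closest_on_segment(p, a, b),
                  _closest_on_segment(p, b, c),
                  _closest_on_segment(p, c, a)]
    return min(candidates, key=lambda q: float((q - p) @ (q - p)))


def brute_nearest(point, triangles):
    """Minimal distance and closest point over every triangle."""
    p = np.asarray(point, dtype=float)
    best_d = math.inf
    best_q = None
    for tri in np.asarray(triangles, dtype=float):
        q = _closest_on_triangle(p, tri[0], tri[1], tri[2])
        d = float(np.linalg.norm(q - p))
        if d < best_d:
            best_d, best_q = d, q
    return best_d, best_q


def brute_ray(origin, direction, triangles, t_min=1e-9):
    """Smallest ray parameter over per-face Möller-Trumbore, or None."""
    o = np.asarray(origin, dtype=float)
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    best_t = math.inf
    for tri in np.asarray(triangles, dtype=float):
        v0, v1, v2 = tri
        e1, e2 = v1 - v0, v2 - v0
        h = np.cross(d, e2)
        det = float(e1 @ h)
        if abs(det) < 1e-12:
            continue
        s = o - v0
        u = float(s @ h) / det
        if u < -1e-12 or u > 1 + 1e-12:
            continue
        q = np.cross(s, e1)
        v = float(d @ q) / det
        if v < -1e-12 or u + v > 1 + 1e-12:
            continue
        t = float(e2 @ q) / det
        if t > t_min and t < best_t:
            best_t = t
    return None if math.isinf(best_t) else best_t


def _clip_polygon(poly, signed):
    """Keep the part of a convex polygon with signed value >= 0."""
    out = []
    k = len(poly)
    for i in range(k):
        j = (i + 1) % k
        si, sj = signed[i], signed[j]
        if si >= 0:
            out.append(poly[i])
        if (si >= 0) != (sj >= 0):
            t = si / (si - sj)
            out.append(poly[i] + t * (poly[j] - poly[i]))
    return out


def _closest_on_planar_polygon(p, poly, plane_n):
    if len(poly) == 1:
        return poly[0]
    if len(poly) == 2:
        return _closest_on_segment(p, poly[0], poly[1])
    n = plane_n / np.linalg.norm(plane_n)
    foot = p - float((p - poly[0]) @ n) * n
    inside = True
    for i in range(len(poly)):
        u = poly[i]
        v = poly[(i + 1) % len(poly)]
        if float(np.cross(v - u, foot - u) @ n) < -1e-12:
            inside = False
            break
    if inside:
        return foot
    return min(
        (_closest_on_segment(p, poly[i], poly[(i + 1) % len(poly)])
         for i in range(len(poly))),
        key=lambda q: float((q - p) @ (q - p)),
    )


def brute_clt(probe, anchor, normal, delta, triangles):
    """Minimal distance from ``probe`` to the mesh restricted to the
    opposite-surface half-space (q - anchor) . normal >= delta, looping
    over every triangle and clipping exactly.  Returns inf when nothing
    qualifies; add delta for the cortical thickness convention."""
    p = np.asarray(probe, dtype=float)
    a0 = np.asarray(anchor, dtype=float)
    n = np.asarray(normal, dtype=float)
    best = math.inf
    for tri in np.asarray(triangles, dtype=float):
        signed = [float((tri[i] - a0) @ n) - delta for i in range(3)]
        if max(signed) < 0:
            continue
        if min(signed) >= 0:
            poly = [tri[0], tri[1], tri[2]]
        else:
            poly = _clip_polygon([tri[0], tri[1], tri[2]], signed)
            if not poly:
                continue
        plane_n = np.cross(tri[1] - tri[0], tri[2] - tri[0])
        q = _closest_on_planar_polygon(p, poly, plane_n)
        d = float(np.linalg.norm(q - p))
        if d < best:
            best = d
    return best
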