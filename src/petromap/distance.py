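"""Exact point-to-mesh and ray-to-mesh queries with KD-tree pruning.

All queries return exact (machine-precision) results over the triangle
set: a cKDTree over triangle centroids only prunes candidates, using the
bound  |p - centroid| - circumradius <= current-best,  which can never
discard the true minimiser.  This keeps results bit-comparable with a
brute-force loop over every triangle while scaling to 10^5-face meshes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from .geometry import TriangleMesh, EmptyMeshError

__all__ = [
    "closest_point_on_triangles",
    "MeshQuery",
    "nearest_on_mesh",
    "ray_first_hit",
    "RayHit",
]


def closest_point_on_triangles(point: np.ndarray, triangles: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Closest point on each triangle to ``point``.

    ``triangles`` is (n, 3, 3).  Returns (distances (n,), closest points
    (n, 3)) using the standard barycentric region classification, fully
    vectorised over triangles.
    """
    p = np.asarray(point, dtype=float)
    tri = np.asarray(triangles, dtype=float)
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab = b - a
    ac = c - a
    ap = p - a

    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    vc = d1 * d4 - d3 * d2
    vb = d5 * d2 - d1 * d6
    va = d3 * d6 - d5 * d4

    out = np.empty_like(a)
    done = np.zeros(len(tri), dtype=bool)

    def take(mask, value):
        m = mask & ~done
        if m.any():
            out[m] = value[m] if value.ndim == 2 else value
            done[m] = True

    take((d1 <= 0) & (d2 <= 0), a)                      # vertex region A
    take((d3 >= 0) & (d4 <= d3), b)                     # vertex region B
    with np.errstate(divide="ignore", invalid="ignore"):
        v_ab = np.where(d1 - d3 != 0, d1 / (d1 - d3), 0.0)
        take((vc <= 0) & (d1 >= 0) & (d3 <= 0), a + v_ab[:, None] * ab)
        take((d6 >= 0) & (d5 <= d6), c)                 # vertex region C
        w_ac = np.where(d2 - d6 != 0, d2 / (d2 - d6), 0.0)
        take((vb <= 0) & (d2 >= 0) & (d6 <= 0), a + w_ac[:, None] * ac)
        num = d4 - d3
        den = (d4 - d3) + (d5 - d6)
        w_bc = np.where(den != 0, num / den, 0.0)
        take((va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0), b + w_bc[:, None] * (c - b))
        denom = va + vb + vc
        denom = np.where(denom != 0, denom, 1.0)
        v = vb / denom
        w = vc / denom
        take(np.ones(len(tri), dtype=bool), a + v[:, None] * ab + w[:, None] * ac)

    dist = np.linalg.norm(out - p, axis=1)
    return dist, out


def _closest_point_on_polygon(point: np.ndarray, poly: np.ndarray,
                              plane_normal: np.ndarray) -> np.ndarray:
    """Closest point on a planar convex polygon (vertices (k, 3), k >= 1)."""
    p = np.asarray(point, dtype=float)
    k = len(poly)
    if k == 1:
        return poly[0]
    if k == 2:
        d = poly[1] - poly[0]
        L2 = float(d @ d)
        t = 0.0 if L2 == 0 else float(np.clip((p - poly[0]) @ d / L2, 0.0, 1.0))
        return poly[0] + t * d
    # project p onto the polygon's plane and test containment
    n = plane_normal / np.linalg.norm(plane_normal)
    proj = p - float((p - poly[0]) @ n) * n
    inside = True
    for i in range(k):
        e = poly[(i + 1) % k] - poly[i]
        if float(np.cross(e, proj - poly[i]) @ n) < -1e-12:
            inside = False
            break
    if inside:
        return proj
    best = None
    best_d = np.inf
    for i in range(k):
        a, b = poly[i], poly[(i + 1) % k]
        d = b - a
        L2 = float(d @ d)
        t = 0.0 if L2 == 0 else float(np.clip((p - a) @ d / L2, 0.0, 1.0))
        q = a + t * d
        dd = float(np.linalg.norm(q - p))
        if dd < best_d:
            best_d, best = dd, q
    return best


def _clip_triangle_halfspace(tri: np.ndarray, signed: np.ndarray) -> np.ndarray:
    """Sutherland-Hodgman clip of one triangle against signed >= 0."""
    out: list[np.ndarray] = []
    for i in range(3):
        j = (i + 1) % 3
        vi, vj = tri[i], tri[j]
        si, sj = signed[i], signed[j]
        if si >= 0:
            out.append(vi)
        if (si >= 0) != (sj >= 0):
            t = si / (si - sj)
            out.append(vi + t * (vj - vi))
    return np.asarray(out)


@dataclass(frozen=True)
class RayHit:
    point: np.ndarray
    t: float
    face: int


def _moller_trumbore(origin: np.ndarray, direction: np.ndarray,
                     triangles: np.ndarray, t_min: float = 1e-9) -> tuple[np.ndarray, np.ndarray]:
    """Ray/triangle intersection parameters for one ray against (n,3,3).

    Returns (t values with inf for misses, hit mask).
    """
    o = np.asarray(origin, dtype=float)
    d = np.asarray(direction, dtype=float)
    v0, v1, v2 = triangles[:, 0], triangles[:, 1], triangles[:, 2]
    e1 = v1 - v0
    e2 = v2 - v0
    h = np.cross(d[None, :], e2)
    det = np.einsum("ij,ij->i", e1, h)
    eps = 1e-12
    with np.errstate(divide="ignore", invalid="ignore"):
        inv_det = np.where(np.abs(det) > eps, 1.0 / det, 0.0)
        s = o - v0
        u = np.einsum("ij,ij->i", s, h) * inv_det
        q = np.cross(s, e1)
        v = np.einsum("j,ij->i", d, q) * inv_det
        t = np.einsum("ij,ij->i", e2, q) * inv_det
    hit = (np.abs(det) > eps) & (u >= -1e-12) & (v >= -1e-12) & (u + v <= 1 + 1e-12) & (t > t_min)
    t = np.where(hit, t, np.inf)
    return t, hit


def ray_first_hit(mesh: TriangleMesh, origin, direction) -> Optional[RayHit]:
    """First intersection of a ray with the mesh (smallest t > 1e-9).

    Returns ``None`` when the ray misses.  Raises on a zero direction
    vector; the direction is normalised so t is in millimetres.
    """
    d = np.asarray(direction, dtype=float)
    norm = np.linalg.norm(d)
    if norm < 1e-12:
        raise ValueError("zero direction vector")
    d = d / norm
    o = np.asarray(origin, dtype=float)
    t, hit = _moller_trumbore(o, d, mesh.triangles)
    if not hit.any():
        return None
    face = int(np.argmin(t))
    t_hit = float(t[face])
    return RayHit(point=o + t_hit * d, t=t_hit, face=face)


class MeshQuery:
    """Pruned exact nearest-point and ray queries on one mesh.

    Results match a brute-force loop over every triangle to machine
    precision; the KD-tree over triangle centroids is only used to discard
    triangles that provably cannot contain the minimiser.
    """

    def __init__(self, mesh: TriangleMesh):
        if len(mesh.faces) == 0:
            raise EmptyMeshError("empty mesh")
        self.mesh = mesh
        tri = mesh.triangles
        self._centroids = tri.mean(axis=1)
        self._radii = np.linalg.norm(tri - self._centroids[:, None, :], axis=2).max(axis=1)
        self._r_max = float(self._radii.max())
        self._tree = cKDTree(self._centroids)
        self._vtree = cKDTree(mesh.vertices)
        # 2D tree over centroid (x, y) for vertical-ray pruning
        self._tree_xy = cKDTree(self._centroids[:, :2])
        self._r_max_xy = float(
            np.linalg.norm((tri - self._centroids[:, None, :])[:, :, :2], axis=2).max()
        )

    # -- nearest ------------------------------------------------------------

    def _candidates(self, point: np.ndarray, upper: float) -> np.ndarray:
        idx = self._tree.query_ball_point(point, upper + self._r_max + 1e-9)
        return np.asarray(idx, dtype=np.int64)

    def nearest(self, point) -> tuple[float, np.ndarray]:
        """Exact minimal distance and closest surface point."""
        p = np.asarray(point, dtype=float)
        d_vert, _ = self._vtree.query(p)
        cand = self._candidates(p, float(d_vert))
        dist, pts = closest_point_on_triangles(p, self.mesh.triangles[cand])
        k = int(np.argmin(dist))
        return float(dist[k]), pts[k]

    def nearest_many(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Vectorised :meth:`nearest` over an (n, 3) array."""
        pts = np.asarray(points, dtype=float).reshape(-1, 3)
        d_vert, _ = self._vtree.query(pts, workers=-1)
        out_d = np.empty(len(pts))
        out_p = np.empty_like(pts)
        cand_lists = self._tree.query_ball_point(pts, d_vert + self._r_max + 1e-9)
        for i, (p, cand) in enumerate(zip(pts, cand_lists)):
            dist, cp = closest_point_on_triangles(p, self.mesh.triangles[np.asarray(cand)])
            k = int(np.argmin(dist))
            out_d[i] = dist[k]
            out_p[i] = cp[k]
        return out_d, out_p

    # -- half-space-constrained nearest --------------------------------------

    def nearest_in_halfspace(self, probe, anchor, normal, offset: float,
                             max_dist: float = np.inf) -> tuple[float, Optional[np.ndarray]]:
        """Minimal distance from ``probe`` to the mesh restricted to the
        half-space  {q : (q - anchor) . normal >= offset}.

        Triangles straddling the plane are clipped exactly; the result is
        identical to a brute-force clip-every-triangle loop.  Returns
        (inf, None) when no surface point within ``max_dist`` satisfies
        the constraint.
        """
        p = np.asarray(probe, dtype=float)
        a = np.asarray(anchor, dtype=float)
        n = np.asarray(normal, dtype=float)

        # upper bound from qualifying vertices
        upper = max_dist
        k = min(64, len(self.mesh.vertices))
        dv, iv = self._vtree.query(p, k=k)
        dv = np.atleast_1d(dv)
        iv = np.atleast_1d(iv)
        sv = (self.mesh.vertices[iv] - a) @ n - offset
        ok = sv >= 0
        if ok.any():
            upper = min(upper, float(dv[ok].min()))
        if not ok.any():
            # no qualifying vertex among the k nearest: scan all once.  A
            # linear constraint attains its max over a triangle at a vertex,
            # so if no vertex qualifies, no surface point does.
            s_all = (self.mesh.vertices - a) @ n - offset
            ok_all = s_all >= 0
            if not ok_all.any():
                return np.inf, None
            upper = min(upper, float(np.linalg.norm(
                self.mesh.vertices[ok_all] - p, axis=1).min()))

        if not np.isfinite(upper):
            return np.inf, None

        cand = self._candidates(p, upper)
        if len(cand) == 0:
            return np.inf, None
        tri = self.mesh.triangles[cand]
        signed = (tri - a) @ n - offset          # (m, 3)
        full_in = (signed >= 0).all(axis=1)
        full_out = (signed < 0).all(axis=1)
        straddle = ~full_in & ~full_out

        best_d = np.inf
        best_p: Optional[np.ndarray] = None
        if full_in.any():
            dist, cp = closest_point_on_triangles(p, tri[full_in])
            k = int(np.argmin(dist))
            if dist[k] < best_d:
                best_d = float(dist[k])
                best_p = cp[k]
        if straddle.any():
            normals = self.mesh.face_normals[cand]
            for t, s, fn in zip(tri[straddle], signed[straddle], normals[straddle]):
                poly = _clip_triangle_halfspace(t, s)
                if len(poly) == 0:
                    continue
                q = _closest_point_on_polygon(p, poly, fn)
                d = float(np.linalg.norm(q - p))
                if d < best_d:
                    best_d = d
                    best_p = q
        if best_d > max_dist:
            return np.inf, None
        return best_d, best_p

    # -- vertical rays -------------------------------------------------------

    def first_hit_down(self, xy: np.ndarray, z_start: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """First hit of vertical −z rays from (x, y, z_start) for each row
        of ``xy``.  Returns (hit mask, hit points (n,3) with NaN on miss,
        face indices with −1 on miss)."""
        xy = np.asarray(xy, dtype=float).reshape(-1, 2)
        n = len(xy)
        hit_mask = np.zeros(n, dtype=bool)
        hit_pts = np.full((n, 3), np.nan)
        hit_face = np.full(n, -1, dtype=np.int64)
        d = np.array([0.0, 0.0, -1.0])
        cand_lists = self._tree_xy.query_ball_point(xy, self._r_max_xy + 1e-9)
        for i, cand in enumerate(cand_lists):
            if not cand:
                continue
            cand = np.asarray(cand, dtype=np.int64)
            o = np.array([xy[i, 0], xy[i, 1], z_start])
            t, hit = _moller_trumbore(o, d, self.mesh.triangles[cand])
            if not hit.any():
                continue
            k = int(np.argmin(t))
            hit_mask[i] = True
            hit_pts[i] = o + t[k] * d
            hit_face[i] = cand[k]
        return hit_mask, hit_pts, hit_face


def nearest_on_mesh(mesh: TriangleMesh, point) -> tuple[float, np.ndarray]:
    """Exact minimal Euclidean distance from a point to a mesh surface.

    Convenience one-shot wrapper; build a :class:`MeshQuery` for repeated
    queries against the same mesh.
    """
    return MeshQuery(mesh).nearest(point)
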