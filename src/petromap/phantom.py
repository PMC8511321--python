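"""Seeded synthetic temporal-bone phantom with analytic ground truth.

The phantom emulates the geometric features the pipeline measures on real
segmented anatomy: a cortical shell of spatially varying thickness whose
outer face is a gently domed heightfield, spherical air cells embedded
strictly inside the shell, and a dura/sinus surface lying 1–11 mm beneath
the outer face, optionally with a cylindrical sinus ridge bulging toward
the bone.  The inner cortical wall and the dura sheet are offsets of the
outer surface along its exact analytic normal, so the true cortical layer
thickness (CLT) and distance to dura/venous sinus (DDVS) at any footprint
point have closed forms:

    clt(x, y)  = min( t(x, y),  min_k |s(x, y) − c_k| − r_k )
    ddvs(x, y) = min( d(x, y),  dist(s(x, y), sinus axis) − R )

with s the outer-surface point above (x, y), t the thickness field, d the
dura-depth field and (c_k, r_k) the air cells.  Offset-surface distances
equal the offset exactly when the offset is below the surface's radius of
curvature and the fields vary slowly (|∇t|, |∇d| ≪ 1); the default dome
keeps the radius of curvature above 300 mm so the approximation error is
far below the mesh chord error.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import trimesh
import yaml

from .geometry import TriangleMesh

__all__ = [
    "ScalarField2D",
    "SinusTube",
    "PhantomConfig",
    "PhantomTruth",
    "generate_phantom",
    "sample_truth",
]


@dataclass(frozen=True)
class ScalarField2D:
    """Slowly varying scalar field over the footprint plane (mm).

    kinds: ``constant`` (value a), ``linear`` (a + b·u) and ``sinusoid``
    (a + b·sin(2π u / wavelength)) with u the x or y coordinate.
    """

    kind: str = "constant"
    a: float = 2.0
    b: float = 0.0
    wavelength: float = 60.0
    axis: str = "x"

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "linear", "sinusoid"):
            raise ValueError(f"unknown field kind {self.kind!r}")
        if self.axis not in ("x", "y"):
            raise ValueError("axis must be 'x' or 'y'")

    def __call__(self, x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        u = x if self.axis == "x" else y
        if self.kind == "constant":
            return np.broadcast_to(np.float64(self.a), u.shape).copy() if u.shape else np.float64(self.a)
        if self.kind == "linear":
            return self.a + self.b * u
        return self.a + self.b * np.sin(2.0 * np.pi * u / self.wavelength)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d) -> "ScalarField2D":
        if isinstance(d, (int, float)):
            return cls(kind="constant", a=float(d))
        return cls(**d)


@dataclass(frozen=True)
class SinusTube:
    """Straight cylindrical sinus segment under the outer surface.

    The axis runs between the surface points above ``p0`` and ``p1``
    (footprint coordinates, mm), pushed ``depth`` mm along the inward
    surface normal; the tube has radius ``radius``.  The mesh is a capsule
    so the point-to-tube distance is exactly dist(p, axis segment) − radius.
    """

    p0: tuple[float, float]
    p1: tuple[float, float]
    depth: float
    radius: float

    def to_dict(self) -> dict:
        return {"p0": list(self.p0), "p1": list(self.p1),
                "depth": self.depth, "radius": self.radius}

    @classmethod
    def from_dict(cls, d) -> "SinusTube":
        return cls(p0=tuple(d["p0"]), p1=tuple(d["p1"]),
                   depth=float(d["depth"]), radius=float(d["radius"]))


@dataclass(frozen=True)
class AirCellSpec:
    """Requested air-cell population: count and sampling ranges."""

    count: int = 0
    radius_range: tuple[float, float] = (0.5, 1.2)
    depth_range: tuple[float, float] = (0.8, 3.5)


@dataclass
class PhantomConfig:
    grid_extent: float = 55.0
    mesh_resolution: float = 1.0
    dome_amplitude: float = 2.5
    dome_sigma: float = 30.0
    base_thickness_field: ScalarField2D = field(default_factory=lambda: ScalarField2D(a=2.0))
    dura_depth_field: ScalarField2D = field(default_factory=lambda: ScalarField2D(a=5.0))
    air_cells: AirCellSpec = field(default_factory=AirCellSpec)
    explicit_cells: Optional[list[tuple[float, float, float, float]]] = None  # (x, y, depth, radius)
    sinus_tube: Optional[SinusTube] = None
    seed: int = 0

    # margins enforced between cells and the bounding surfaces (mm)
    cell_margin: float = 0.15

    def to_dict(self) -> dict:
        d = {
            "grid_extent": self.grid_extent,
            "mesh_resolution": self.mesh_resolution,
            "dome_amplitude": self.dome_amplitude,
            "dome_sigma": self.dome_sigma,
            "base_thickness_field": self.base_thickness_field.to_dict(),
            "dura_depth_field": self.dura_depth_field.to_dict(),
            "air_cells": dataclasses.asdict(self.air_cells),
            "explicit_cells": self.explicit_cells,
            "sinus_tube": self.sinus_tube.to_dict() if self.sinus_tube else None,
            "seed": self.seed,
            "cell_margin": self.cell_margin,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomConfig":
        d = dict(d)
        if "base_thickness_field" in d:
            d["base_thickness_field"] = ScalarField2D.from_dict(d["base_thickness_field"])
        if "dura_depth_field" in d:
            d["dura_depth_field"] = ScalarField2D.from_dict(d["dura_depth_field"])
        if d.get("air_cells") is not None and not isinstance(d["air_cells"], AirCellSpec):
            ac = dict(d["air_cells"])
            if "radius_range" in ac:
                ac["radius_range"] = tuple(ac["radius_range"])
            if "depth_range" in ac:
                ac["depth_range"] = tuple(ac["depth_range"])
            d["air_cells"] = AirCellSpec(**ac)
        if d.get("explicit_cells") is not None:
            d["explicit_cells"] = [tuple(c) for c in d["explicit_cells"]]
        if d.get("sinus_tube") is not None:
            d["sinus_tube"] = SinusTube.from_dict(d["sinus_tube"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PhantomConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


class PhantomConfigError(ValueError):
    pass


@dataclass
class PhantomTruth:
    """Closed-form CLT/DDVS ground truth for a generated phantom."""

    grid_extent: float
    dome_amplitude: float
    dome_sigma: float
    thickness_field: ScalarField2D
    dura_depth_field: ScalarField2D
    cells: np.ndarray                      # (n, 4): center xyz + radius
    sinus: Optional[tuple[np.ndarray, np.ndarray, float]]  # (a, b, radius) in 3D
    n_cells_requested: int
    n_cells_placed: int

    # -- analytic surface ----------------------------------------------------

    def surface_height(self, x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return self.dome_amplitude * np.exp(-(x ** 2 + y ** 2) / (2.0 * self.dome_sigma ** 2))

    def surface_point(self, x, y) -> np.ndarray:
        z = self.surface_height(x, y)
        return np.stack(np.broadcast_arrays(x, y, z), axis=-1).astype(float)

    def inward_normal(self, x, y) -> np.ndarray:
        """Exact unit inward (−z-ward) normal of the outer surface."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        z = self.surface_height(x, y)
        gx = -z * x / self.dome_sigma ** 2
        gy = -z * y / self.dome_sigma ** 2
        n = np.stack(np.broadcast_arrays(gx, gy, -np.ones_like(z)), axis=-1)
        return n / np.linalg.norm(n, axis=-1, keepdims=True)

    # -- ground truth --------------------------------------------------------

    def clt_at(self, x, y):
        """Analytic cortical layer thickness above (x, y)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        t = np.asarray(self.thickness_field(x, y), dtype=float)
        if len(self.cells):
            s = self.surface_point(x, y).reshape(-1, 3)
            d_cell = np.linalg.norm(
                s[:, None, :] - self.cells[None, :, :3], axis=2
            ) - self.cells[None, :, 3]
            t = np.minimum(t, d_cell.min(axis=1).reshape(t.shape))
        return t

    def ddvs_at(self, x, y):
        """Analytic distance from the outer surface to dura/sinus above (x, y)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        d = np.asarray(self.dura_depth_field(x, y), dtype=float)
        if self.sinus is not None:
            a, b, radius = self.sinus
            s = self.surface_point(x, y).reshape(-1, 3)
            ab = b - a
            L2 = float(ab @ ab)
            tt = np.clip((s - a) @ ab / L2, 0.0, 1.0)
            foot = a + tt[:, None] * ab
            d_tube = np.linalg.norm(s - foot, axis=1) - radius
            d = np.minimum(d, d_tube.reshape(d.shape))
        return d

    def in_footprint(self, x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        e = self.grid_extent
        return (np.abs(x) <= e) & (np.abs(y) <= e)

    # -- serialization -------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "grid_extent": self.grid_extent,
            "dome_amplitude": self.dome_amplitude,
            "dome_sigma": self.dome_sigma,
            "thickness_field": self.thickness_field.to_dict(),
            "dura_depth_field": self.dura_depth_field.to_dict(),
            "cells": self.cells.tolist(),
            "sinus": None if self.sinus is None else
                     [self.sinus[0].tolist(), self.sinus[1].tolist(), self.sinus[2]],
            "n_cells_requested": self.n_cells_requested,
            "n_cells_placed": self.n_cells_placed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomTruth":
        sinus = d.get("sinus")
        return cls(
            grid_extent=float(d["grid_extent"]),
            dome_amplitude=float(d["dome_amplitude"]),
            dome_sigma=float(d["dome_sigma"]),
            thickness_field=ScalarField2D.from_dict(d["thickness_field"]),
            dura_depth_field=ScalarField2D.from_dict(d["dura_depth_field"]),
            cells=np.asarray(d["cells"], dtype=float).reshape(-1, 4),
            sinus=None if sinus is None else
                  (np.asarray(sinus[0], float), np.asarray(sinus[1], float), float(sinus[2])),
            n_cells_requested=int(d["n_cells_requested"]),
            n_cells_placed=int(d["n_cells_placed"]),
        )


# ---------------------------------------------------------------------------
# mesh construction helpers


def _grid_axes(extent: float, resolution: float) -> np.ndarray:
    n = max(2, int(round(2.0 * extent / resolution)) + 1)
    return np.linspace(-extent, extent, n)


def _heightfield_mesh(xs: np.ndarray, ys: np.ndarray, z: np.ndarray,
                      flip: bool) -> tuple[np.ndarray, np.ndarray]:
    """Triangulate a heightfield grid; flip reverses winding."""
    nx, ny = len(xs), len(ys)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    verts = np.column_stack([X.ravel(), Y.ravel(), np.asarray(z).ravel()])
    idx = np.arange(nx * ny).reshape(nx, ny)
    q00 = idx[:-1, :-1].ravel()
    q10 = idx[1:, :-1].ravel()
    q01 = idx[:-1, 1:].ravel()
    q11 = idx[1:, 1:].ravel()
    f1 = np.column_stack([q00, q10, q11])
    f2 = np.column_stack([q00, q11, q01])
    faces = np.vstack([f1, f2])
    if flip:
        faces = faces[:, ::-1]
    return verts, faces


def _offset_surface(truth: PhantomTruth, xs: np.ndarray, ys: np.ndarray,
                    offset_field: ScalarField2D) -> np.ndarray:
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    s = truth.surface_point(X, Y)
    n = truth.inward_normal(X, Y)
    off = np.asarray(offset_field(X, Y), dtype=float)[..., None]
    return (s + off * n).reshape(-1, 3)


def _boundary_loop(nx: int, ny: int) -> np.ndarray:
    """Indices of the grid boundary ordered counter-clockwise seen from +z."""
    idx = np.arange(nx * ny).reshape(nx, ny)
    loop = np.concatenate([
        idx[:, 0],            # y = min, x increasing
        idx[-1, 1:],          # x = max, y increasing
        idx[-2::-1, -1],      # y = max, x decreasing
        idx[0, -2:0:-1],      # x = min, y decreasing (stop before start)
    ])
    return loop


def _wall_faces(loop_outer: np.ndarray, loop_inner: np.ndarray) -> np.ndarray:
    n = len(loop_outer)
    faces = []
    for i in range(n):
        j = (i + 1) % n
        o0, o1 = loop_outer[i], loop_outer[j]
        i0, i1 = loop_inner[i], loop_inner[j]
        faces.append([o0, i0, i1])
        faces.append([o0, i1, o1])
    return np.asarray(faces, dtype=np.int64)


def _icosphere(center: np.ndarray, radius: float, inverted: bool) -> tuple[np.ndarray, np.ndarray]:
    s = trimesh.creation.icosphere(subdivisions=3, radius=radius)
    v = np.asarray(s.vertices) + np.asarray(center)
    f = np.asarray(s.faces)
    if inverted:
        f = f[:, ::-1]
    return v, f


def _capsule_mesh(a: np.ndarray, b: np.ndarray, radius: float,
                  n_phi: int = 32, seg_len: float = 1.5) -> tuple[np.ndarray, np.ndarray]:
    """Sphere-capped cylinder from ``a`` to ``b`` with short axial segments.

    Short segments keep triangle circumradii small, which the pruned
    nearest-point queries rely on for tight candidate sets.
    """
    axis = b - a
    height = float(np.linalg.norm(axis))
    z = axis / height
    ref = np.array([1.0, 0.0, 0.0]) if abs(z[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    x = np.cross(ref, z)
    x /= np.linalg.norm(x)
    y = np.cross(z, x)

    phi = 2.0 * np.pi * np.arange(n_phi) / n_phi
    circle = np.cos(phi)[:, None] * x + np.sin(phi)[:, None] * y  # (n_phi, 3)

    # ring stations: lower hemisphere, cylinder, upper hemisphere
    n_cap = max(8, int(np.ceil(0.5 * np.pi * radius / seg_len)))
    n_axial = max(2, int(np.ceil(height / seg_len)))
    rings: list[tuple[float, float]] = []  # (axial offset from a, ring radius)
    for ang in np.linspace(-0.5 * np.pi, 0.0, n_cap + 1)[1:-1]:
        rings.append((radius * np.sin(ang), radius * np.cos(ang)))
    for t in np.linspace(0.0, height, n_axial + 1):
        rings.append((t, radius))
    for ang in np.linspace(0.0, 0.5 * np.pi, n_cap + 1)[1:-1]:
        rings.append((height + radius * np.sin(ang), radius * np.cos(ang)))

    verts = [a - radius * z]                       # bottom pole
    for off, r in rings:
        verts.append(a + off * z + r * circle)
    verts.append(a + (height + radius) * z)        # top pole
    vertices = np.vstack([np.atleast_2d(v) for v in verts])

    faces = []
    # bottom fan (pole index 0, first ring starts at 1)
    for k in range(n_phi):
        faces.append([0, 1 + (k + 1) % n_phi, 1 + k])
    n_rings = len(rings)
    for ri in range(n_rings - 1):
        base0 = 1 + ri * n_phi
        base1 = base0 + n_phi
        for k in range(n_phi):
            k1 = (k + 1) % n_phi
            faces.append([base0 + k, base0 + k1, base1 + k1])
            faces.append([base0 + k, base1 + k1, base1 + k])
    top = 1 + n_rings * n_phi
    base = 1 + (n_rings - 1) * n_phi
    for k in range(n_phi):
        faces.append([top, base + k, base + (k + 1) % n_phi])
    return vertices, np.asarray(faces, dtype=np.int64)


# ---------------------------------------------------------------------------


def _place_cells(cfg: PhantomConfig, truth: PhantomTruth,
                 rng: np.random.Generator) -> list[tuple[float, float, float, float]]:
    """Rejection-sample (x, y, depth, radius) air cells against the margins."""
    spec = cfg.air_cells
    placed: list[tuple[float, float, float, float]] = []
    if spec.count <= 0:
        return placed
    lateral = cfg.grid_extent - max(spec.radius_range) - 2.0
    attempts = 0
    max_attempts = spec.count * 400
    while len(placed) < spec.count and attempts < max_attempts:
        attempts += 1
        x, y = rng.uniform(-lateral, lateral, size=2)
        r = rng.uniform(*spec.radius_range)
        depth = rng.uniform(*spec.depth_range)
        if not _cell_ok(cfg, truth, placed, x, y, depth, r):
            continue
        placed.append((float(x), float(y), float(depth), float(r)))
    return placed


def _cell_ok(cfg: PhantomConfig, truth: PhantomTruth,
             placed: Sequence[tuple[float, float, float, float]],
             x: float, y: float, depth: float, r: float) -> bool:
    m = cfg.cell_margin
    t_here = float(cfg.base_thickness_field(x, y))
    if depth - r < m:                 # pierces the outer surface
        return False
    if depth + r > t_here - m:        # pierces the inner surface
        return False
    c = truth.surface_point(x, y) + depth * truth.inward_normal(x, y)
    for (px, py, pd, pr) in placed:
        pc = truth.surface_point(px, py) + pd * truth.inward_normal(px, py)
        if np.linalg.norm(c - pc) < r + pr + 2.0 * m:
            return False
    return True


def generate_phantom(config: PhantomConfig) -> tuple[TriangleMesh, TriangleMesh, PhantomTruth]:
    """Build the bone shell, the dura/sinus surface and the analytic truth.

    The bone mesh is watertight: outer heightfield + inner offset
    heightfield + boundary wall, plus one inverted sphere per air cell.
    Identical configs (including seed) yield identical meshes.
    """
    xs = _grid_axes(config.grid_extent, config.mesh_resolution)
    ys = xs
    X, Y = np.meshgrid(xs, ys, indexing="ij")

    t_grid = np.asarray(config.base_thickness_field(X, Y), dtype=float)
    d_grid = np.asarray(config.dura_depth_field(X, Y), dtype=float)
    if np.any(t_grid <= 0.1):
        raise PhantomConfigError("thickness field must exceed 0.1 mm everywhere")
    if np.any(d_grid <= t_grid):
        raise PhantomConfigError("dura depth must exceed the shell thickness everywhere")

    truth = PhantomTruth(
        grid_extent=config.grid_extent,
        dome_amplitude=config.dome_amplitude,
        dome_sigma=config.dome_sigma,
        thickness_field=config.base_thickness_field,
        dura_depth_field=config.dura_depth_field,
        cells=np.zeros((0, 4)),
        sinus=None,
        n_cells_requested=config.air_cells.count if config.explicit_cells is None
        else len(config.explicit_cells),
        n_cells_placed=0,
    )

    # air cells: explicit list validated, or rejection-sampled
    rng = np.random.default_rng(config.seed)
    if config.explicit_cells is not None:
        for k, (x, y, depth, r) in enumerate(config.explicit_cells):
            if not _cell_ok(config, truth,
                            [c for i, c in enumerate(config.explicit_cells) if i < k],
                            x, y, depth, r):
                raise PhantomConfigError(
                    f"air cell {k} (x={x}, y={y}, depth={depth}, r={r}) violates "
                    "the shell margins or overlaps another cell"
                )
        cell_params = [tuple(map(float, c)) for c in config.explicit_cells]
    else:
        cell_params = _place_cells(config, truth, rng)

    centers = np.array([
        truth.surface_point(x, y) + depth * truth.inward_normal(x, y)
        for (x, y, depth, r) in cell_params
    ]).reshape(-1, 3)
    radii = np.array([r for (_, _, _, r) in cell_params])
    truth.cells = np.column_stack([centers, radii]) if len(cell_params) else np.zeros((0, 4))
    truth.n_cells_placed = len(cell_params)

    # sinus tube in 3D
    if config.sinus_tube is not None:
        st = config.sinus_tube
        a3 = (truth.surface_point(*st.p0) + st.depth * truth.inward_normal(*st.p0)).ravel()
        b3 = (truth.surface_point(*st.p1) + st.depth * truth.inward_normal(*st.p1)).ravel()
        # the tube must stay clear of the inner cortical wall
        t_max = float(np.max([config.base_thickness_field(*st.p0),
                              config.base_thickness_field(*st.p1)]))
        if st.depth - st.radius <= t_max:
            raise PhantomConfigError("sinus tube intersects the cortical shell")
        truth.sinus = (a3, b3, st.radius)

    # bone: outer + inner + wall + inverted cell spheres
    z_out = truth.surface_height(X, Y)
    v_outer, f_outer = _heightfield_mesh(xs, ys, z_out, flip=False)
    v_inner = _offset_surface(truth, xs, ys, config.base_thickness_field)
    _, f_inner = _heightfield_mesh(xs, ys, z_out, flip=True)
    nx, ny = len(xs), len(ys)
    loop = _boundary_loop(nx, ny)
    n0 = len(v_outer)
    verts = [v_outer, v_inner]
    faces = [f_outer, f_inner + n0, _wall_faces(loop, loop + n0)]
    offset = 2 * n0
    for c, r in zip(centers, radii):
        sv, sf = _icosphere(c, float(r), inverted=True)
        verts.append(sv)
        faces.append(sf + offset)
        offset += len(sv)
    bone = TriangleMesh(np.vstack(verts), np.vstack(faces), name="phantom_bone")

    # dura: open offset sheet (+ capsule ridge)
    v_dura = _offset_surface(truth, xs, ys, config.dura_depth_field)
    _, f_dura = _heightfield_mesh(xs, ys, z_out, flip=True)
    dverts = [v_dura]
    dfaces = [f_dura]
    if truth.sinus is not None:
        a3, b3, radius = truth.sinus
        cv, cf = _capsule_mesh(a3, b3, radius)
        dfaces.append(cf + len(v_dura))
        dverts.append(cv)
    dura = TriangleMesh(np.vstack(dverts), np.vstack(dfaces), name="phantom_dura")

    return bone, dura, truth


def sample_truth(truth: PhantomTruth, points: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Analytic (clt, ddvs) at footprint points (n, 2).

    Out-of-footprint points get NaN; the third return is the validity mask.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    x, y = pts[:, 0], pts[:, 1]
    ok = truth.in_footprint(x, y)
    clt = np.where(ok, truth.clt_at(x, y), np.nan)
    ddvs = np.where(ok, truth.ddvs_at(x, y), np.nan)
    return clt, ddvs, ok
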