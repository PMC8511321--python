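"""Mesh data model and the anatomical coordinate frame.

All geometry is in millimetres.  The analysis frame is anchored at the
centre of the external auditory canal (EAC): the z-axis runs along the ear
canal pointing laterally (out of the head), the x-axis is parallel to the
temporal line pointing posteriorly, and the y-axis completes a right-handed
triad (pointing superiorly by convention).  Left-sided anatomies are
mirrored into the right-side convention so that both ears share one map
coordinate system.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import trimesh

logger = logging.getLogger(__name__)

__all__ = [
    "TriangleMesh",
    "AnatomyFrame",
    "PolarCoord",
    "to_frame",
    "from_frame",
    "load_mesh",
]


class EmptyMeshError(ValueError):
    """Raised when an operation receives a mesh with no faces."""


@dataclass
class TriangleMesh:
    """A triangulated surface in millimetres.

    Thin, validated wrapper around vertex/face arrays.  Degenerate
    (zero-area) faces are dropped at construction with a logged count;
    a mesh that becomes empty raises :class:`EmptyMeshError`.
    """

    vertices: np.ndarray
    faces: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if not np.isfinite(self.vertices).all():
            raise ValueError("mesh vertices contain non-finite coordinates")
        if self.faces.size and self.faces.max() >= len(self.vertices):
            raise ValueError("face index out of range")
        if self.faces.size and self.faces.min() < 0:
            raise ValueError("negative face index")
        self._drop_degenerate_faces()
        if len(self.faces) == 0:
            raise EmptyMeshError("empty mesh")
        self._cache: dict = {}

    def _drop_degenerate_faces(self) -> None:
        tri = self.vertices[self.faces]
        cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        area2 = np.linalg.norm(cross, axis=1)
        keep = area2 > 1e-12
        n_dropped = int((~keep).sum())
        if n_dropped:
            logger.info("dropped %d degenerate faces from mesh %r", n_dropped, self.name)
            self.faces = self.faces[keep]

    # -- derived quantities -------------------------------------------------

    @property
    def triangles(self) -> np.ndarray:
        """(n_faces, 3, 3) array of triangle corner coordinates."""
        if "triangles" not in self._cache:
            self._cache["triangles"] = self.vertices[self.faces]
        return self._cache["triangles"]

    @property
    def face_normals(self) -> np.ndarray:
        """Unit face normals following the winding order."""
        if "face_normals" not in self._cache:
            tri = self.triangles
            cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
            norm = np.linalg.norm(cross, axis=1, keepdims=True)
            self._cache["face_normals"] = cross / norm
        return self._cache["face_normals"]

    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces, process=False)

    @property
    def is_watertight(self) -> bool:
        return bool(self.as_trimesh().is_watertight)

    @property
    def volume(self) -> float:
        """Signed volume; positive for consistently outward-wound closed meshes."""
        return float(self.as_trimesh().volume)

    def bounds(self) -> np.ndarray:
        return np.array([self.vertices.min(axis=0), self.vertices.max(axis=0)])

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "TriangleMesh":
        """Rigidly transformed copy: v -> R v + t."""
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        return TriangleMesh(self.vertices @ R.T + t, self.faces.copy(), name=self.name)

    def mirrored_x(self) -> "TriangleMesh":
        """Mirror about the y-z plane, re-winding faces to keep orientation."""
        v = self.vertices.copy()
        v[:, 0] = -v[:, 0]
        f = self.faces[:, ::-1].copy()
        return TriangleMesh(v, f, name=self.name)

    # -- I/O ----------------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Write STL or PLY depending on the suffix."""
        self.as_trimesh().export(str(path))

    @classmethod
    def load(cls, path: str | Path, name: str | None = None,
             units: str | None = None) -> "TriangleMesh":
        """Load an STL or PLY surface.

        Meshes are assumed to be in millimetres.  A bounding-box diagonal
        below 1 suggests metres; such meshes are rejected unless
        ``units='mm'`` explicitly vouches for them (``units='m'`` scales
        by 1000).
        """
        # process=True merges the per-facet duplicate vertices STL stores,
        # restoring connectivity (and hence watertightness checks)
        tm = trimesh.load_mesh(str(path), process=True)
        if isinstance(tm, trimesh.Scene):
            tm = tm.to_mesh()
        v = np.asarray(tm.vertices, dtype=float)
        if units == "m":
            v = v * 1000.0
        elif units not in (None, "mm"):
            raise ValueError(f"unknown units {units!r}")
        diag = float(np.linalg.norm(v.max(axis=0) - v.min(axis=0))) if len(v) else 0.0
        if units is None and diag < 1.0:
            raise ValueError(
                f"mesh {path} has bounding-box diagonal {diag:.3g} < 1; "
                "looks like metres — pass units='m' or units='mm' explicitly"
            )
        return cls(v, np.asarray(tm.faces), name=name or Path(path).stem)


def load_mesh(path: str | Path, **kw) -> TriangleMesh:
    """Convenience alias for :meth:`TriangleMesh.load`."""
    return TriangleMesh.load(path, **kw)


@dataclass(frozen=True)
class PolarCoord:
    """In-plane polar coordinates of a point in the anatomy frame.

    ``r`` is the radial distance in the frame's x-y plane (mm); ``theta``
    the angle around the canal axis in degrees, measured from the x-axis
    (posterior) positive toward +y (superior), in (−180, 180]; ``x`` and
    ``y`` the signed in-plane coordinates.
    """

    r: float
    theta: float
    x: float
    y: float

    def __post_init__(self) -> None:
        if self.r < 0:
            raise ValueError("r must be non-negative")
        if not (-180.0 < self.theta <= 180.0):
            raise ValueError("theta must lie in (-180, 180]")


@dataclass(frozen=True)
class AnatomyFrame:
    """EAC-anchored coordinate frame of one temporal bone.

    ``origin`` sits at the centre of the external auditory canal,
    ``z_axis`` points laterally along the canal, ``x_axis`` posteriorly
    along the temporal line.  ``side`` selects whether local x is mirrored
    into the shared right-side convention.
    """

    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    z_axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    x_axis: tuple[float, float, float] = (1.0, 0.0, 0.0)
    side: str = "right"

    def __post_init__(self) -> None:
        z = np.asarray(self.z_axis, dtype=float)
        x = np.asarray(self.x_axis, dtype=float)
        if abs(np.linalg.norm(z) - 1.0) > 1e-9 or abs(np.linalg.norm(x) - 1.0) > 1e-9:
            raise ValueError("frame axes must be unit length")
        if abs(float(z @ x)) > 1e-6:
            raise ValueError("z_axis and x_axis must be orthogonal")
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")

    @property
    def y_axis(self) -> np.ndarray:
        return np.cross(self.z_axis, self.x_axis)

    @property
    def rotation(self) -> np.ndarray:
        """Rotation matrix with columns (x_axis, y_axis, z_axis)."""
        return np.column_stack([self.x_axis, self.y_axis, self.z_axis])

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "origin": list(map(float, self.origin)),
            "z_axis": list(map(float, self.z_axis)),
            "x_axis": list(map(float, self.x_axis)),
            "side": self.side,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AnatomyFrame":
        return cls(
            origin=tuple(d["origin"]),
            z_axis=tuple(d["z_axis"]),
            x_axis=tuple(d["x_axis"]),
            side=d.get("side", "right"),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "AnatomyFrame":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _polar_from_local(local: np.ndarray) -> PolarCoord:
    x, y = float(local[0]), float(local[1])
    r = math.hypot(x, y)
    # theta is undefined at the origin; fix it to 0 (avoids the
    # atan2(0, -0.0) = 180 signed-zero artifact after mirroring)
    theta = 0.0 if r == 0.0 else math.degrees(math.atan2(y, x))
    if theta <= -180.0:
        theta += 360.0
    return PolarCoord(r=r, theta=theta, x=x, y=y)


def to_frame(frame: AnatomyFrame, point: Sequence[float]) -> tuple[np.ndarray, PolarCoord]:
    """Express a world-space point in the anatomy frame.

    Returns the local Cartesian point (after mirroring for left-sided
    frames) and its in-plane polar coordinates.
    """
    p = np.asarray(point, dtype=float)
    local = frame.rotation.T @ (p - np.asarray(frame.origin, dtype=float))
    if frame.side == "left":
        local = local.copy()
        local[0] = -local[0]
    return local, _polar_from_local(local)


def to_frame_many(frame: AnatomyFrame, points: np.ndarray) -> np.ndarray:
    """Vectorised local coordinates (no polar) for an (n, 3) array."""
    p = np.asarray(points, dtype=float)
    local = (p - np.asarray(frame.origin, dtype=float)) @ frame.rotation
    if frame.side == "left":
        local = local.copy()
        local[:, 0] = -local[:, 0]
    return local


def from_frame(frame: AnatomyFrame, local: Sequence[float]) -> np.ndarray:
    """Inverse of :func:`to_frame` (un-mirrors left-sided frames)."""
    q = np.asarray(local, dtype=float).copy()
    if frame.side == "left":
        q[0] = -q[0]
    return frame.rotation @ q + np.asarray(frame.origin, dtype=float)
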