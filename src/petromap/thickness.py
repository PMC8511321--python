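"""Grid-projected cortical thickness (CLT) and dura distance (DDVS).

A regular grid in the anatomy frame's x-y plane is projected onto the
lateral (outer) surface of the bone along −z.  At each projected sample
the cortical layer thickness is the minimal distance to the nearest
"opposite" surface — the interior cortical wall or an air-cell wall — and
the DDVS is the minimal distance to the dura/venous-sinus mesh.

The opposite-surface criterion: candidate surface points q must lie in
the inward half-space, (q − p)·n̂ ≥ δ with n̂ the inward surface normal
and δ a small margin (default 0.05 mm) that prevents self-hits on the
sample's own outer-surface patch.  The distance is measured from the
probe point p + δ·n̂ and δ is added back, so a slab of thickness t reports
exactly t.  Values beyond ``max_thickness`` are censored at that cap:
far-field cortical measures are not meaningful for screw seating.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .geometry import AnatomyFrame, PolarCoord, TriangleMesh, to_frame_many, _polar_from_local
from .distance import MeshQuery, _moller_trumbore

__all__ = [
    "GridSpec",
    "SurfaceSample",
    "ThicknessMap",
    "CLTParams",
    "project_grid",
    "compute_clt",
    "compute_ddvs",
    "samples_to_map",
]


@dataclass(frozen=True)
class GridSpec:
    """Regular sampling grid in the frame's x-y plane (mm).

    ``extent`` is (xmin, xmax, ymin, ymax); projection is along −z.
    """

    spacing: float = 0.5
    extent: tuple[float, float, float, float] = (-50.0, 50.0, -50.0, 50.0)

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        xmin, xmax, ymin, ymax = self.extent
        if xmax <= xmin or ymax <= ymin:
            raise ValueError("extent must be a non-empty rectangle")

    @property
    def xs(self) -> np.ndarray:
        xmin, xmax, _, _ = self.extent
        n = int(math.floor((xmax - xmin) / self.spacing + 1e-9)) + 1
        return xmin + self.spacing * np.arange(n)

    @property
    def ys(self) -> np.ndarray:
        _, _, ymin, ymax = self.extent
        n = int(math.floor((ymax - ymin) / self.spacing + 1e-9)) + 1
        return ymin + self.spacing * np.arange(n)

    @property
    def shape(self) -> tuple[int, int]:
        return len(self.xs), len(self.ys)

    def to_dict(self) -> dict:
        return {"spacing": self.spacing, "extent": list(self.extent)}

    @classmethod
    def from_dict(cls, d: dict) -> "GridSpec":
        return cls(spacing=float(d["spacing"]), extent=tuple(d["extent"]))


@dataclass
class SurfaceSample:
    """One projected grid point on the outer bone surface (frame coords, mm)."""

    grid_index: tuple[int, int]
    position: Optional[np.ndarray] = None
    inward_normal: Optional[np.ndarray] = None
    polar: Optional[PolarCoord] = None
    clt: float = np.nan
    clt_censored: bool = False
    ddvs: float = np.nan
    region: Optional[str] = None
    valid: bool = False


@dataclass
class ThicknessMap:
    """A 2D metric map on the sampling grid; NaN marks missing cells."""

    metric: str                      # "CLT" or "DDVS"
    grid: np.ndarray                 # shape (nx, ny), mm
    spacing: float
    extent: tuple[float, float, float, float]
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        spec = GridSpec(self.spacing, tuple(self.extent))
        if self.grid.shape != spec.shape:
            raise ValueError(
                f"grid shape {self.grid.shape} inconsistent with extent/spacing {spec.shape}"
            )

    @property
    def spec(self) -> GridSpec:
        return GridSpec(self.spacing, tuple(self.extent))

    # -- I/O ----------------------------------------------------------------

    def save(self, prefix: str | Path) -> tuple[Path, Path]:
        """Write <prefix>.csv (grid values) and <prefix>.json (metadata)."""
        prefix = Path(prefix)
        csv_path = prefix.with_suffix(".csv")
        json_path = prefix.with_suffix(".json")
        np.savetxt(csv_path, self.grid, delimiter=",", fmt="%.9g",
                   header="rows: x index, cols: y index; frame-local mm (right-side convention)")
        json_path.write_text(json.dumps({
            "metric": self.metric,
            "spacing": self.spacing,
            "extent": list(self.extent),
            "subject_id": self.subject_id,
        }, indent=2) + "\n")
        return csv_path, json_path

    @classmethod
    def load(cls, prefix: str | Path) -> "ThicknessMap":
        prefix = Path(prefix)
        meta = json.loads(prefix.with_suffix(".json").read_text())
        grid = np.loadtxt(prefix.with_suffix(".csv"), delimiter=",", ndmin=2)
        return cls(metric=meta["metric"], grid=grid, spacing=meta["spacing"],
                   extent=tuple(meta["extent"]), subject_id=meta.get("subject_id", ""))

    def render_png(self, path: str | Path, vmax: float = 10.0) -> None:
        """Render with the fixed 0–``vmax`` mm colour scale used for all maps."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 5))
        xmin, xmax, ymin, ymax = self.extent
        im = ax.imshow(self.grid.T, origin="lower", vmin=0.0, vmax=vmax,
                       extent=(xmin, xmax, ymin, ymax), cmap="viridis")
        ax.set_xlabel("x (posterior, mm)")
        ax.set_ylabel("y (superior, mm)")
        ax.set_title(f"{self.metric} {self.subject_id}".strip())
        fig.colorbar(im, ax=ax, label=f"{self.metric} (mm)")
        fig.savefig(path, dpi=120)
        plt.close(fig)


@dataclass(frozen=True)
class CLTParams:
    """Tunables of the opposite-surface search."""

    delta: float = 0.05          # inward probe offset / self-hit margin (mm)
    max_thickness: float = 10.0  # censoring cap (mm)
    mode: str = "nearest"        # "nearest" (Euclidean minimum) or "ray" (along normal)

    def __post_init__(self) -> None:
        if self.mode not in ("nearest", "ray"):
            raise ValueError("mode must be 'nearest' or 'ray'")
        if self.delta <= 0 or self.max_thickness <= self.delta:
            raise ValueError("require 0 < delta < max_thickness")


def project_grid(bone: TriangleMesh, frame: AnatomyFrame, grid: GridSpec) -> list[SurfaceSample]:
    """Project grid nodes onto the bone's lateral surface along −z.

    The bone is first expressed in the anatomy frame (left sides are
    mirrored into the right-side convention).  Nodes whose vertical ray
    misses the mesh become invalid samples.
    """
    local = to_frame_many(frame, bone.vertices)
    faces = bone.faces[:, ::-1] if frame.side == "left" else bone.faces
    bone_local = TriangleMesh(local, faces, name=bone.name)
    return project_grid_local(bone_local, grid)


def project_grid_local(bone_local: TriangleMesh, grid: GridSpec) -> list[SurfaceSample]:
    """:func:`project_grid` for a bone already in frame coordinates."""
    query = MeshQuery(bone_local)
    xs, ys = grid.xs, grid.ys
    XX, YY = np.meshgrid(xs, ys, indexing="ij")
    xy = np.column_stack([XX.ravel(), YY.ravel()])
    z_start = float(bone_local.vertices[:, 2].max()) + 5.0
    hit, pts, face = query.first_hit_down(xy, z_start)
    if not hit.any():
        raise ValueError("mesh outside grid extent: no projection ray hits the bone")

    normals = bone_local.face_normals
    samples: list[SurfaceSample] = []
    nx, ny = grid.shape
    k = 0
    for i in range(nx):
        for j in range(ny):
            s = SurfaceSample(grid_index=(i, j))
            if hit[k]:
                n = normals[face[k]].copy()
                if n[2] < 0:          # orient toward +z (outward), then invert
                    n = -n
                s.position = pts[k]
                s.inward_normal = -n
                s.polar = _polar_from_local(pts[k])
                s.valid = True
            samples.append(s)
            k += 1
    return samples


def compute_clt(samples: Sequence[SurfaceSample], bone: TriangleMesh,
                params: CLTParams = CLTParams(),
                query: Optional[MeshQuery] = None) -> list[SurfaceSample]:
    """Fill ``clt`` on each valid sample (in place; returns the list).

    ``bone`` must be in the same (frame) coordinates as the samples.  In
    ``nearest`` mode the CLT is the exact minimal Euclidean distance from
    the probe point to any opposite-surface point; in ``ray`` mode it is
    the first intersection along the inward normal.
    """
    import warnings

    if query is None:
        query = MeshQuery(bone)
    if not bone.is_watertight:
        warnings.warn("bone mesh is not watertight; CLT is best-effort", stacklevel=2)

    delta = params.delta
    cap = params.max_thickness
    for s in samples:
        if not s.valid:
            continue
        p = s.position
        n = s.inward_normal
        probe = p + delta * n
        if params.mode == "nearest":
            d, _ = query.nearest_in_halfspace(probe, p, n, delta, max_dist=cap)
            if np.isfinite(d):
                value = d + delta
            else:
                # beyond the cap, or no opposite surface at all?
                qualifies = ((bone.vertices - p) @ n - delta >= 0).any()
                value = cap if qualifies else np.nan
        else:
            value = _ray_thickness(query, probe, n, cap)
            if np.isfinite(value):
                value = value + delta
        if np.isfinite(value) and value >= cap:
            s.clt = cap
            s.clt_censored = True
        else:
            s.clt = float(value)
            s.clt_censored = False
    return list(samples)


def _ray_thickness(query: MeshQuery, origin: np.ndarray, direction: np.ndarray,
                   cap: float) -> float:
    """First-hit distance along the inward normal, pruned to the cap length."""
    mid = origin + 0.5 * cap * direction
    cand = query._tree.query_ball_point(mid, 0.5 * cap + query._r_max + 1e-9)
    if not cand:
        return np.nan
    tris = query.mesh.triangles[np.asarray(cand, dtype=np.int64)]
    t, hit = _moller_trumbore(origin, direction, tris)
    if not hit.any():
        return np.nan
    return float(t.min())


def compute_ddvs(samples: Sequence[SurfaceSample], dura: TriangleMesh,
                 query: Optional[MeshQuery] = None) -> list[SurfaceSample]:
    """Fill ``ddvs``: minimal distance from each sample to the dura/sinus mesh."""
    if query is None:
        query = MeshQuery(dura)
    valid = [s for s in samples if s.valid]
    if valid:
        pts = np.array([s.position for s in valid])
        d, _ = query.nearest_many(pts)
        for s, di in zip(valid, d):
            s.ddvs = float(di)
    return list(samples)


def samples_to_map(samples: Sequence[SurfaceSample], metric: str,
                   grid: GridSpec, subject_id: str = "") -> ThicknessMap:
    """Arrange one metric of a sample list onto its grid (NaN = missing)."""
    key = metric.lower()
    if key not in ("clt", "ddvs"):
        raise ValueError("metric must be 'CLT' or 'DDVS'")
    arr = np.full(grid.shape, np.nan)
    for s in samples:
        if not s.valid:
            continue
        i, j = s.grid_index
        arr[i, j] = getattr(s, key)
    return ThicknessMap(metric=metric.upper(), grid=arr, spacing=grid.spacing,
                        extent=grid.extent, subject_id=subject_id)


def samples_to_dataframe(samples: Sequence[SurfaceSample]):
    """Long-format table of all samples (frame-local mm, degrees)."""
    import pandas as pd

    rows = []
    for s in samples:
        rows.append({
            "i": s.grid_index[0],
            "j": s.grid_index[1],
            "valid": s.valid,
            "x": s.position[0] if s.valid else np.nan,
            "y": s.position[1] if s.valid else np.nan,
            "z": s.position[2] if s.valid else np.nan,
            "r": s.polar.r if s.valid else np.nan,
            "theta": s.polar.theta if s.valid else np.nan,
            "region": s.region,
            "clt": s.clt,
            "clt_censored": s.clt_censored,
            "ddvs": s.ddvs,
        })
    return pd.DataFrame(rows)
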