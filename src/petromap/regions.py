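"""Region of interest and the seven anatomical regions of the lateral map.

All geometry lives in the anatomy frame's x-y plane (x posterior along
the temporal line, y superior, polar angle theta measured from +x toward
+y).  The region of interest (ROI) for screw placement is the angular
sector theta ∈ [−60°, +30°] between an inner radius of 15 mm and an outer
radius that grows linearly with theta from 15 mm at −60° to 50 mm at +30°.

Within the ROI seven regions are assigned:

* mastoid tip — y ≤ −8 mm and x ≥ −16 mm (no further than 16 mm anterior);
* mastoid — the 15–30 mm annulus strictly inferior to the −45° separating
  line (the line through the origin shifted 4 mm inferiorly);
* petrous pyramid — the 15 mm wide band centred on that same line, out to
  30 mm from the origin;
* parietal — the band's continuation beyond 30 mm and the posterior area
  superior to it;
* superior temporal surface — theta ∈ [0°, 30°] beyond 30 mm, superior to
  the band;
* middle fossa — the remaining superior area within 30 mm;
* retrosigmoid — the remaining postero-inferior area beyond the mastoid
  annulus.

Only the ROI bounds, the 15/30 mm radii, the 45° band with its 15 mm
thickness and −4 mm shift, and the mastoid-tip bounds are prescribed by
the mapping convention; the shapes of the superior temporal surface,
middle fossa and retrosigmoid regions are a reconstruction of the
published region sketch and are fully configurable.  Boundary ties are
broken by the fixed precedence mastoid tip > mastoid > petrous pyramid >
parietal > the rest, so labels are deterministic and exclusive.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

from .geometry import PolarCoord

__all__ = [
    "RegionConfig",
    "REGION_LABELS",
    "in_roi",
    "assign_region",
    "region_masks",
]

REGION_LABELS = (
    "superior_temporal_surface",
    "middle_fossa",
    "mastoid",
    "mastoid_tip",
    "petrous_pyramid",
    "parietal",
    "retrosigmoid",
    "outside_roi",
)


@dataclass(frozen=True)
class RegionConfig:
    """Parametric boundaries of the ROI and the seven regions (mm, degrees)."""

    # region of interest
    theta_min: float = -60.0
    theta_max: float = 30.0
    r_min: float = 15.0
    r_max_at_theta_max: float = 50.0
    r_max_at_theta_min: float = 15.0

    # mastoid annulus and the separating 45° line
    mastoid_r_outer: float = 30.0
    band_angle_deg: float = -45.0       # band axis direction from +x
    band_thickness: float = 15.0        # total width of the petrous band
    parietal_split_r: float = 30.0      # petrous/parietal split radius
    band_y_shift: float = -4.0          # band origin shift along y

    # mastoid tip bounds
    tip_y_max: float = -8.0
    tip_x_min: float = -16.0

    def __post_init__(self) -> None:
        if self.theta_min >= self.theta_max:
            raise ValueError("theta_min must be below theta_max")
        if self.r_min >= self.r_max_at_theta_max:
            raise ValueError("r_min must be below r_max_at_theta_max")
        if self.band_thickness <= 0:
            raise ValueError("band thickness must be positive")

    def r_max(self, theta: float) -> float:
        """Outer ROI radius at ``theta``: linear between the two anchors."""
        f = (theta - self.theta_min) / (self.theta_max - self.theta_min)
        return self.r_max_at_theta_min + f * (self.r_max_at_theta_max - self.r_max_at_theta_min)

    def band_signed_distance(self, x: float, y: float) -> float:
        """Signed perpendicular distance to the band axis (positive superior)."""
        phi = math.radians(self.band_angle_deg)
        # unit normal of the axis line, pointing toward the superior side
        nx, ny = -math.sin(phi), math.cos(phi)
        return nx * x + ny * (y - self.band_y_shift)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RegionConfig":
        return cls(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "RegionConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def in_roi(polar: PolarCoord, config: RegionConfig = RegionConfig()) -> bool:
    """Whether a point lies in the region of interest for screw placement."""
    if not (config.theta_min <= polar.theta <= config.theta_max):
        return False
    return config.r_min <= polar.r <= config.r_max(polar.theta)


def assign_region(polar: PolarCoord, config: RegionConfig = RegionConfig()) -> str:
    """Deterministic region label for one point (see module docstring).

    Precedence on boundary ties: mastoid tip > mastoid > petrous pyramid >
    parietal > superior temporal surface / middle fossa / retrosigmoid.
    """
    if not in_roi(polar, config):
        return "outside_roi"
    x, y, r, theta = polar.x, polar.y, polar.r, polar.theta
    if y <= config.tip_y_max and x >= config.tip_x_min:
        return "mastoid_tip"
    d = config.band_signed_distance(x, y)
    half = 0.5 * config.band_thickness
    # strictly inferior to the separating line, so the band axis itself
    # stays with the petrous pyramid
    if r <= config.mastoid_r_outer and d < 0.0:
        return "mastoid"
    if abs(d) <= half:
        return "petrous_pyramid" if r <= config.parietal_split_r else "parietal"
    if d > half:
        if r <= config.parietal_split_r:
            return "middle_fossa"
        return "superior_temporal_surface" if theta >= 0.0 else "parietal"
    # d < -half, r > mastoid_r_outer: postero-inferior remainder
    return "retrosigmoid"


def region_masks(samples: Sequence, config: RegionConfig = RegionConfig()) -> dict[str, np.ndarray]:
    """Index sets per region over a sample sequence.

    Accepts :class:`~petromap.thickness.SurfaceSample` objects (their
    ``region`` field is filled in place) or bare :class:`PolarCoord`.
    Invalid samples are skipped; the masks partition the valid ROI
    samples.
    """
    masks: dict[str, list[int]] = {label: [] for label in REGION_LABELS}
    for idx, s in enumerate(samples):
        polar = s if isinstance(s, PolarCoord) else s.polar
        if polar is None or (hasattr(s, "valid") and not s.valid):
            continue
        label = assign_region(polar, config)
        if hasattr(s, "region"):
            s.region = label
        masks[label].append(idx)
    return {label: np.asarray(ix, dtype=np.int64) for label, ix in masks.items()}
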