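"""Volume-of-interest construction from cephalometric landmarks and sub-ROIs.

The navigation VOI is bounded by eight user-supplied skull landmarks:
S (sella centre), N (frontonasal suture), Ba (anterior foramen magnum),
ANS and PNS (anterior/posterior nasal spine and hard palate), A (maxillary
symphysis) and the paired MX points (left and right maxillary/zygomatic
recess). The solid bounded by these points is realised as their axis-aligned
bounding box, rasterised by the voxel-centre rule over half-open intervals;
an explicit mask, when supplied, always takes precedence over the landmark
box.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import CTVolume, VOIMask

__all__ = [
    "LANDMARK_NAMES",
    "SINUS_NAMES",
    "LandmarkSet",
    "RegionSet",
    "landmarks_to_voi",
    "restrict",
]

LANDMARK_NAMES = ("S", "N", "Ba", "ANS", "PNS", "A", "MX_left", "MX_right")

#: Fixed Lund-Mackay sinus vocabulary: five sinus pairs.
SINUS_NAMES = tuple(
    f"{sinus}_{side}"
    for sinus in ("maxillary", "anterior_ethmoid", "posterior_ethmoid", "sphenoid", "frontal")
    for side in ("left", "right")
)

OMC_SIDES = ("left", "right")


@dataclass
class LandmarkSet:
    """The eight named cephalometric points, in patient-space mm."""

    points: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        missing = [n for n in LANDMARK_NAMES if n not in self.points]
        if missing:
            raise ValueError(f"missing landmarks: {', '.join(missing)}")
        self.points = {n: np.asarray(self.points[n], dtype=float) for n in LANDMARK_NAMES}
        for n, p in self.points.items():
            if p.shape != (3,) or not np.all(np.isfinite(p)):
                raise ValueError(f"landmark {n} must be a finite 3-D point, got {p}")
        # MX points must straddle the midsagittal plane through S-N
        # (approximated as the left-right coordinate of the S-N midline)
        mid_x = 0.5 * (self.points["S"][0] + self.points["N"][0])
        dl = self.points["MX_left"][0] - mid_x
        dr = self.points["MX_right"][0] - mid_x
        if dl * dr >= 0:
            raise ValueError(
                "MX_left and MX_right must lie on opposite sides of the "
                f"midsagittal plane (x = {mid_x:g} mm)"
            )

    def as_array(self) -> np.ndarray:
        return np.stack([self.points[n] for n in LANDMARK_NAMES])

    @classmethod
    def from_json(cls, path: str | Path) -> "LandmarkSet":
        with open(path) as fh:
            raw = json.load(fh)
        return cls({k: np.asarray(v, dtype=float) for k, v in raw.items()})

    @classmethod
    def from_csv(cls, path: str | Path) -> "LandmarkSet":
        """CSV columns: name, x_mm, y_mm, z_mm."""
        pts: dict[str, np.ndarray] = {}
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                pts[row["name"]] = np.array(
                    [float(row["x_mm"]), float(row["y_mm"]), float(row["z_mm"])]
                )
        return cls(pts)


@dataclass
class RegionSet:
    """The total VOI with optional per-sinus and OMC sub-ROIs.

    Sub-ROIs are intersected with the total VOI on construction so the
    subset invariant holds by force; sinus names must come from the fixed
    Lund-Mackay vocabulary and OMC sides from {left, right}.
    """

    total: VOIMask
    sinuses: dict[str, VOIMask] = field(default_factory=dict)
    omc: dict[str, VOIMask] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = [n for n in self.sinuses if n not in SINUS_NAMES]
        if bad:
            raise ValueError(f"unknown sinus names {bad}; expected one of {SINUS_NAMES}")
        bad = [s for s in self.omc if s not in OMC_SIDES]
        if bad:
            raise ValueError(f"unknown OMC sides {bad}; expected {OMC_SIDES}")
        self.sinuses = {n: restrict(m, self.total) for n, m in self.sinuses.items()}
        self.omc = {s: restrict(m, self.total) for s, m in self.omc.items()}

    @property
    def has_all_sinuses(self) -> bool:
        return all(n in self.sinuses for n in SINUS_NAMES)


def landmarks_to_voi(landmarks: LandmarkSet, grid: CTVolume) -> VOIMask:
    """Rasterise the axis-aligned bounding box of the landmarks onto the grid.

    A voxel is included iff its centre lies inside the half-open box
    ``[lo, hi)`` spanned by the landmark extremes on each axis. A landmark
    outside the grid's physical extent, or a box with zero extent on any
    axis, is an error.
    """
    pts = landmarks.as_array()
    lo = pts.min(axis=0)
    hi = pts.max(axis=0)
    for ax in range(3):
        ext_lo = grid.origin[ax] - 0.5 * grid.spacing[ax]
        ext_hi = grid.origin[ax] + (grid.shape[ax] - 0.5) * grid.spacing[ax]
        if lo[ax] < ext_lo or hi[ax] > ext_hi:
            raise ValueError(
                f"landmark extent [{lo[ax]:g}, {hi[ax]:g}] mm exceeds grid extent "
                f"[{ext_lo:g}, {ext_hi:g}] mm on axis {ax}"
            )
        if hi[ax] - lo[ax] <= 0:
            raise ValueError(f"degenerate landmark box: zero extent on axis {ax}")

    inside_1d = [
        (grid.voxel_centers(ax) >= lo[ax]) & (grid.voxel_centers(ax) < hi[ax])
        for ax in range(3)
    ]
    mask = (
        inside_1d[0][:, None, None]
        & inside_1d[1][None, :, None]
        & inside_1d[2][None, None, :]
    )
    return VOIMask(voxels=mask, spacing=grid.spacing, origin=grid.origin)


def restrict(region: VOIMask, container: VOIMask) -> VOIMask:
    """Voxelwise intersection of a sub-ROI with its containing VOI."""
    if not region.grid_matches(container):
        raise ValueError(
            f"grid mismatch: {region.shape}/{region.spacing} vs "
            f"{container.shape}/{container.spacing}"
        )
    return VOIMask(
        voxels=region.voxels & container.voxels,
        spacing=region.spacing,
        origin=region.origin,
    )
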