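"""HU-threshold voxel classification and first-order densitometric features.

Voxels inside a region of interest are assigned to one of three tissue
classes by Hounsfield-unit bands — air, soft tissue, bone — or marked
*excluded* when their HU falls outside the analysable window
[-2000, +2000] (metal artefacts, padding). The published bands are written
for integer HU (air up to -250, soft -249..+250, bone from +251); to make
the map total over float HU the bands are realised as contiguous half-open
intervals split at -249.5 and +250.5, which reproduces the integer
assignments exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np

from .io import CTVolume, VOIMask

__all__ = [
    "TissueLabel",
    "ThresholdScheme",
    "DEFAULT_SCHEME",
    "LabelVolume",
    "DensitometricProfile",
    "classify_voxels",
    "profile",
    "hu_histogram",
    "HIST_LO",
    "HIST_HI",
]

HIST_LO = -2000
HIST_HI = 2000


class TissueLabel(IntEnum):
    OUTSIDE = 0
    AIR = 1
    SOFT = 2
    BONE = 3
    EXCLUDED = 4


@dataclass(frozen=True)
class ThresholdScheme:
    """Contiguous HU bands: air [hu_min, air_soft), soft [air_soft, soft_bone),
    bone [soft_bone, hu_max]; anything outside [hu_min, hu_max] is excluded."""

    hu_min: float = -2000.0
    air_soft: float = -249.5
    soft_bone: float = 250.5
    hu_max: float = 2000.0

    def __post_init__(self) -> None:
        if not (self.hu_min < self.air_soft < self.soft_bone < self.hu_max):
            raise ValueError(
                f"threshold bands must be totally ordered air < soft < bone, got "
                f"{self.hu_min} < {self.air_soft} < {self.soft_bone} < {self.hu_max}"
            )


DEFAULT_SCHEME = ThresholdScheme()


@dataclass
class LabelVolume:
    """Per-voxel tissue labels on the CT grid (``TissueLabel`` values)."""

    labels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def counts(self) -> dict[str, int]:
        return {
            lab.name.lower(): int(np.count_nonzero(self.labels == lab))
            for lab in TissueLabel
        }


@dataclass
class DensitometricProfile:
    """Volumetric and densitometric summary of one region.

    Volumes are voxel counts times the voxel volume, in mm^3 (cm^3 mirrors
    via properties). ``pct_air``/``pct_soft`` use the patency-relevant
    air+soft denominator; the total-volume percentages are available under
    ``pct_air_total``/``pct_soft_total``. HU statistics and the per-1-HU
    histogram cover in-region, in-band voxels only.
    """

    n_air: int
    n_soft: int
    n_bone: int
    n_excluded: int
    voxel_volume_mm3: float
    hu_min: float
    hu_max: float
    hu_mean: float
    histogram: np.ndarray = field(repr=False)
    region_name: str = "total"

    @property
    def n_total(self) -> int:
        return self.n_air + self.n_soft + self.n_bone + self.n_excluded

    # --- volumes ---------------------------------------------------------
    @property
    def v_air_mm3(self) -> float:
        return self.n_air * self.voxel_volume_mm3

    @property
    def v_soft_mm3(self) -> float:
        return self.n_soft * self.voxel_volume_mm3

    @property
    def v_bone_mm3(self) -> float:
        return self.n_bone * self.voxel_volume_mm3

    @property
    def v_excluded_mm3(self) -> float:
        return self.n_excluded * self.voxel_volume_mm3

    @property
    def v_total_mm3(self) -> float:
        return self.n_total * self.voxel_volume_mm3

    @property
    def v_air_cm3(self) -> float:
        return self.v_air_mm3 / 1000.0

    @property
    def v_soft_cm3(self) -> float:
        return self.v_soft_mm3 / 1000.0

    @property
    def v_bone_cm3(self) -> float:
        return self.v_bone_mm3 / 1000.0

    @property
    def v_excluded_cm3(self) -> float:
        return self.v_excluded_mm3 / 1000.0

    @property
    def v_total_cm3(self) -> float:
        return self.v_total_mm3 / 1000.0

    # --- percentages -----------------------------------------------------
    @property
    def pct_air(self) -> float | None:
        """Percent air on the air+soft (patency) denominator."""
        denom = self.n_air + self.n_soft
        return 100.0 * self.n_air / denom if denom > 0 else None

    @property
    def pct_soft(self) -> float | None:
        denom = self.n_air + self.n_soft
        return 100.0 * self.n_soft / denom if denom > 0 else None

    @property
    def pct_air_total(self) -> float | None:
        return 100.0 * self.n_air / self.n_total if self.n_total > 0 else None

    @property
    def pct_soft_total(self) -> float | None:
        return 100.0 * self.n_soft / self.n_total if self.n_total > 0 else None

    @property
    def soft_fraction(self) -> float | None:
        """V_soft / (V_soft + V_air), the opacification fraction in [0, 1]."""
        denom = self.n_air + self.n_soft
        return self.n_soft / denom if denom > 0 else None

    def to_dict(self) -> dict:
        d = {
            "region_name": self.region_name,
            "n_air": self.n_air,
            "n_soft": self.n_soft,
            "n_bone": self.n_bone,
            "n_excluded": self.n_excluded,
            "n_total": self.n_total,
            "voxel_volume_mm3": self.voxel_volume_mm3,
            "hu_min": self.hu_min,
            "hu_max": self.hu_max,
            "hu_mean": self.hu_mean,
            "pct_air": self.pct_air,
            "pct_soft": self.pct_soft,
            "pct_air_total": self.pct_air_total,
            "pct_soft_total": self.pct_soft_total,
            "histogram": np.asarray(self.histogram).tolist(),
        }
        for name in ("air", "soft", "bone", "excluded", "total"):
            mm3 = getattr(self, f"v_{name}_mm3")
            d[f"v_{name}_mm3"] = mm3
            d[f"v_{name}_cm3"] = mm3 / 1000.0
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DensitometricProfile":
        return cls(
            n_air=int(d["n_air"]),
            n_soft=int(d["n_soft"]),
            n_bone=int(d["n_bone"]),
            n_excluded=int(d["n_excluded"]),
            voxel_volume_mm3=float(d["voxel_volume_mm3"]),
            hu_min=float(d["hu_min"]),
            hu_max=float(d["hu_max"]),
            hu_mean=float(d["hu_mean"]),
            histogram=np.asarray(d["histogram"], dtype=np.int64),
            region_name=d.get("region_name", "total"),
        )


def _check_region(ct: CTVolume, region: VOIMask) -> None:
    if not ct.grid_matches(region):
        raise ValueError(
            f"grid mismatch: CT shape {ct.shape} spacing {ct.spacing} vs "
            f"mask shape {region.shape} spacing {region.spacing}"
        )
    if region.empty_flag:
        raise ValueError("region mask has no foreground voxels; nothing to classify")


def classify_voxels(
    ct: CTVolume, region: VOIMask, scheme: ThresholdScheme = DEFAULT_SCHEME
) -> LabelVolume:
    """Assign every in-region voxel to air / soft / bone / excluded by HU band.

    Voxels outside the region are labelled ``OUTSIDE``. The labelling is
    deterministic and total: each in-region voxel gets exactly one label.
    """
    _check_region(ct, region)
    hu = ct.voxels
    labels = np.full(hu.shape, TissueLabel.OUTSIDE, dtype=np.uint8)
    m = region.voxels
    in_band = (hu >= scheme.hu_min) & (hu <= scheme.hu_max)
    labels[m & ~in_band] = TissueLabel.EXCLUDED
    labels[m & in_band & (hu < scheme.air_soft)] = TissueLabel.AIR
    labels[m & in_band & (hu >= scheme.air_soft) & (hu < scheme.soft_bone)] = TissueLabel.SOFT
    labels[m & in_band & (hu >= scheme.soft_bone)] = TissueLabel.BONE
    return LabelVolume(labels=labels, spacing=ct.spacing, origin=ct.origin)


def hu_histogram(ct: CTVolume, region: VOIMask) -> np.ndarray:
    """Integer-binned HU histogram over in-region, in-band voxels.

    Bin ``b`` (index ``b + 2000``) covers HU ``[b, b+1)`` for
    ``b in [-2000, 2000)``; the final bin also includes HU exactly +2000 so
    that counts sum to the in-band voxel count.
    """
    _check_region(ct, region)
    vals = ct.voxels[region.voxels]
    vals = vals[(vals >= HIST_LO) & (vals <= HIST_HI)]
    counts, _ = np.histogram(vals, bins=np.arange(HIST_LO, HIST_HI + 1))
    return counts


def profile(
    ct: CTVolume,
    region: VOIMask,
    scheme: ThresholdScheme = DEFAULT_SCHEME,
    region_name: str = "total",
) -> DensitometricProfile:
    """Extract the volumetric/densitometric profile of one region.

    Raises if every in-region voxel is excluded (no analysable HU content).
    """
    lab = classify_voxels(ct, region, scheme)
    m = region.voxels
    n_air = int(np.count_nonzero(lab.labels[m] == TissueLabel.AIR))
    n_soft = int(np.count_nonzero(lab.labels[m] == TissueLabel.SOFT))
    n_bone = int(np.count_nonzero(lab.labels[m] == TissueLabel.BONE))
    n_excl = int(np.count_nonzero(lab.labels[m] == TissueLabel.EXCLUDED))
    if n_air + n_soft + n_bone == 0:
        raise ValueError("all in-region voxels fall outside the analysable HU window")

    in_band = ct.voxels[m]
    in_band = in_band[(in_band >= scheme.hu_min) & (in_band <= scheme.hu_max)]
    hist = hu_histogram(ct, region)
    return DensitometricProfile(
        n_air=n_air,
        n_soft=n_soft,
        n_bone=n_bone,
        n_excluded=n_excl,
        voxel_volume_mm3=ct.voxel_volume_mm3,
        hu_min=float(in_band.min()),
        hu_max=float(in_band.max()),
        hu_mean=float(in_band.mean()),
        histogram=hist,
        region_name=region_name,
    )
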