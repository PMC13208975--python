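"""Seeded synthetic sinus CT phantoms with exact ground truth.

A phantom is a block of bone-density material containing air-filled
ellipsoidal cavities (five sinus pairs) and two small cuboid drainage
channels standing in for the ostiomeatal complexes. Each cavity is
partially filled with soft-tissue-density material from its inferior
extent upward ("gravity fill", mimicking mucosal thickening and retained
secretions) to a known fill fraction; per-voxel HU is drawn from a
per-class Gaussian and clipped to that class's HU band, so the noise-free
label of every voxel is recoverable exactly by HU thresholding and the
counted ground-truth volumes are exact.

Default HU model: air N(-1000, 30), soft tissue N(+40, 50), bone
N(+700, 100), clipped to [-2000, -250], [-249, +250] and [+251, +2000]
respectively. Default geometry: a 128^3 grid at 0.5 mm isotropic spacing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .densitometry import TissueLabel
from .io import CTVolume, VOIMask
from .voi import RegionSet, SINUS_NAMES

__all__ = [
    "HUModel",
    "Cavity",
    "Channel",
    "PhantomSpec",
    "CavityTruth",
    "PhantomTruth",
    "generate_phantom",
    "default_phantom_spec",
    "default_cohort",
    "nominal_overall_fraction",
]


@dataclass(frozen=True)
class HUModel:
    """Per-tissue-class HU mean/SD plus the clip band keeping noise in-class."""

    air_mean: float = -1000.0
    air_sd: float = 30.0
    soft_mean: float = 40.0
    soft_sd: float = 50.0
    bone_mean: float = 700.0
    bone_sd: float = 100.0
    air_band: tuple[float, float] = (-2000.0, -250.0)
    soft_band: tuple[float, float] = (-249.0, 250.0)
    bone_band: tuple[float, float] = (251.0, 2000.0)

    def __post_init__(self) -> None:
        if not (-2000.0 <= self.air_mean <= -250.0):
            raise ValueError(f"air mean {self.air_mean} outside the air HU band [-2000, -250]")
        if not (-250.0 < self.soft_mean <= 250.0):
            raise ValueError(f"soft mean {self.soft_mean} outside the soft HU band (-250, +250]")
        if not (250.0 < self.bone_mean <= 2000.0):
            raise ValueError(f"bone mean {self.bone_mean} outside the bone HU band (+250, +2000]")


@dataclass(frozen=True)
class Cavity:
    """An ellipsoidal air cavity: centre and semi-axes in mm."""

    name: str
    side: str
    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]
    fill_fraction: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.fill_fraction <= 1.0):
            raise ValueError(f"fill_fraction must lie in [0, 1], got {self.fill_fraction}")
        if any(a <= 0 for a in self.semi_axes):
            raise ValueError(f"semi-axes must be positive, got {self.semi_axes}")

    @property
    def region_name(self) -> str:
        return f"{self.name}_{self.side}"

    @property
    def analytic_volume_mm3(self) -> float:
        a, b, c = self.semi_axes
        return 4.0 / 3.0 * np.pi * a * b * c


@dataclass(frozen=True)
class Channel:
    """A small cuboid drainage channel (OMC stand-in): centre and edge lengths in mm."""

    side: str
    center: tuple[float, float, float]
    size: tuple[float, float, float]
    fill_fraction: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.fill_fraction <= 1.0):
            raise ValueError(f"fill_fraction must lie in [0, 1], got {self.fill_fraction}")
        if any(s <= 0 for s in self.size):
            raise ValueError(f"channel size must be positive, got {self.size}")

    @property
    def region_name(self) -> str:
        return f"omc_{self.side}"

    @property
    def analytic_volume_mm3(self) -> float:
        return float(np.prod(self.size))


@dataclass
class PhantomSpec:
    """Full description of one synthetic sinus phantom."""

    grid_shape: tuple[int, int, int] = (128, 128, 128)
    spacing: tuple[float, float, float] = (0.5, 0.5, 0.5)
    cavities: list[Cavity] = field(default_factory=list)
    omc_channels: list[Channel] = field(default_factory=list)
    hu_model: HUModel = field(default_factory=HUModel)
    seed: int = 0

    def __post_init__(self) -> None:
        extent = np.asarray(self.grid_shape) * np.asarray(self.spacing)
        for cav in self.cavities:
            c, s = np.asarray(cav.center), np.asarray(cav.semi_axes)
            if np.any(c - s < 0) or np.any(c + s > extent):
                raise ValueError(f"cavity {cav.region_name} does not fit inside the grid")
        for ch in self.omc_channels:
            c, s = np.asarray(ch.center), np.asarray(ch.size) / 2.0
            if np.any(c - s < 0) or np.any(c + s > extent):
                raise ValueError(f"channel {ch.region_name} does not fit inside the grid")

    # -- config round trip -------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        return cls(
            grid_shape=tuple(d.get("grid_shape", (128, 128, 128))),
            spacing=tuple(d.get("spacing", (0.5, 0.5, 0.5))),
            cavities=[
                Cavity(
                    name=c["name"],
                    side=c["side"],
                    center=tuple(c["center"]),
                    semi_axes=tuple(c["semi_axes"]),
                    fill_fraction=float(c["fill_fraction"]),
                )
                for c in d.get("cavities", [])
            ],
            omc_channels=[
                Channel(
                    side=c["side"],
                    center=tuple(c["center"]),
                    size=tuple(c["size"]),
                    fill_fraction=float(c["fill_fraction"]),
                )
                for c in d.get("omc_channels", [])
            ],
            hu_model=HUModel(**{k: tuple(v) if isinstance(v, list) else v
                                for k, v in d.get("hu_model", {}).items()}),
            seed=int(d.get("seed", 0)),
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "PhantomSpec":
        """Load a phantom configuration from YAML or JSON."""
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        return cls.from_dict(data)

    def save(self, path: str | Path) -> None:
        p = Path(path)
        if p.suffix in (".yaml", ".yml"):
            p.write_text(yaml.safe_dump(self.to_dict()))
        else:
            p.write_text(json.dumps(self.to_dict(), indent=2))


@dataclass
class CavityTruth:
    """Exact voxel bookkeeping for one cavity or channel."""

    n_air: int
    n_soft: int

    @property
    def n_voxels(self) -> int:
        return self.n_air + self.n_soft

    @property
    def realized_fraction(self) -> float:
        return self.n_soft / self.n_voxels


@dataclass
class PhantomTruth:
    """Noise-free labels, exact per-cavity counts and ground-truth scores."""

    labels: np.ndarray  # TissueLabel values per voxel
    cavities: dict[str, CavityTruth]
    channels: dict[str, CavityTruth]
    regions: RegionSet

    @property
    def n_air(self) -> int:
        return sum(t.n_air for t in self.cavities.values()) + sum(
            t.n_air for t in self.channels.values()
        )

    @property
    def n_soft(self) -> int:
        return sum(t.n_soft for t in self.cavities.values()) + sum(
            t.n_soft for t in self.channels.values()
        )

    @property
    def overall_fraction(self) -> float:
        """Ground-truth P(ABCD) over all cavities and channels."""
        return self.n_soft / (self.n_soft + self.n_air)

    def to_dict(self) -> dict:
        return {
            "overall_fraction": self.overall_fraction,
            "n_air": self.n_air,
            "n_soft": self.n_soft,
            "cavities": {
                k: {"n_air": t.n_air, "n_soft": t.n_soft, "realized_fraction": t.realized_fraction}
                for k, t in self.cavities.items()
            },
            "channels": {
                k: {"n_air": t.n_air, "n_soft": t.n_soft, "realized_fraction": t.realized_fraction}
                for k, t in self.channels.items()
            },
        }


# ---------------------------------------------------------------------------
# rasterisation helpers


def _voxel_centers(spec: PhantomSpec):
    axes = [np.arange(n) * s + 0.5 * s for n, s in zip(spec.grid_shape, spec.spacing)]
    return axes


def _ellipsoid_mask(spec: PhantomSpec, cav: Cavity) -> np.ndarray:
    x, y, z = _voxel_centers(spec)
    cx, cy, cz = cav.center
    ax, ay, az = cav.semi_axes
    u = ((x - cx) / ax) ** 2
    v = ((y - cy) / ay) ** 2
    w = ((z - cz) / az) ** 2
    return (u[:, None, None] + v[None, :, None] + w[None, None, :]) <= 1.0


def _cuboid_mask(spec: PhantomSpec, ch: Channel) -> np.ndarray:
    x, y, z = _voxel_centers(spec)
    inside = []
    for ax_centers, c, s in zip((x, y, z), ch.center, ch.size):
        inside.append((ax_centers >= c - s / 2.0) & (ax_centers < c + s / 2.0))
    return inside[0][:, None, None] & inside[1][None, :, None] & inside[2][None, None, :]


def _gravity_fill(mask: np.ndarray, fill_fraction: float) -> tuple[np.ndarray, int, int]:
    """Select the soft-filled voxels of a cavity, bottom (low z) first.

    Voxels are ordered by (z, y, x) and the first ``round(f * n)`` become
    soft tissue — the contiguous, gravity-like fill whose realized fraction
    is the closest achievable to the nominal one.
    """
    idx = np.argwhere(mask)
    n = idx.shape[0]
    if n == 0:
        raise ValueError("cavity rasterizes to zero voxels; fill fraction is unachievable")
    k = int(np.floor(fill_fraction * n + 0.5))
    k = min(max(k, 0), n)
    order = np.lexsort((idx[:, 0], idx[:, 1], idx[:, 2]))  # primary key: z, then y, x
    soft_idx = idx[order[:k]]
    soft = np.zeros_like(mask)
    if k:
        soft[soft_idx[:, 0], soft_idx[:, 1], soft_idx[:, 2]] = True
    return soft, k, n


def generate_phantom(spec: PhantomSpec) -> tuple[CTVolume, PhantomTruth]:
    """Render a phantom spec into a noisy HU volume plus exact ground truth.

    Identical specs (including seed) produce bit-identical output. Cavities
    and channels must be pairwise disjoint after rasterisation.
    """
    labels = np.full(spec.grid_shape, TissueLabel.BONE, dtype=np.uint8)
    occupied = np.zeros(spec.grid_shape, dtype=bool)

    cavity_truth: dict[str, CavityTruth] = {}
    channel_truth: dict[str, CavityTruth] = {}
    sinus_masks: dict[str, np.ndarray] = {}
    omc_masks: dict[str, np.ndarray] = {}

    structures = [(cav.region_name, _ellipsoid_mask(spec, cav), cav.fill_fraction, "cavity")
                  for cav in spec.cavities]
    structures += [(ch.region_name, _cuboid_mask(spec, ch), ch.fill_fraction, "channel")
                   for ch in spec.omc_channels]

    for name, mask, fill, kind in structures:
        if np.any(mask & occupied):
            raise ValueError(f"structure {name} overlaps a previously placed structure")
        occupied |= mask
        soft, k, n = _gravity_fill(mask, fill)
        labels[mask] = TissueLabel.AIR
        labels[soft] = TissueLabel.SOFT
        truth = CavityTruth(n_air=n - k, n_soft=k)
        if kind == "cavity":
            cavity_truth[name] = truth
            sinus_masks[name] = mask
        else:
            channel_truth[name] = truth
            omc_masks[name.removeprefix("omc_")] = mask

    # total VOI: bounding box of all structures, padded by 2 mm of bone wall
    idx = np.argwhere(occupied)
    if idx.size == 0:
        raise ValueError("phantom spec contains no cavities or channels")
    pad = np.ceil(2.0 / np.asarray(spec.spacing)).astype(int)
    lo = np.maximum(idx.min(axis=0) - pad, 0)
    hi = np.minimum(idx.max(axis=0) + pad + 1, np.asarray(spec.grid_shape))
    total = np.zeros(spec.grid_shape, dtype=bool)
    total[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = True

    # noisy HU, clipped so every voxel stays in its class's band
    rng = np.random.default_rng(spec.seed)
    hu = np.empty(spec.grid_shape, dtype=np.float32)
    m = spec.hu_model
    for lab, mean, sd, band in (
        (TissueLabel.AIR, m.air_mean, m.air_sd, m.air_band),
        (TissueLabel.SOFT, m.soft_mean, m.soft_sd, m.soft_band),
        (TissueLabel.BONE, m.bone_mean, m.bone_sd, m.bone_band),
    ):
        sel = labels == lab
        vals = rng.normal(mean, sd, size=int(sel.sum()))
        hu[sel] = np.clip(vals, band[0], band[1])

    # voxel centres sit at (i + 1/2) * spacing, so the grid covers [0, extent]
    origin = tuple(0.5 * s for s in spec.spacing)
    ct = CTVolume(voxels=hu, spacing=spec.spacing, origin=origin)

    def _mask(arr: np.ndarray) -> VOIMask:
        return VOIMask(voxels=arr, spacing=spec.spacing, origin=origin)

    regions = RegionSet(
        total=_mask(total),
        sinuses={k: _mask(v) for k, v in sinus_masks.items()},
        omc={k: _mask(v) for k, v in omc_masks.items()},
    )
    truth = PhantomTruth(
        labels=labels, cavities=cavity_truth, channels=channel_truth, regions=regions
    )
    return ct, truth


# ---------------------------------------------------------------------------
# default anatomy and cohort generation

#: Five sinus pairs: name -> (left centre mm, semi-axes mm) on the default
#: 64 mm cube; right side mirrors about the midline x = 32 mm.
_DEFAULT_GEOMETRY = {
    "maxillary": ((18.0, 24.0, 20.0), (8.0, 9.0, 10.0)),
    "anterior_ethmoid": ((26.0, 22.0, 38.0), (4.0, 5.0, 5.0)),
    "posterior_ethmoid": ((26.0, 34.0, 38.0), (4.0, 5.0, 5.0)),
    "sphenoid": ((26.0, 46.0, 34.0), (5.0, 6.0, 7.0)),
    "frontal": ((24.0, 20.0, 52.0), (6.0, 5.0, 6.0)),
}
_DEFAULT_OMC = {"left": ((30.0, 28.0, 32.0), (3.0, 3.0, 8.0))}
_MIDLINE_X = 32.0


def _mirror(center: tuple[float, float, float]) -> tuple[float, float, float]:
    return (2 * _MIDLINE_X - center[0], center[1], center[2])


def default_phantom_spec(
    fill_fraction: float = 0.5,
    omc_fill: float | None = None,
    grid_shape: tuple[int, int, int] = (128, 128, 128),
    spacing: tuple[float, float, float] = (0.5, 0.5, 0.5),
    per_cavity_fill: dict[str, float] | None = None,
    hu_model: HUModel | None = None,
    seed: int = 0,
) -> PhantomSpec:
    """The desk-scale default anatomy: 5 ellipsoidal sinus pairs + 2 OMC channels.

    ``fill_fraction`` applies to every structure unless overridden per
    region via ``per_cavity_fill`` (keys like ``"maxillary_left"``) or, for
    the channels, ``omc_fill``. Geometry is stated on a 64 mm cube and
    scaled to the requested grid extent.
    """
    scale = (np.asarray(grid_shape) * np.asarray(spacing)) / 64.0
    overrides = per_cavity_fill or {}
    cavities = []
    for name, (lcenter, semi) in _DEFAULT_GEOMETRY.items():
        for side, center in (("left", lcenter), ("right", _mirror(lcenter))):
            f = overrides.get(f"{name}_{side}", fill_fraction)
            cavities.append(
                Cavity(
                    name=name,
                    side=side,
                    center=tuple(float(v) for v in np.asarray(center) * scale),
                    semi_axes=tuple(float(v) for v in np.asarray(semi) * scale),
                    fill_fraction=float(f),
                )
            )
    channels = []
    (lcenter, size) = _DEFAULT_OMC["left"]
    for side, center in (("left", lcenter), ("right", _mirror(lcenter))):
        f = overrides.get(f"omc_{side}", omc_fill if omc_fill is not None else fill_fraction)
        channels.append(
            Channel(
                side=side,
                center=tuple(float(v) for v in np.asarray(center) * scale),
                size=tuple(float(v) for v in np.asarray(size) * scale),
                fill_fraction=float(f),
            )
        )
    return PhantomSpec(
        grid_shape=tuple(grid_shape),
        spacing=tuple(spacing),
        cavities=cavities,
        omc_channels=channels,
        hu_model=hu_model or HUModel(),
        seed=seed,
    )


def nominal_overall_fraction(spec: PhantomSpec) -> float:
    """Volume-weighted nominal fill fraction of a spec (analytic volumes)."""
    vols = [c.analytic_volume_mm3 for c in spec.cavities] + [
        ch.analytic_volume_mm3 for ch in spec.omc_channels
    ]
    fills = [c.fill_fraction for c in spec.cavities] + [
        ch.fill_fraction for ch in spec.omc_channels
    ]
    return float(np.average(fills, weights=vols))


def _beta_params(mean: float, concentration: float) -> tuple[float, float]:
    return mean * concentration, (1.0 - mean) * concentration


def default_cohort(
    n_patients: int,
    effect: tuple[float, float] = (0.68, 0.52),
    seed: int = 0,
    grid_shape: tuple[int, int, int] = (128, 128, 128),
    spacing: tuple[float, float, float] = (0.5, 0.5, 0.5),
    pre_concentration: float = 10.0,
    cavity_concentration: float = 60.0,
    response_concentration: float = 20.0,
    response_ceiling: float = 1.25,
) -> list[tuple[PhantomSpec, PhantomSpec]]:
    """Paired pre/post phantom specs emulating a before-and-after cohort.

    Each patient's pre-treatment opacification fraction is drawn from a Beta
    distribution with mean ``effect[0]``; the post-treatment fraction is the
    pre fraction times a Beta-distributed response factor with mean
    ``effect[1]/effect[0]`` and support ``(0, response_ceiling)``, so most
    patients improve but a few may slightly worsen. Per-cavity fills are
    Beta-jittered around the patient fraction. Deterministic under ``seed``.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be at least 1")
    pre_mean, post_mean = effect
    if not (0 < pre_mean < 1 and 0 < post_mean < 1):
        raise ValueError(f"effect means must lie in (0, 1), got {effect}")

    factor_mean = post_mean / pre_mean
    if not (0 < factor_mean < response_ceiling):
        raise ValueError("post/pre ratio incompatible with the response ceiling")

    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    phantom_seeds = rng.integers(0, 2**31 - 1, size=2 * n_patients)

    pairs: list[tuple[PhantomSpec, PhantomSpec]] = []
    region_names = list(SINUS_NAMES) + ["omc_left", "omc_right"]
    for i in range(n_patients):
        a, b = _beta_params(pre_mean, pre_concentration)
        patient_pre = float(rng.beta(a, b))
        a, b = _beta_params(factor_mean / response_ceiling, response_concentration)
        factor = float(rng.beta(a, b)) * response_ceiling
        patient_post = float(np.clip(patient_pre * factor, 0.0, 1.0))

        specs = []
        for j, frac in enumerate((patient_pre, patient_post)):
            frac = float(np.clip(frac, 1e-3, 1 - 1e-3))
            a, b = _beta_params(frac, cavity_concentration)
            fills = {name: float(rng.beta(a, b)) for name in region_names}
            specs.append(
                default_phantom_spec(
                    fill_fraction=frac,
                    per_cavity_fill=fills,
                    grid_shape=grid_shape,
                    spacing=spacing,
                    seed=int(phantom_seeds[2 * i + j]),
                )
            )
        pairs.append((specs[0], specs[1]))
    return pairs
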