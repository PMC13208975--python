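"""Reading and writing CT volumes, region masks and result records.

CT volumes are handled in patient-space millimetres with array axes ordered
``(x, y, z)``. Hounsfield units are stored as 32-bit float after calibration
(DICOM rescale slope/intercept, NIfTI scl fields) has been applied exactly
once. NIfTI inputs are reoriented to the closest RAS-canonical frame so that
masks and volumes written by this package line up voxel-for-voxel.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable

import nibabel as nib
import numpy as np
import pandas as pd
import pydicom

SCHEMA_VERSION = "1.0"

__all__ = [
    "CTVolume",
    "VOIMask",
    "read_ct",
    "read_mask",
    "write_nifti",
    "write_result",
    "read_result",
    "SCHEMA_VERSION",
]


@dataclass
class CTVolume:
    """A calibrated 3-D Hounsfield-unit volume on a regular grid.

    Parameters
    ----------
    voxels:
        3-D float array of HU values, axes ordered ``(x, y, z)``.
    spacing:
        Voxel edge lengths in mm, one per axis; strictly positive.
    origin:
        Physical position (mm) of the centre of voxel ``(0, 0, 0)``.
    axes_order:
        Named axis convention tag; this package always uses ``"xyz"``.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axes_order: str = "xyz"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float32)
        if self.voxels.ndim != 3:
            raise ValueError(f"CT volume must be 3-D, got shape {self.voxels.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three strictly positive values, got {self.spacing}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("CT volume contains non-finite HU values after calibration")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def voxel_centers(self, axis: int) -> np.ndarray:
        """Physical coordinates (mm) of voxel centres along one axis."""
        return self.origin[axis] + np.arange(self.shape[axis]) * self.spacing[axis]

    def grid_matches(self, other: "CTVolume | VOIMask") -> bool:
        return self.shape == other.shape and np.allclose(self.spacing, other.spacing)


@dataclass
class VOIMask:
    """A binary volume-of-interest mask on the same grid as its CT volume."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    empty_flag: bool = field(init=False, default=False)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels) != 0
        if self.voxels.ndim != 3:
            raise ValueError(f"mask must be 3-D, got shape {self.voxels.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        self.empty_flag = not bool(self.voxels.any())

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    @property
    def foreground_count(self) -> int:
        return int(self.voxels.sum())

    def grid_matches(self, other: "CTVolume | VOIMask") -> bool:
        return self.shape == other.shape and np.allclose(self.spacing, other.spacing)


# ---------------------------------------------------------------------------
# readers


def _read_nifti(path: Path) -> CTVolume:
    img = nib.load(str(path))
    if len(img.shape) != 3:
        raise ValueError(
            f"expected a 3-D scalar NIfTI volume, got shape {tuple(img.shape)} from {path}"
        )
    img = nib.as_closest_canonical(img)
    # get_fdata applies scl_slope/scl_inter exactly once
    data = np.asarray(img.get_fdata(dtype=np.float32))
    zooms = img.header.get_zooms()[:3]
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return CTVolume(voxels=data, spacing=tuple(float(z) for z in zooms), origin=origin)


def _read_dicom_dir(path: Path) -> CTVolume:
    datasets = []
    for f in sorted(path.iterdir()):
        if not f.is_file():
            continue
        try:
            ds = pydicom.dcmread(str(f))
        except Exception:
            continue
        if not hasattr(ds, "PixelData"):
            continue
        datasets.append(ds)
    if not datasets:
        raise ValueError(f"no readable DICOM slices found in {path}")

    uids = sorted({str(ds.SeriesInstanceUID) for ds in datasets})
    if len(uids) > 1:
        raise ValueError(f"directory mixes multiple DICOM series: {', '.join(uids)}")

    for ds in datasets:
        if "RescaleSlope" not in ds or "RescaleIntercept" not in ds:
            raise ValueError(
                "DICOM slice is missing RescaleSlope/RescaleIntercept; "
                "refusing to assume an identity calibration"
            )

    iop = np.asarray(datasets[0].ImageOrientationPatient, dtype=float)
    normal = np.cross(iop[:3], iop[3:])
    # sort slices by their position along the slice normal, not by filename
    datasets.sort(key=lambda ds: float(np.dot(np.asarray(ds.ImagePositionPatient, float), normal)))

    positions = np.array(
        [np.dot(np.asarray(ds.ImagePositionPatient, float), normal) for ds in datasets]
    )
    if len(datasets) > 1:
        dz = float(np.median(np.diff(positions)))
        if dz <= 0:
            raise ValueError("DICOM slices do not advance along the slice normal")
    else:
        dz = float(getattr(datasets[0], "SliceThickness", 1.0))

    row_spacing, col_spacing = (float(v) for v in datasets[0].PixelSpacing)
    slices = []
    for ds in datasets:
        hu = ds.pixel_array.astype(np.float32) * float(ds.RescaleSlope) + float(
            ds.RescaleIntercept
        )
        # pixel_array is (rows, cols) == (y, x); transpose to (x, y)
        slices.append(hu.T)
    vol = np.stack(slices, axis=-1)
    origin = tuple(float(v) for v in datasets[0].ImagePositionPatient)
    return CTVolume(voxels=vol, spacing=(col_spacing, row_spacing, dz), origin=origin)


def read_ct(path: str | Path, format: str | None = None) -> CTVolume:
    """Read a CT volume from a NIfTI file or a DICOM series directory.

    ``format`` may be ``"nifti"`` or ``"dicom_dir"``; when omitted it is
    inferred from the path (directory -> DICOM series, file -> NIfTI).
    HU calibration is applied during reading; the returned volume never
    needs a second rescale.
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"no such path: {p}")
    if format is None:
        format = "dicom_dir" if p.is_dir() else "nifti"
    if format == "nifti":
        return _read_nifti(p)
    if format == "dicom_dir":
        return _read_dicom_dir(p)
    raise ValueError(f"unknown format {format!r}; expected 'nifti' or 'dicom_dir'")


def read_mask(path: str | Path, reference: CTVolume) -> VOIMask:
    """Read a binary mask (NIfTI) and check it against a reference grid.

    Any nonzero voxel is foreground. An all-zero mask is returned with its
    ``empty_flag`` set (scoring an empty region raises later); a shape
    mismatch is an immediate error.
    """
    img = nib.load(str(Path(path)))
    if len(img.shape) != 3:
        raise ValueError(f"expected a 3-D mask, got shape {tuple(img.shape)}")
    img = nib.as_closest_canonical(img)
    data = np.asarray(img.dataobj)
    if data.shape != reference.shape:
        raise ValueError(
            f"mask shape {tuple(data.shape)} does not match CT shape {tuple(reference.shape)}"
        )
    mask = VOIMask(voxels=data, spacing=reference.spacing, origin=reference.origin)
    if mask.empty_flag:
        warnings.warn(f"mask {path} has no foreground voxels", stacklevel=2)
    return mask


# ---------------------------------------------------------------------------
# writers


def write_nifti(obj: CTVolume | VOIMask, path: str | Path) -> None:
    """Write a CT volume (float32) or mask (uint8) as NIfTI-1."""
    affine = np.eye(4)
    affine[0, 0], affine[1, 1], affine[2, 2] = obj.spacing
    affine[:3, 3] = obj.origin
    if isinstance(obj, VOIMask):
        data = obj.voxels.astype(np.uint8)
    else:
        data = obj.voxels.astype(np.float32)
    nib.save(nib.Nifti1Image(data, affine), str(path))


def _flatten_for_csv(d: dict[str, Any]) -> dict[str, Any]:
    out: dict[str, Any] = {}
    for k, v in d.items():
        if isinstance(v, dict):
            for kk, vv in _flatten_for_csv(v).items():
                out[f"{k}.{kk}"] = vv
        elif isinstance(v, (list, tuple)):
            continue  # arrays (histograms, per-subject vectors) stay JSON-only
        else:
            out[k] = v
    return out


def write_result(record: Any, path: str | Path, format: str = "json") -> None:
    """Serialize a result record (anything with ``to_dict``) to JSON or a CSV row.

    Volumes appear under both mm^3 and cm^3 keys; floats are written at full
    precision; every record carries ``schema_version``.
    """
    if hasattr(record, "to_dict"):
        payload = record.to_dict()
    elif isinstance(record, dict):
        payload = dict(record)
    else:
        raise TypeError(f"cannot serialize record of type {type(record).__name__}")
    payload["schema_version"] = SCHEMA_VERSION
    payload.setdefault("record_type", type(record).__name__)

    p = Path(path)
    if format == "json":
        with open(p, "w") as fh:
            json.dump(payload, fh, indent=2, default=_json_default)
    elif format == "csv_row":
        row = _flatten_for_csv(payload)
        df = pd.DataFrame([row])
        header = not p.exists()
        df.to_csv(p, mode="a", header=header, index=False)
    else:
        raise ValueError(f"unknown format {format!r}; expected 'json' or 'csv_row'")


def write_cohort_csv(records: Iterable[Any], path: str | Path) -> None:
    """Write one CSV row per record."""
    for r in records:
        write_result(r, path, format="csv_row")


def _json_default(obj: Any) -> Any:
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def read_result(path: str | Path) -> dict[str, Any]:
    """Read back a JSON result record as a plain dict."""
    with open(path) as fh:
        return json.load(fh)
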