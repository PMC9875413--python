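"""Volumetric scan containers, SUV conversion, and NIfTI I/O.

A :class:`ScanVolume` holds a 3D intensity grid — PET activity in kBq/mL,
dimensionless SUV, or a CT-like density — together with its voxel spacing
and the acquisition metadata needed downstream (injected dose, body
weight). A :class:`RoiMask` is a binary tumor mask on the same grid.

The axis convention throughout the package is (z, y, x) with 0-based
indices; phantoms and masks share one grid, so world coordinates beyond
``spacing_mm`` are never needed. Images and masks are written as NIfTI
(``.nii`` / ``.nii.gz``) with a JSON sidecar carrying the scan metadata.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "ScanVolume",
    "RoiMask",
    "MetadataError",
    "AlignmentError",
    "to_suv",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
]

#: minimum foreground voxels for texture analysis to be meaningful
MIN_ROI_VOXELS = 27


class MetadataError(ValueError):
    """A required metadata field is missing or non-positive."""


class AlignmentError(ValueError):
    """Image and mask grids disagree in shape or spacing."""


@dataclass
class ScanVolume:
    """A 3D intensity grid with voxel spacing and acquisition metadata.

    Parameters
    ----------
    voxels : ndarray, shape (nz, ny, nx)
        Intensity grid. PET activity is kBq/mL and must be non-negative;
        SUV is dimensionless; CT carries an HU-like density.
    spacing_mm : tuple of float
        Per-axis voxel spacing (z, y, x), strictly positive.
    modality : {"PET", "CT"}
    unit : str
        ``"kBq/mL"``, ``"SUV"`` or ``"HU"``.
    meta : dict
        Acquisition metadata; PET scans destined for SUV conversion need
        ``injected_dose_MBq`` and ``body_weight_g``. ``subject_id`` and
        ``day`` are carried through when present.
    """

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float]
    modality: str = "PET"
    unit: str = "kBq/mL"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected a 3D grid, got ndim={self.voxels.ndim}")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be three positive floats, got {self.spacing_mm}")
        if self.modality not in ("PET", "CT"):
            raise ValueError(f"modality must be 'PET' or 'CT', got {self.modality!r}")
        if self.modality == "PET" and np.any(self.voxels < 0):
            raise ValueError("PET activity/SUV must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))


@dataclass
class RoiMask:
    """Binary tumor mask aligned to a :class:`ScanVolume`."""

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels)
        if vox.ndim != 3:
            raise ValueError(f"expected a 3D mask, got ndim={vox.ndim}")
        if not np.isin(vox, (0, 1)).all():
            raise ValueError("mask must be strictly binary")
        self.voxels = vox.astype(bool)
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.sum())

    def check_aligned(self, scan: ScanVolume) -> None:
        if self.shape != scan.shape:
            raise AlignmentError(
                f"mask shape {self.shape} does not match scan shape {scan.shape}"
            )
        if not np.allclose(self.spacing_mm, scan.spacing_mm):
            raise AlignmentError(
                f"mask spacing {self.spacing_mm} does not match scan spacing {scan.spacing_mm}"
            )


def to_suv(scan: ScanVolume) -> ScanVolume:
    """Convert a PET activity image (kBq/mL) to standardized uptake values.

    SUV normalizes the activity concentration to the injected FDG dose per
    gram of body weight (1 g of tissue taken as 1 mL)::

        SUV = activity[kBq/mL] * body_weight[g] / injected_dose[kBq]

    No decay correction between injection and acquisition is applied.

    Raises
    ------
    MetadataError
        If ``injected_dose_MBq`` or ``body_weight_g`` is absent or
        non-positive, naming the offending field.
    """
    if scan.modality != "PET":
        raise ValueError("SUV conversion is defined for PET scans only")
    if scan.unit == "SUV":
        return scan
    for key in ("injected_dose_MBq", "body_weight_g"):
        value = scan.meta.get(key)
        if value is None:
            raise MetadataError(f"missing metadata field {key!r} required for SUV conversion")
        if not np.isfinite(value) or value <= 0:
            raise MetadataError(f"metadata field {key!r} must be positive, got {value}")
    dose_kbq = scan.meta["injected_dose_MBq"] * 1000.0
    suv = scan.voxels * scan.meta["body_weight_g"] / dose_kbq
    return replace(scan, voxels=suv, unit="SUV", meta=dict(scan.meta))


# --------------------------------------------------------------------------
# NIfTI I/O with a JSON metadata sidecar


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def write_volume(scan: ScanVolume, path: str | Path) -> None:
    """Write a scan as NIfTI plus a JSON sidecar with its metadata."""
    path = Path(path)
    affine = np.diag(list(scan.spacing_mm[::-1]) + [1.0])
    img = nib.Nifti1Image(
        np.asarray(scan.voxels, dtype=np.float32).transpose(2, 1, 0), affine
    )
    img.header.set_zooms(scan.spacing_mm[::-1])
    nib.save(img, str(path))
    sidecar = {"modality": scan.modality, "unit": scan.unit, **scan.meta}
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2, sort_keys=True))


def read_volume(path: str | Path) -> ScanVolume:
    """Read a NIfTI scan written by :func:`write_volume`.

    The sidecar is optional: a scan without one loads with empty metadata
    and fails later, at SUV conversion, if dose/weight are then required.
    """
    path = Path(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=np.float64).transpose(2, 1, 0)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3][::-1])
    meta: dict = {}
    modality, unit = "PET", "kBq/mL"
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        modality = meta.pop("modality", modality)
        unit = meta.pop("unit", unit)
    return ScanVolume(voxels=data, spacing_mm=spacing, modality=modality, unit=unit, meta=meta)


def write_mask(mask: RoiMask, path: str | Path) -> None:
    path = Path(path)
    affine = np.diag(list(mask.spacing_mm[::-1]) + [1.0])
    img = nib.Nifti1Image(mask.voxels.astype(np.uint8).transpose(2, 1, 0), affine)
    img.header.set_zooms(mask.spacing_mm[::-1])
    nib.save(img, str(path))


def read_mask(path: str | Path, reference: ScanVolume | None = None) -> RoiMask:
    """Read a binary ROI mask; verify alignment against ``reference`` if given."""
    path = Path(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).transpose(2, 1, 0)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3][::-1])
    mask = RoiMask(voxels=(data > 0).astype(np.uint8), spacing_mm=spacing)
    if reference is not None:
        mask.check_aligned(reference)
    return mask
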