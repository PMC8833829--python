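"""PET volume I/O and SUV conversion.

Volumes are stored as plain NIfTI-1 images whose header carries the voxel
spacing; acquisition metadata (injected activity, body weight, scanner) that
NIfTI has no standard slot for travels in a JSON sidecar next to the image
(``<name>.json`` for ``<name>.nii`` / ``<name>.nii.gz``).

SUV normalization follows the body-weight convention

    SUV = (tissue activity [Bq] / tissue weight [g]) / (injected activity [Bq] / body weight [g])

with tissue weight obtained from the stored activity concentration (Bq/mL)
through a fixed tissue density of 1 g/mL, so SUV is dimensionless. No decay
correction is applied here: volumes are assumed decay-corrected upstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "ValidationError",
    "VolumeFormatError",
    "VolumeMeta",
    "PetVolume",
    "SuvVolume",
    "read_volume",
    "write_volume",
    "compute_suv",
]

SIDECAR_KEYS = ("injected_activity_bq", "body_weight_g", "scanner")


class ValidationError(ValueError):
    """An input violates a documented precondition or invariant."""


class VolumeFormatError(ValueError):
    """A file is not a volume this package can read (e.g. not 3-D)."""


@dataclass(frozen=True)
class VolumeMeta:
    """Acquisition metadata required for SUV normalization.

    Parameters
    ----------
    injected_activity_bq : float
        Net injected [18F]FDG activity in Bq.
    body_weight_g : float
        Patient (or phantom) weight in grams.
    scanner : str
        Scanner/batch label (e.g. ``"DST"``, ``"D690"``, ``"DIQ5"``).
    """

    injected_activity_bq: float
    body_weight_g: float
    scanner: str = "unknown"

    def __post_init__(self) -> None:
        if not self.injected_activity_bq > 0:
            raise ValidationError("injected_activity_bq must be > 0")
        if not self.body_weight_g > 0:
            raise ValidationError("body_weight_g must be > 0")


@dataclass(frozen=True)
class PetVolume:
    """3-D activity-concentration grid (Bq/mL) on a physical voxel lattice."""

    grid: np.ndarray
    spacing: tuple[float, float, float]
    meta: VolumeMeta

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        if grid.ndim != 3:
            raise VolumeFormatError(f"expected a 3-D grid, got ndim={grid.ndim}")
        if np.any(grid < 0):
            raise ValidationError("activity concentration must be non-negative")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValidationError(f"spacing must be three positive lengths, got {spacing}")
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "spacing", spacing)

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in mL (= cm^3)."""
        sx, sy, sz = self.spacing
        return sx * sy * sz / 1000.0


@dataclass(frozen=True)
class SuvVolume:
    """3-D SUV grid (dimensionless) sharing the source volume's lattice."""

    grid: np.ndarray
    spacing: tuple[float, float, float]
    meta: VolumeMeta

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        if grid.ndim != 3:
            raise VolumeFormatError(f"expected a 3-D grid, got ndim={grid.ndim}")
        if np.any(grid < 0):
            raise ValidationError("SUV must be non-negative")
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))

    @property
    def voxel_volume_ml(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz / 1000.0


def sidecar_path(path: str | Path) -> Path:
    """Path of the JSON metadata sidecar for a NIfTI file."""
    path = Path(path)
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def read_volume(path: str | Path) -> PetVolume:
    """Read a NIfTI activity volume and its JSON sidecar.

    Raises
    ------
    FileNotFoundError
        If the image or sidecar is missing.
    VolumeFormatError
        If the image is not 3-D.
    ValidationError
        If a required sidecar key is absent, naming the missing key.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise VolumeFormatError(f"{path}: expected 3-D volume, got shape {data.shape}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])

    side = sidecar_path(path)
    if not side.exists():
        raise FileNotFoundError(side)
    meta_raw = json.loads(side.read_text())
    for key in SIDECAR_KEYS[:2]:
        if key not in meta_raw:
            raise ValidationError(f"sidecar {side} is missing required key {key!r}")
    meta = VolumeMeta(
        injected_activity_bq=float(meta_raw["injected_activity_bq"]),
        body_weight_g=float(meta_raw["body_weight_g"]),
        scanner=str(meta_raw.get("scanner", "unknown")),
    )
    return PetVolume(grid=data.astype(float), spacing=spacing, meta=meta)


def write_volume(vol: PetVolume, path: str | Path) -> Path:
    """Write a volume as NIfTI (float64) plus its JSON sidecar."""
    path = Path(path)
    affine = np.diag([*vol.spacing, 1.0])
    img = nib.Nifti1Image(vol.grid.astype(np.float64), affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))
    side = sidecar_path(path)
    side.write_text(
        json.dumps(
            {
                "injected_activity_bq": vol.meta.injected_activity_bq,
                "body_weight_g": vol.meta.body_weight_g,
                "scanner": vol.meta.scanner,
            },
            indent=2,
        )
    )
    return path


def compute_suv(vol: PetVolume, tissue_density: float = 1.0) -> SuvVolume:
    """Convert an activity-concentration volume to SUV.

    Per voxel: ``SUV = (concentration / density) / (injected_activity / body_weight)``.
    With the default density of 1 g/mL this is the body-weight SUV.
    """
    if not tissue_density > 0:
        raise ValidationError("tissue_density must be > 0")
    norm = vol.meta.injected_activity_bq / vol.meta.body_weight_g
    suv = (vol.grid / tissue_density) / norm
    return SuvVolume(grid=suv, spacing=vol.spacing, meta=vol.meta)
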