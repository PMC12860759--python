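"""Image containers with physical spacing, and NIfTI round-tripping.

The analyses operate on a single axial CT or PET slice (2-D, Hounsfield
units or SUV g/mL) or on a PET volume (3-D, SUV g/mL).  Physical pixel /
voxel spacing is data carried alongside the arrays, never hard-coded:
texture scales and metabolic volumes are defined in millimetres, not
pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np

__all__ = [
    "Modality",
    "PlanarImage",
    "VolumeImage",
    "Mask",
    "load_planar_nifti",
    "save_planar_nifti",
    "load_volume_nifti",
    "save_volume_nifti",
]


class Modality:
    CT = "CT"
    PET = "PET"


def _check_spacing(spacing: Sequence[float], ndim: int) -> tuple[float, ...]:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != ndim:
        raise ValueError(f"expected {ndim} spacing entries, got {len(spacing)}")
    if any(not np.isfinite(s) or s <= 0 for s in spacing):
        raise ValueError(f"spacing must be positive and finite, got {spacing}")
    return spacing


@dataclass(frozen=True)
class PlanarImage:
    """A 2-D image slice with per-axis physical spacing in mm.

    ``modality`` is ``"CT"`` (values in HU) or ``"PET"`` (values in SUV
    g/mL); downstream operations use it to decide whether the HU exclusion
    window and LoG filtration apply.
    """

    values: np.ndarray
    pixel_spacing_mm: tuple[float, float]
    modality: str = Modality.CT

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError(f"PlanarImage requires a 2-D array, got ndim={values.ndim}")
        if not np.all(np.isfinite(values)):
            raise ValueError("PlanarImage values must be finite")
        object.__setattr__(self, "values", values)
        object.__setattr__(
            self, "pixel_spacing_mm", _check_spacing(self.pixel_spacing_mm, 2)
        )
        if self.modality not in (Modality.CT, Modality.PET):
            raise ValueError(f"unknown modality {self.modality!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class VolumeImage:
    """A 3-D PET volume (SUV g/mL) with voxel dimensions in mm."""

    values: np.ndarray
    voxel_spacing_mm: tuple[float, float, float]
    modality: str = Modality.PET

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 3:
            raise ValueError(f"VolumeImage requires a 3-D array, got ndim={values.ndim}")
        if not np.all(np.isfinite(values)):
            raise ValueError("VolumeImage values must be finite")
        if values.min() < 0:
            raise ValueError("SUV values must be non-negative")
        object.__setattr__(self, "values", values)
        object.__setattr__(
            self, "voxel_spacing_mm", _check_spacing(self.voxel_spacing_mm, 3)
        )

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in millilitres (mm^3 / 1000)."""
        return float(np.prod(self.voxel_spacing_mm)) / 1000.0


@dataclass(frozen=True)
class Mask:
    """Boolean grid congruent with its image; at least one true pixel."""

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values).astype(bool)
        if not values.any():
            raise ValueError("mask must select at least one pixel")
        object.__setattr__(self, "values", values)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape

    @property
    def n_selected(self) -> int:
        return int(self.values.sum())

    def check_congruent(self, image: PlanarImage | VolumeImage) -> None:
        if self.values.shape != image.values.shape:
            raise ValueError(
                f"mask shape {self.values.shape} does not match image shape "
                f"{image.values.shape}"
            )


# ---------------------------------------------------------------------------
# NIfTI I/O.  2-D slices are stored as (nx, ny, 1) volumes; spacing travels
# in the affine diagonal / header zooms.
# ---------------------------------------------------------------------------

def _affine_from_spacing(spacing: Sequence[float]) -> np.ndarray:
    aff = np.eye(4)
    for i, s in enumerate(spacing):
        aff[i, i] = s
    return aff


def save_planar_nifti(image: PlanarImage, path: str | Path) -> None:
    data = image.values[:, :, np.newaxis]
    aff = _affine_from_spacing((*image.pixel_spacing_mm, 1.0))
    nib.save(nib.Nifti1Image(data, aff), str(path))


def load_planar_nifti(
    path: str | Path,
    modality: str = Modality.CT,
    spacing_override: tuple[float, float] | None = None,
) -> PlanarImage:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim == 3:
        if data.shape[2] != 1:
            raise ValueError(f"{path}: expected a single-slice NIfTI, got {data.shape}")
        data = data[:, :, 0]
    zooms = img.header.get_zooms()[:2]
    spacing = spacing_override if spacing_override is not None else tuple(zooms)
    return PlanarImage(data, spacing, modality=modality)


def save_volume_nifti(volume: VolumeImage, path: str | Path) -> None:
    aff = _affine_from_spacing(volume.voxel_spacing_mm)
    nib.save(nib.Nifti1Image(volume.values, aff), str(path))


def load_volume_nifti(
    path: str | Path, spacing_override: tuple[float, float, float] | None = None
) -> VolumeImage:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    zooms = img.header.get_zooms()[:3]
    spacing = spacing_override if spacing_override is not None else tuple(zooms)
    return VolumeImage(data, spacing)


def save_mask_nifti(mask: Mask, spacing: Sequence[float], path: str | Path) -> None:
    data = mask.values.astype(np.uint8)
    if data.ndim == 2:
        data = data[:, :, np.newaxis]
        spacing = (*spacing, 1.0)
    nib.save(nib.Nifti1Image(data, _affine_from_spacing(spacing)), str(path))


def load_mask_nifti(path: str | Path) -> Mask:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim == 3 and data.shape[2] == 1:
        data = data[:, :, 0]
    return Mask(data > 0.5)
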