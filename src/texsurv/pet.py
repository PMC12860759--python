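"""Threshold-based PET VOI segmentation and SUV metrics.

A measurement box is placed around the lesion (an input here, mirroring
the manual placement step); the volume of interest (VOI) is segmented
inside the box at 40% of the most intense voxel, and SUVmax, SUVmean,
metabolic tumour volume (MTV, mL) and total lesion glycolysis
(TLG = SUVmean x MTV, g) are reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .images import Mask, VolumeImage

__all__ = ["BoundingBox", "PetMetrics", "segment_voi", "pet_metrics", "hottest_slice"]


@dataclass(frozen=True)
class BoundingBox:
    """Half-open index ranges per axis: ``lo <= i < hi``."""

    lo: tuple[int, int, int]
    hi: tuple[int, int, int]

    def __post_init__(self) -> None:
        if any(h <= l for l, h in zip(self.lo, self.hi)):
            raise ValueError(f"empty bounding box: lo={self.lo}, hi={self.hi}")
        if any(l < 0 for l in self.lo):
            raise ValueError("bounding box indices must be non-negative")

    def check_within(self, volume: VolumeImage) -> None:
        if any(h > s for h, s in zip(self.hi, volume.values.shape)):
            raise ValueError(
                f"bounding box {self.hi} exceeds grid {volume.values.shape}"
            )

    @property
    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(l, h) for l, h in zip(self.lo, self.hi))


@dataclass(frozen=True)
class PetMetrics:
    suvmax: float  # g/mL
    suvmean: float  # g/mL
    mtv_ml: float  # metabolic tumour volume
    tlg_g: float  # suvmean * mtv

    def to_dict(self) -> dict[str, float]:
        return {
            "suvmax": self.suvmax,
            "suvmean": self.suvmean,
            "mtv_ml": self.mtv_ml,
            "tlg_g": self.tlg_g,
        }


def segment_voi(
    volume: VolumeImage, box: BoundingBox, threshold_fraction: float = 0.40
) -> Mask:
    """Segment the VOI inside the box at a fraction of the in-box maximum.

    A voxel belongs to the VOI when its value is at least
    ``threshold_fraction`` times the most intense in-box voxel (>=, so the
    max voxel itself is always included).  Raises on an all-zero box.
    """
    if not 0 < threshold_fraction <= 1:
        raise ValueError(f"threshold fraction must be in (0, 1], got {threshold_fraction}")
    box.check_within(volume)
    sub = volume.values[box.slices]
    vmax = sub.max()
    if vmax <= 0:
        raise ValueError("all-zero measurement box: nothing to segment")
    voi = np.zeros(volume.values.shape, dtype=bool)
    voi[box.slices] = sub >= threshold_fraction * vmax
    return Mask(voi)


def pet_metrics(volume: VolumeImage, voi: Mask) -> PetMetrics:
    """SUVmax, SUVmean, MTV and TLG over a segmented VOI.

    MTV counts whole voxels (voxel count x voxel volume, in mL); TLG is
    SUVmean x MTV.
    """
    voi.check_congruent(volume)
    vals = volume.values[voi.values]
    suvmax = float(vals.max())
    suvmean = float(vals.mean())
    mtv = voi.n_selected * volume.voxel_volume_ml
    return PetMetrics(suvmax=suvmax, suvmean=suvmean, mtv_ml=mtv, tlg_g=suvmean * mtv)


def hottest_slice(volume: VolumeImage, voi: Mask, axis: int = 2,
                  criterion: str = "sum") -> int:
    """Index of the most metabolically active axial slice.

    Operationalised as the slice with the maximal in-VOI summed SUV
    (``criterion="sum"``; ``"max"`` selects the slice holding the single
    hottest voxel instead).  Ties break to the lowest index.
    """
    voi.check_congruent(volume)
    masked = np.where(voi.values, volume.values, 0.0)
    in_voi = voi.values.any(axis=tuple(i for i in range(3) if i != axis))
    if criterion == "sum":
        per_slice = masked.sum(axis=tuple(i for i in range(3) if i != axis))
    elif criterion == "max":
        per_slice = masked.max(axis=tuple(i for i in range(3) if i != axis))
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    per_slice = np.where(in_voi, per_slice, -np.inf)
    return int(np.argmax(per_slice))
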