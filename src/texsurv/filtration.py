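"""Hounsfield-window thresholding and Laplacian-of-Gaussian band-pass filtration.

Filtration-histogram texture analysis of a tumour ROI proceeds in two steps:

1.  On CT, a Hounsfield-unit window is applied to the raw ROI pixels to
    exclude air (below -50 HU) and calcification/bone (above 200 HU); the
    boundaries -50 and 200 themselves are retained.  The window decides
    *which* pixels enter the statistics — it is always evaluated on the
    unfiltered HU values, never on filtered responses.

2.  The whole slice is band-pass filtered with a Laplacian-of-Gaussian
    (LoG) kernel at a spatial scale filter (SSF) of 2 (fine), 3-5 (medium)
    or 6 mm (coarse); SSF = 0 means no filtration.  The SSF is interpreted
    as the radius (in mm) of the object size the filter responds to most
    strongly, i.e. the LoG zero-crossing circle: sigma = SSF / sqrt(2) in
    physical units, converted to pixels per axis through the pixel spacing.
    The response is negated so that bright blobs give positive values
    (keeping "mean of positive pixels" a bright-object statistic).

PET texture analysis uses the unfiltered image only (SSF = 0) and no HU
window.

Kernels are explicitly sampled from the analytic Gaussian and its second
derivative, re-centred so the band-pass kernel sums to exactly zero (a
constant image maps to exactly zero response), and applied separably with
mirror boundary handling over the whole slice, so filter support may
extend beyond the ROI.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import convolve1d

from .images import Mask, Modality, PlanarImage

__all__ = [
    "SSF_VALUES",
    "HU_WINDOW",
    "TextureMap",
    "PixelSample",
    "threshold_hu",
    "log_filter",
    "filtered_sample",
    "texture_samples",
    "log_kernels_1d",
]

#: Spatial scale filter values used throughout (mm); 0 = unfiltered.
SSF_VALUES = (0, 2, 3, 4, 5, 6)

#: Inclusive HU retention window: excludes air (<-50) and bone/calcification (>200).
HU_WINDOW = (-50.0, 200.0)

#: Kernel truncation radius in units of sigma.
_TRUNCATE = 4.0


@dataclass(frozen=True)
class TextureMap:
    """A filtered (or, for ssf_mm=0, verbatim) copy of a planar image."""

    values: np.ndarray
    ssf_mm: float
    modality: str

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class PixelSample:
    """The multiset of in-ROI pixel values that survive windowing/filtration.

    ``provenance`` records the modality, the SSF and whether the HU window
    was applied, so every downstream feature value can be traced back to
    the exact extraction settings.
    """

    values: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float).ravel()
        if values.size == 0:
            raise ValueError("empty pixel sample: ROI unanalysable")
        if not np.all(np.isfinite(values)):
            raise ValueError("pixel sample contains non-finite values")
        object.__setattr__(self, "values", values)

    @property
    def n(self) -> int:
        return int(self.values.size)


def threshold_hu(
    image: PlanarImage, mask: Mask, window: tuple[float, float] = HU_WINDOW
) -> Mask:
    """Restrict a CT ROI mask to pixels inside the HU retention window.

    Returns the sub-mask of ``mask`` whose unfiltered HU values satisfy
    ``window[0] <= value <= window[1]`` (boundaries retained).  Raises
    ``ValueError`` if the image is not CT or if no pixel survives.
    """
    if image.modality != Modality.CT:
        raise ValueError("HU thresholding applies to CT images only")
    mask.check_congruent(image)
    lo, hi = window
    keep = mask.values & (image.values >= lo) & (image.values <= hi)
    if not keep.any():
        raise ValueError(
            f"no ROI pixel inside the HU window [{lo}, {hi}]: ROI unanalysable"
        )
    return Mask(keep)


def log_kernels_1d(sigma_px: float) -> tuple[np.ndarray, np.ndarray]:
    """Sampled 1-D Gaussian and Gaussian-second-derivative kernels.

    Both are sampled at integer offsets in ``[-R, R]`` with
    ``R = ceil(4 sigma)``.  The smoothing kernel ``g`` is normalised to sum
    to 1; the second-derivative kernel ``h`` shares the same normalisation
    and is then re-centred to sum to exactly 0, which makes the assembled
    LoG kernel annihilate constants identically.
    """
    if sigma_px <= 0:
        raise ValueError(f"sigma must be positive, got {sigma_px}")
    radius = int(np.ceil(_TRUNCATE * sigma_px))
    x = np.arange(-radius, radius + 1, dtype=float)
    g = np.exp(-(x**2) / (2.0 * sigma_px**2))
    norm = g.sum()
    h = (x**2 / sigma_px**2 - 1.0) / sigma_px**2 * np.exp(-(x**2) / (2.0 * sigma_px**2))
    g = g / norm
    h = h / norm
    h = h - h.mean()
    return g, h


def ssf_to_sigma_mm(ssf_mm: float) -> float:
    """Physical sigma (mm) for an SSF value: the LoG zero-crossing circle
    (radius sqrt(2)*sigma) is placed at the SSF radius."""
    return float(ssf_mm) / np.sqrt(2.0)


def log_filter(image: PlanarImage, ssf_mm: float) -> TextureMap:
    """Apply the negated-LoG band-pass filter at one spatial scale.

    ``ssf_mm = 0`` returns the unfiltered image verbatim.  Otherwise the
    response is ``-(d2/dx2 + d2/dy2) G_sigma * I`` computed separably with
    mirror padding; anisotropic pixel spacing is handled with a per-axis
    sigma in pixels.
    """
    if ssf_mm not in SSF_VALUES:
        raise ValueError(f"unsupported SSF {ssf_mm}; expected one of {SSF_VALUES}")
    if ssf_mm == 0:
        return TextureMap(image.values.copy(), 0, image.modality)

    sigma_mm = ssf_to_sigma_mm(ssf_mm)
    out = np.zeros_like(image.values)
    # d2/dx2 smoothed along y, plus d2/dy2 smoothed along x
    kernels = []
    for axis in (0, 1):
        sigma_px = sigma_mm / image.pixel_spacing_mm[axis]
        kernels.append(log_kernels_1d(sigma_px))
    for deriv_axis in (0, 1):
        smooth_axis = 1 - deriv_axis
        part = convolve1d(
            image.values, kernels[deriv_axis][1], axis=deriv_axis, mode="mirror"
        )
        part = convolve1d(
            part, kernels[smooth_axis][0], axis=smooth_axis, mode="mirror"
        )
        out += part
    return TextureMap(-out, ssf_mm, image.modality)


def filtered_sample(image: PlanarImage, mask: Mask, ssf_mm: float) -> PixelSample:
    """Pixel sample at the retained mask positions of one texture map.

    For CT the caller passes the HU-thresholded mask (see
    :func:`threshold_hu`): the window is decided on unfiltered HU values
    and the resulting retained-pixel set indexes the filtered map.
    """
    mask.check_congruent(image)
    tmap = log_filter(image, ssf_mm)
    values = tmap.values[mask.values]
    return PixelSample(
        values,
        provenance={
            "modality": image.modality,
            "ssf_mm": ssf_mm,
            "hu_window": image.modality == Modality.CT,
        },
    )


def texture_samples(
    image: PlanarImage,
    mask: Mask,
    ssf_values: Sequence[float] | None = None,
    hu_window: tuple[float, float] = HU_WINDOW,
) -> dict[float, PixelSample]:
    """All-SSF pixel samples for one ROI.

    CT images are HU-windowed once (on raw values) and filtered at every
    requested SSF; PET images are used unfiltered (SSF 0 only) with no
    window, matching PET texture analysis practice.
    """
    if image.modality == Modality.CT:
        if ssf_values is None:
            ssf_values = SSF_VALUES
        retained = threshold_hu(image, mask, hu_window)
    else:
        if ssf_values is None:
            ssf_values = (0,)
        elif any(s != 0 for s in ssf_values):
            raise ValueError("PET texture analysis is unfiltered: only SSF 0 applies")
        retained = mask
    return {ssf: filtered_sample(image, retained, ssf) for ssf in ssf_values}
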