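"""Synthetic phantoms and cohorts with the structure the analysis assumes.

Nothing downstream needs real scans: texture filtration is exercised on
stationary Gaussian random-field phantoms with a controllable correlation
length, PET quantification on volumes containing a smooth hot lesion of
known SUVmax, and the discovery statistics on right-censored cohorts with
a planted threshold effect — by default shaped like a 66-subject stage II
colorectal cohort with 19 expected deaths.

All generators take one integer seed and are bit-reproducible per seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.optimize import brentq

from .images import Mask, Modality, PlanarImage, VolumeImage
from .pet import BoundingBox

__all__ = [
    "PhantomSpec",
    "CohortSpec",
    "gen_texture_phantom",
    "gen_pet_lesion",
    "gen_cohort",
    "write_cohort_csv",
    "read_cohort_csv",
]


# ---------------------------------------------------------------------------
# CT texture phantom
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhantomSpec:
    """A 2-D random-field phantom with a centred circular ROI.

    The field is Gaussian-smoothed white noise (correlation scale
    ``correlation_length_mm``) rescaled post hoc to the exact target
    in-ROI mean and marginal SD, mimicking tumour ROIs whose coarse-scale
    structure varies between subjects.
    """

    grid_size: int = 64
    pixel_spacing_mm: float = 1.0
    mean_hu: float = 40.0
    sd_hu: float = 15.0
    correlation_length_mm: float = 2.0
    lesion_radius_mm: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_size < 16:
            raise ValueError("grid_size must be >= 16")
        if self.pixel_spacing_mm <= 0:
            raise ValueError("pixel_spacing_mm must be positive")
        if self.sd_hu < 0:
            raise ValueError("sd_hu must be non-negative")
        if self.correlation_length_mm < 0:
            raise ValueError("correlation_length_mm must be non-negative")
        if self.lesion_radius_mm < 2 * self.pixel_spacing_mm:
            raise ValueError("lesion_radius_mm must be >= 2 pixel spacings")


def _disc_mask(grid_size: int, spacing: float, radius_mm: float) -> np.ndarray:
    c = (grid_size - 1) / 2.0
    ii, jj = np.meshgrid(np.arange(grid_size), np.arange(grid_size), indexing="ij")
    r2 = ((ii - c) ** 2 + (jj - c) ** 2) * spacing**2
    return r2 <= radius_mm**2


def gen_texture_phantom(spec: PhantomSpec) -> tuple[PlanarImage, Mask]:
    """Stationary Gaussian-random-field CT phantom plus its disc ROI.

    The whole slice carries the field (the ROI only marks the analysed
    disc), so whole-slice filtration behaves as it would on a real scan.
    In-ROI mean and SD equal ``mean_hu`` / ``sd_hu`` exactly by post-hoc
    rescaling; ``sd_hu = 0`` yields a constant slice.
    """
    disc = _disc_mask(spec.grid_size, spec.pixel_spacing_mm, spec.lesion_radius_mm)
    if disc.sum() < 9:
        raise ValueError("degenerate phantom: ROI covers fewer than 9 pixels")
    rng = np.random.default_rng(spec.seed)
    if spec.sd_hu == 0:
        values = np.full((spec.grid_size, spec.grid_size), spec.mean_hu, dtype=float)
    else:
        noise = rng.standard_normal((spec.grid_size, spec.grid_size))
        sigma_px = spec.correlation_length_mm / spec.pixel_spacing_mm
        f = gaussian_filter(noise, sigma_px, mode="wrap") if sigma_px > 0 else noise
        m, s = f[disc].mean(), f[disc].std()
        if s == 0:
            raise RuntimeError("degenerate field realisation: zero in-ROI variance")
        values = (f - m) / s * spec.sd_hu + spec.mean_hu
    image = PlanarImage(
        values, (spec.pixel_spacing_mm, spec.pixel_spacing_mm), modality=Modality.CT
    )
    return image, Mask(disc)


# ---------------------------------------------------------------------------
# PET hot lesion
# ---------------------------------------------------------------------------

def gen_pet_lesion(
    grid: tuple[int, int, int],
    spacing: tuple[float, float, float],
    background_suv: float = 1.0,
    lesion_suvmax: float = 10.0,
    lesion_radius_mm: float = 15.0,
    seed: int = 0,
    noise_sd_frac: float = 0.02,
) -> tuple[VolumeImage, BoundingBox]:
    """PET volume with a centred Gaussian hot lesion and its measurement box.

    The radial profile is scaled so the 40%-of-SUVmax contour sits at
    ``lesion_radius_mm`` (when 0.4*SUVmax exceeds the background); the
    centre voxel equals ``lesion_suvmax`` exactly.  Mild background noise
    (``noise_sd_frac`` of the background, clipped at zero and kept out of
    the lesion core) makes volumes non-trivial without moving the maximum.
    The returned box bounds every voxel at or above 40% of SUVmax with a
    one-voxel margin.
    """
    if not lesion_suvmax > background_suv > 0:
        raise ValueError("need lesion_suvmax > background_suv > 0")
    grid = tuple(int(g) for g in grid)
    spacing = tuple(float(s) for s in spacing)
    half_extent = min(g // 2 * s for g, s in zip(grid, spacing))
    if lesion_radius_mm >= half_extent:
        raise ValueError(
            f"lesion radius {lesion_radius_mm} mm does not fit the "
            f"{grid} grid at spacing {spacing}"
        )
    amp = lesion_suvmax - background_suv
    thr = 0.40 * lesion_suvmax
    if thr > background_suv:
        sigma2 = lesion_radius_mm**2 / (2.0 * np.log(amp / (thr - background_suv)))
    else:  # 40% threshold below background: radius loses its contour meaning
        sigma2 = (lesion_radius_mm / 1.5) ** 2
    centre = tuple((g - 1) // 2 for g in grid)
    axes = [
        (np.arange(g) - c) * s for g, c, s in zip(grid, centre, spacing)
    ]
    r2 = (
        axes[0][:, None, None] ** 2
        + axes[1][None, :, None] ** 2
        + axes[2][None, None, :] ** 2
    )
    values = background_suv + amp * np.exp(-r2 / (2.0 * sigma2))
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, noise_sd_frac * background_suv, size=grid)
    noise[r2 <= lesion_radius_mm**2] = 0.0  # keep the lesion core deterministic
    values = np.clip(values + noise, 0.0, None)
    values[centre] = lesion_suvmax

    hot = np.argwhere(values >= thr)
    lo = np.maximum(hot.min(axis=0) - 1, 0)
    hi = np.minimum(hot.max(axis=0) + 2, grid)
    box = BoundingBox(tuple(int(x) for x in lo), tuple(int(x) for x in hi))
    return VolumeImage(values, spacing), box


# ---------------------------------------------------------------------------
# Survival cohort with a planted threshold effect
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSpec:
    """A right-censored cohort whose hazard doubles across a marker cut.

    Defaults emulate the study cohort shape this pipeline targets: 66
    subjects, 19 expected deaths, a planted hazard ratio of 3.4 for the
    adverse marker side, ~7.5-year baseline median survival and a 10-year
    administrative horizon.
    """

    n_subjects: int = 66
    n_events_target: int = 19
    baseline_median_months: float = 90.0
    planted_hr: float = 3.4
    marker_cut: float = 50.0
    marker_direction: str = ">="  # side of the cut with poor prognosis
    censor_horizon_months: float = 120.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 4:
            raise ValueError("n_subjects must be >= 4")
        if not 1 <= self.n_events_target <= self.n_subjects:
            raise ValueError("n_events_target must be in [1, n_subjects]")
        if self.planted_hr <= 0:
            raise ValueError("planted_hr must be positive")
        if self.censor_horizon_months <= 0:
            raise ValueError("censor_horizon_months must be positive")
        if self.baseline_median_months <= 0:
            raise ValueError("baseline_median_months must be positive")
        if self.marker_direction not in ("<", ">="):
            raise ValueError('marker_direction must be "<" or ">="')


def _p_event(lam: float, fmax: float, horizon: float) -> float:
    """P(exponential(lam) death observed before min(horizon, U(0, fmax)))."""
    if fmax <= 0:
        return 0.0
    if fmax <= horizon:
        return 1.0 - (1.0 - np.exp(-lam * fmax)) / (lam * fmax)
    surv_tail = np.exp(-lam * horizon)
    return 1.0 - ((1.0 - surv_tail) / lam + (fmax - horizon) * surv_tail) / fmax


def _calibrate_followup(
    lam_good: float, lam_poor: float, horizon: float, target_frac: float
) -> float:
    """Accrual window f_max such that the expected event fraction matches.

    Group hazards are fixed by the baseline median and the planted HR, so
    the event fraction is tuned through the administrative follow-up
    (uniform accrual over [0, f_max], truncated at the horizon).  Returns
    inf when even horizon-only censoring cannot yield enough events.
    """

    def expected(fmax: float) -> float:
        return 0.5 * (_p_event(lam_good, fmax, horizon) + _p_event(lam_poor, fmax, horizon))

    attainable = 0.5 * (
        (1.0 - np.exp(-lam_good * horizon)) + (1.0 - np.exp(-lam_poor * horizon))
    )
    if target_frac >= attainable:
        if target_frac > attainable * 1.02:
            warnings.warn(
                f"event target {target_frac:.3f} exceeds the attainable fraction "
                f"{attainable:.3f} under horizon-only censoring; expect fewer events",
                stacklevel=3,
            )
        return np.inf
    return brentq(lambda f: expected(f) - target_frac, 1e-6, 100.0 * horizon)


def gen_cohort(
    spec: CohortSpec,
    n_linked_markers: int = 1,
    n_null_markers: int = 0,
    marker_separation: float = 10.0,
) -> pd.DataFrame:
    """Cohort table with planted and null markers and censored survival.

    Each subject is assigned poor/good status with probability 1/2; linked
    markers are drawn from a two-normal mixture straddling ``marker_cut``
    (component SD = 10% of the separation) so the adverse side of the cut
    tags the poor group; null markers are independent of outcome.
    Survival is exponential per group (rate scaled by ``planted_hr`` on
    the poor side) and right-censored at the earlier of the
    administrative horizon and a uniform-accrual follow-up calibrated so
    the expected event count matches ``n_events_target``.

    Columns: ``subject_id, time_months, event, true_poor, marker_1..``
    (linked markers first, then null markers).
    """
    if n_linked_markers < 1:
        raise ValueError("at least one linked marker is required")
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    lam_good = np.log(2.0) / spec.baseline_median_months
    lam_poor = spec.planted_hr * lam_good
    fmax = _calibrate_followup(
        lam_good, lam_poor, spec.censor_horizon_months, spec.n_events_target / n
    )

    sd = 0.1 * marker_separation
    offset = marker_separation / 2.0
    sign = 1.0 if spec.marker_direction == ">=" else -1.0
    component = rng.random(n) < 0.5  # mixture component straddling the cut
    centre = spec.marker_cut + sign * np.where(component, offset, -offset)
    marker1 = rng.normal(centre, sd)
    # hazard follows the side of the cut the marker lands on
    poor = marker1 >= spec.marker_cut if spec.marker_direction == ">=" else marker1 < spec.marker_cut
    lam = np.where(poor, lam_poor, lam_good)
    t_death = rng.exponential(1.0 / lam)
    if np.isinf(fmax):
        followup = np.full(n, spec.censor_horizon_months)
    else:
        followup = np.minimum(rng.uniform(0.0, fmax, size=n), spec.censor_horizon_months)
    event = (t_death <= followup).astype(int)
    time = np.where(event == 1, t_death, followup)
    time = np.maximum(time, 1e-9)  # survival times must stay positive

    data: dict[str, np.ndarray] = {
        "subject_id": np.array([f"S{i:03d}" for i in range(n)]),
        "time_months": time,
        "event": event,
        "true_poor": poor.astype(int),
    }
    data["marker_1"] = marker1
    col = 2
    for _ in range(n_linked_markers - 1):
        # further markers tagging the same high-hazard subgroup
        centre2 = spec.marker_cut + sign * np.where(poor, offset, -offset)
        data[f"marker_{col}"] = rng.normal(centre2, sd)
        col += 1
    for _ in range(n_null_markers):
        data[f"marker_{col}"] = rng.normal(spec.marker_cut, marker_separation, size=n)
        col += 1
    return pd.DataFrame(data)


def write_cohort_csv(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False)


def read_cohort_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("time_months", "event"):
        if col not in df.columns:
            raise ValueError(f"cohort CSV missing required column {col!r}")
    return df
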