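"""First-order histogram statistics of a pixel sample.

Six statistics summarise each (filtered) pixel sample: mean, standard
deviation, entropy (irregularity), mean of positive pixels (MPP),
skewness (bright-object preponderance when positive) and kurtosis
(tissue contrast).  Conventions:

- mean and SD are the sample mean and the (n-1)-denominator SD;
- skewness and kurtosis are population (n-denominator) standardised
  moments, kurtosis on the *excess* scale (a normal sample gives 0 —
  negative kurtosis values are meaningful);
- entropy is the Shannon entropy in bits of the normalised histogram with
  a fixed bin width whose bins are anchored at 0 (bin k covers
  ``[k*w, (k+1)*w)``); it depends on the bin width, which is therefore an
  explicit, logged parameter;
- MPP averages strictly positive values only and is reported absent
  (NaN) when the sample has none — never imputed as 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps

from .filtration import PixelSample
from .images import Modality

__all__ = [
    "FeatureVector",
    "STAT_NAMES",
    "compute_features",
    "default_bin_width",
    "feature_table",
    "marker_name",
]

STAT_NAMES = ("mean", "sd", "entropy", "mpp", "skewness", "kurtosis")


@dataclass(frozen=True)
class FeatureVector:
    mean: float
    sd: float
    entropy: float
    mpp: float  # NaN when the sample has no positive pixel
    skewness: float  # NaN when n == 1
    kurtosis: float  # excess scale; NaN when n == 1
    modality: str = Modality.CT
    ssf_mm: float = 0.0
    bin_width: float = 1.0

    def to_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in STAT_NAMES}


def default_bin_width(sample: PixelSample) -> float:
    """Entropy bin width: 1 HU for unfiltered CT, sample-range/128 otherwise.

    Unfiltered CT is naturally quantised in integer HU; filtered maps and
    PET values are continuous, so the width adapts to the sample spread.
    A degenerate (constant) sample falls back to width 1.
    """
    prov = sample.provenance
    if prov.get("modality") == Modality.CT and prov.get("ssf_mm", 0) == 0:
        return 1.0
    rng = float(np.ptp(sample.values))
    return rng / 128.0 if rng > 0 else 1.0


def _histogram_entropy_bits(values: np.ndarray, bin_width: float) -> float:
    # fixed-width bins anchored at 0: bin index floor(v / w)
    idx = np.floor(values / bin_width).astype(np.int64)
    _, counts = np.unique(idx, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def compute_features(
    sample: PixelSample, bin_width: float | None = None
) -> FeatureVector:
    """The six first-order statistics of one pixel sample."""
    if bin_width is None:
        bin_width = default_bin_width(sample)
    if bin_width <= 0:
        raise ValueError(f"bin_width must be positive, got {bin_width}")
    v = sample.values
    n = v.size
    mean = float(v.mean())
    sd = float(v.std(ddof=1)) if n > 1 else 0.0
    entropy = _histogram_entropy_bits(v, bin_width)
    positives = v[v > 0]
    mpp = float(positives.mean()) if positives.size else float("nan")
    if n > 1 and v.std() > 0:
        skewness = float(sps.skew(v, bias=True))
        kurtosis = float(sps.kurtosis(v, fisher=True, bias=True))
    else:
        # n == 1, or a constant sample: standardised moments are 0/0
        skewness, kurtosis = float("nan"), float("nan")
    return FeatureVector(
        mean=mean,
        sd=sd,
        entropy=entropy,
        mpp=mpp,
        skewness=skewness,
        kurtosis=kurtosis,
        modality=sample.provenance.get("modality", Modality.CT),
        ssf_mm=sample.provenance.get("ssf_mm", 0.0),
        bin_width=bin_width,
    )


def marker_name(modality: str, stat: str, ssf_mm: float) -> str:
    """Column naming: ``ctta_mean6``, ``pta_skewness0``, ...

    CT texture markers carry the ``ctta`` prefix, PET texture markers
    ``pta``; the trailing integer is the SSF in mm.
    """
    prefix = "ctta" if modality == Modality.CT else "pta"
    return f"{prefix}_{stat}{int(ssf_mm)}"


def feature_table(
    per_subject_samples: Mapping[str, Mapping[float, PixelSample]],
    bin_width: float | None = None,
) -> pd.DataFrame:
    """One row per subject, one column per (modality, stat, SSF) marker.

    ``per_subject_samples`` maps subject id -> {ssf: PixelSample}, e.g. the
    output of :func:`texsurv.filtration.texture_samples` per subject.
    Absent features (no positive pixel for MPP, n=1 moments) appear as NaN
    and are dropped per-marker downstream.
    """
    rows = []
    for subject_id, samples in per_subject_samples.items():
        row: dict[str, object] = {"subject_id": subject_id}
        for ssf, sample in samples.items():
            fv = compute_features(sample, bin_width)
            for stat, value in fv.to_dict().items():
                row[marker_name(fv.modality, stat, ssf)] = value
        rows.append(row)
    return pd.DataFrame(rows)
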