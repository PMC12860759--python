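"""End-to-end discovery runs: configuration, feature extraction, reporting.

A run goes: (CT texture features + PET metrics, when image manifests are
supplied) -> per-marker optimised Kaplan-Meier cutoffs -> Benjamini-
Hochberg control -> selection rules -> k-fold cutoff-transfer
cross-validation -> multivariate Cox on the survivors -> combined
two-marker stratum.  Every seed and decision knob lands in the run log;
reruns with the same config are byte-identical (no timestamps in the
bundle).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .discovery import EVENT_COL, TIME_COL, MarkerDiscovery, adverse_mask, format_p
from .features import compute_features, feature_table, marker_name
from .filtration import texture_samples
from .images import (
    Modality,
    PlanarImage,
    load_mask_nifti,
    load_planar_nifti,
    load_volume_nifti,
)
from .pet import BoundingBox, hottest_slice, pet_metrics, segment_voi
from .survival import km_estimate

__all__ = [
    "RunConfig",
    "PipelineError",
    "extract_ct_features",
    "extract_pet_features",
    "run_discovery",
]


class PipelineError(RuntimeError):
    """Raised when a pipeline stage fails; names the stage."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")


@dataclass
class RunConfig:
    """Configuration of one discovery run (YAML/JSON loadable)."""

    cohort_csv: str
    out_dir: str = "texsurv_run"
    ct_manifest: str | None = None  # CSV: subject_id, image, mask
    pet_manifest: str | None = None  # CSV: subject_id, image, lo0..lo2, hi0..hi2
    ssf_values: list[float] = field(default_factory=lambda: [0, 2, 3, 4, 5, 6])
    bin_width: float | None = None
    min_group_size: int = 2
    fdr_q: float = 0.2
    k_folds: int = 3
    seed: int = 0
    require_median_significant: bool = False
    display_decimals: int = 3

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        if not Path(self.cohort_csv).exists():
            raise ValueError(f"cohort CSV not found: {self.cohort_csv}")
        for p in (self.ct_manifest, self.pet_manifest):
            if p is not None and not Path(p).exists():
                raise ValueError(f"manifest not found: {p}")
        if not 0 < self.fdr_q < 1:
            raise ValueError("fdr_q must lie in (0, 1)")


def extract_ct_features(
    manifest: pd.DataFrame, ssf_values=None, bin_width: float | None = None
) -> pd.DataFrame:
    """CT texture features for every subject in an image manifest.

    ``manifest`` columns: ``subject_id``, ``image`` (single-slice NIfTI,
    HU), ``mask`` (NIfTI ROI).  Returns one row per subject with
    ``ctta_<stat><ssf>`` columns.
    """
    samples = {}
    for row in manifest.itertuples(index=False):
        image = load_planar_nifti(row.image, modality=Modality.CT)
        mask = load_mask_nifti(row.mask)
        samples[row.subject_id] = texture_samples(image, mask, ssf_values)
    return feature_table(samples, bin_width)


def extract_pet_features(
    manifest: pd.DataFrame, bin_width: float | None = None
) -> pd.DataFrame:
    """PET SUV metrics plus unfiltered PET texture of the hottest slice.

    ``manifest`` columns: ``subject_id``, ``image`` (PET NIfTI) and the
    measurement-box indices ``lo0,lo1,lo2,hi0,hi1,hi2`` (half-open).  The
    VOI is segmented at 40% of the in-box maximum; texture statistics are
    computed, without filtration, on the most metabolically active axial
    slice of the VOI.
    """
    rows = []
    for row in manifest.itertuples(index=False):
        volume = load_volume_nifti(row.image)
        box = BoundingBox(
            (int(row.lo0), int(row.lo1), int(row.lo2)),
            (int(row.hi0), int(row.hi1), int(row.hi2)),
        )
        voi = segment_voi(volume, box)
        metrics = pet_metrics(volume, voi)
        out = {
            "subject_id": row.subject_id,
            "pet_suvmax": metrics.suvmax,
            "pet_suvmean": metrics.suvmean,
            "pet_mtv": metrics.mtv_ml,
            "pet_tlg": metrics.tlg_g,
        }
        z = hottest_slice(volume, voi)
        slice_img = PlanarImage(
            volume.values[:, :, z], volume.voxel_spacing_mm[:2], modality=Modality.PET
        )
        from .images import Mask

        slice_mask = Mask(voi.values[:, :, z])
        sample = texture_samples(slice_img, slice_mask)[0]
        fv = compute_features(sample, bin_width)
        for stat, value in fv.to_dict().items():
            out[marker_name(Modality.PET, stat, 0)] = value
        rows.append(out)
    return pd.DataFrame(rows)


def _km_curves_frame(cohort: pd.DataFrame, results, markers) -> pd.DataFrame:
    rows = []
    for m in markers:
        res = results.cutoff_results[m]
        sub = cohort.loc[cohort[m].notna()]
        poor = adverse_mask(sub[m].to_numpy(float), res)
        for label, sel in (("poor", poor), ("good", ~poor)):
            if not sel.any() or sub.loc[sel, EVENT_COL].sum() == 0:
                continue
            curve = km_estimate(
                sub.loc[sel, TIME_COL].to_numpy(float),
                sub.loc[sel, EVENT_COL].to_numpy(int),
            )
            for t, s, n_r, n_e in zip(
                curve.event_times, curve.survival, curve.n_at_risk, curve.n_events
            ):
                rows.append(
                    {
                        "marker": m,
                        "group": label,
                        "time_months": t,
                        "survival": s,
                        "n_at_risk": n_r,
                        "n_events": n_e,
                    }
                )
    return pd.DataFrame(rows)


def run_discovery(config: RunConfig) -> dict:
    """Execute the full pipeline per config; returns a summary dict.

    Writes into ``config.out_dir``: the marker-augmented cohort, the
    ranked discovery table (``table1.csv``), the shortlist with
    rationales, per-marker CV JSON, the multivariate Cox JSON, the
    combined-stratum JSON, KM curve data for the surviving markers, and a
    run log recording every knob.  Any stage failure raises
    :class:`PipelineError` naming the stage; outputs written before the
    failure are preserved.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = ["texsurv discovery run", "config:"]
    log_lines += [f"  {k}: {v}" for k, v in dataclasses.asdict(config).items()]

    from .synthetic import read_cohort_csv

    try:
        cohort = read_cohort_csv(config.cohort_csv)
    except Exception as exc:
        raise PipelineError("load_cohort", str(exc)) from exc

    if config.ct_manifest:
        try:
            feats = extract_ct_features(
                pd.read_csv(config.ct_manifest), config.ssf_values, config.bin_width
            )
            cohort = cohort.merge(feats, on="subject_id", how="left")
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("ct_features", str(exc)) from exc
    if config.pet_manifest:
        try:
            feats = extract_pet_features(pd.read_csv(config.pet_manifest), config.bin_width)
            cohort = cohort.merge(feats, on="subject_id", how="left")
        except Exception as exc:
            raise PipelineError("pet_features", str(exc)) from exc
    cohort.to_csv(out / "cohort_markers.csv", index=False)

    try:
        model = MarkerDiscovery(
            cohort,
            min_group_size=config.min_group_size,
            fdr_q=config.fdr_q,
        )
        results = model.fit(
            cross_validate=True,
            k_folds=config.k_folds,
            seed=config.seed,
            require_median_significant=config.require_median_significant,
        )
    except ValueError as exc:
        (out / "run_log.txt").write_text("\n".join(log_lines) + f"\nFAILED: {exc}\n")
        raise PipelineError("discovery", str(exc)) from exc

    results.summary().to_csv(out / "table1.csv", index=False)
    pd.DataFrame(
        [
            {
                "marker": r.marker,
                "cutoff": round(r.cutoff, config.display_decimals),
                "direction": r.direction,
                "rationale": why,
            }
            for r, why in results.shortlist
        ]
    ).to_csv(out / "shortlist.csv", index=False)

    for m, cv in results.cv_results.items():
        cv.to_json(out / f"cv_{m}.json")
    if results.cox is not None:
        (out / "cox.json").write_text(json.dumps(results.cox.to_dict(), indent=2))
    if results.combined is not None:
        c = results.combined
        payload = {
            "marker_a": c.marker_a,
            "marker_b": c.marker_b,
            "n_poor": c.n_poor,
            "n_good": c.n_good,
            "flagged_empty": c.flagged_empty,
        }
        if c.hr is not None:
            payload["hr"] = c.hr.hr
            payload["ci95"] = [c.hr.ci_low, c.hr.ci_high]
            payload["logrank_p"] = c.hr.logrank_p
        (out / "combined.json").write_text(json.dumps(payload, indent=2))

    km = _km_curves_frame(cohort, results, results.cv_survivors)
    km.to_csv(out / "km_curves.csv", index=False)

    log_lines.append(f"markers tested: {len(results.cutoff_results)}")
    for m, why in results.skipped.items():
        log_lines.append(f"skipped {m}: {why}")
    log_lines.append(f"BH-significant at q={config.fdr_q}: {results.bh.significant}")
    log_lines.append(f"CV survivors (recombined p < 0.05): {results.cv_survivors}")
    for m, cv in results.cv_results.items():
        log_lines.append(
            f"  {m}: cutoffs={[round(c, 3) for c in cv.fold_cutoffs]} "
            f"directions={cv.fold_directions} recombined_p={format_p(cv.recombined_p)}"
            + ("" if cv.directions_agree else " [direction-unstable]")
        )
    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")

    return {
        "n_tested": len(results.cutoff_results),
        "bh_significant": results.bh.significant,
        "cv_survivors": results.cv_survivors,
        "out_dir": str(out),
        "results": results,
    }
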