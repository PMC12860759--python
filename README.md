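# texsurv

Multiparametric [¹⁸F]FDG PET/CT imaging-biomarker discovery for survival
prognosis: filtration-histogram CT/PET texture analysis, threshold-based
PET quantification, optimised-cutoff Kaplan–Meier discovery with
Benjamini–Hochberg false-discovery control, event-stratified
cutoff-transfer cross-validation, and multivariate Cox modelling — with a
synthetic-data module so the entire cascade is testable without any
patient scans.

## Who this is for

Imaging and biostatistics researchers who dichotomise continuous imaging
markers (texture statistics, SUV metrics) at *optimised* cutoffs to
stratify survival. The minimum-p cutoff search is powerful but heavily
anti-conservative; this package implements the full guarded workflow —
FDR control across the marker family plus out-of-sample cutoff transfer —
and ships the simulations that show why the guards are needed.

## The method

**Texture features.** A tumour ROI on an axial CT slice is windowed to
−50…200 HU (excluding air and calcification/bone), then the whole slice is
band-pass filtered with Laplacian-of-Gaussian kernels at spatial scale
filter (SSF) values of 0 (unfiltered), 2 (fine), 3–5 (medium) and 6 mm
(coarse); σ = SSF/√2 so the LoG zero-crossing circle sits at the SSF
radius, and the response is negated so bright objects score positive. Six
first-order statistics summarise the retained pixels per scale: mean, SD,
entropy (bits), mean of positive pixels, skewness, excess kurtosis. PET
texture uses the unfiltered hottest axial slice only.

**PET quantification.** Inside a measurement box, the VOI is the set of
voxels ≥ 40% of the in-box SUVmax; SUVmax, SUVmean, MTV (mL) and
TLG = SUVmean × MTV follow.

**Discovery.** For each marker *X* and every admissible cutoff *c*
(midpoints of consecutive sorted unique values, group-size floor ≥ 2),
the two-sided log-rank statistic compares {X < c} with {X ≥ c}; the
split with minimal p is kept and its poor-prognosis direction reported.
With m markers tested, Benjamini–Hochberg at FDR q = 0.2 flags ranks
1…k where k = max{i : p₍ᵢ₎ ≤ i·q/m}. Tied-p markers are ranked by group
balance |n_poor − n_good|, optionally requiring significance at the
(unoptimised) median split.

**Validation.** Subjects are dealt into 3 folds with proportional events;
each fold is labelled poor/good using the cutoff (and direction)
re-derived on the other two folds; the recombined out-of-sample labels
are tested with a single log-rank. Survivors enter a multivariate Cox
model (Efron ties, Newton–Raphson) as dichotomised indicators, and the
two top markers define a combined stratum (adverse on both).

## Worked example

```python
from texsurv import CohortSpec, MarkerDiscovery, gen_cohort

cohort = gen_cohort(
    CohortSpec(seed=7, n_subjects=120, n_events_target=40, planted_hr=4.0),
    n_null_markers=4,
)
results = MarkerDiscovery(cohort).fit(seed=7)
print(results)
```

```
MarkerDiscovery: 5 markers tested, 5 BH-significant at q=0.2
  marker cutoff (poor)  n_poor  n_good       p  BH critical  significant
marker_1     >= 49.958      57      63 <0.0001         0.04         True
marker_4      < 29.604       2     118  0.0041         0.08         True
marker_5     >= 72.919       2     118  0.0126         0.12         True
marker_2      < 60.557     109      11  0.0323         0.16         True
marker_3     >= 42.512      96      24  0.1646         0.20         True
cross-validation (recombined log-rank p):
  marker_1: p=<0.0001
  marker_4: p=0.9856
  marker_5: p=0.8943
  marker_2: p=0.1811
  marker_3: p=0.4845
multivariate Cox:
                        coef  se(coef)       HR  HR 95% low  HR 95% high         z         p
marker_1 >= 49.958  1.769802    0.3846  5.86969    2.762126    12.473458  4.601674  0.000004
```

Reading it: `marker_1` carries a planted threshold effect at 50 (hazard
ratio 4 on the high side); the optimised search recovers a cutoff of
49.96 with the poor group on the `>=` side. All four *null* markers also
clear the raw optimised-cutoff screen — three via extreme 2/118 or
109/11 splits, the signature of minimum-p overfitting — but only the
planted marker survives cutoff-transfer cross-validation (recombined
p < 0.0001 versus 0.18–0.99 for the nulls), and the Cox model estimates
its hazard ratio at 5.87 (95% CI 2.76–12.47).

The same run is available from the shell:

```bash
texsurv simulate --kind cohort --out cohort.csv --seed 7 \
    --n-subjects 120 --n-events 40 --planted-hr 4.0 --null-markers 4
texsurv run-all --cohort cohort.csv --out-dir run --seed 7
```

which writes `table1.csv` (the ranked discovery table), `shortlist.csv`,
per-marker CV JSON, `cox.json`, `combined.json`, Kaplan–Meier curve data
and a run log into `run/`. `texsurv features` and `texsurv pet` extract
CT texture features and PET metrics from NIfTI image/mask manifests.

## Limitations

Synthetic cohorts use exponential per-group survival and a clean
two-component marker mixture; phantoms are stationary Gaussian random
fields. See `docs/methods.md` for what these do and do not exercise,
including the measured anti-conservativeness (~9% at the 5% level) of
the recombined cross-validated log-rank and the intrinsic imprecision of
minimum-p cutpoint estimation.
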