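# Methods

This note records the models, conventions and numerical choices behind
`texsurv`, and what its simulations do and do not demonstrate.

## Texture filtration

The CT pipeline applies an inclusive Hounsfield retention window
[−50, 200] HU to the raw (unfiltered) ROI pixels — excluding air below
−50 and calcification/bone above 200 — and the surviving pixel set then
indexes every filtered map: the window decides *which* pixels enter the
statistics, never the filtered values themselves. Exactly −50 and
exactly 200 are retained, because the exclusions are strict
inequalities.

Band-pass filtration uses the Laplacian of Gaussian. The spatial scale
filter (SSF ∈ {0, 2, 3, 4, 5, 6} mm; 0 = unfiltered) is interpreted as
the radius of the object size the filter responds to most strongly, so
σ = SSF/√2 places the LoG zero-crossing circle (radius √2·σ) at the SSF
radius. σ is converted to pixels per axis through the pixel spacing, so
anisotropic grids get per-axis kernels. The response is negated: bright
blobs yield positive values, keeping "mean of positive pixels" a
bright-object statistic. Kernels are sampled analytically from the
Gaussian and its second derivative on a ±4σ support, normalised so the
smoothing kernel sums to one, and the derivative kernel is re-centred to
sum to exactly zero — a constant image maps to exactly zero response
(machine precision), and linearity `LoG(aI + b) = a·LoG(I)` holds
exactly. Convolution is separable with mirror boundary handling and is
applied to the whole slice, not a mask crop, so filter support may
extend beyond the ROI as in whole-image filtration practice. The exact
SSF→σ convention and padding of commercial texture software are
unpublished; these are documented knobs, not claims of bit
compatibility. PET texture is computed without filtration (and without
an HU window) on the most metabolically active axial slice.

## Histogram statistics

Per pixel sample: sample mean; (n−1)-denominator SD; Shannon entropy in
bits of a fixed-width histogram with bins anchored at zero (bin k covers
[k·w, (k+1)·w)); mean of strictly positive pixels; population
(n-denominator) skewness; population *excess* kurtosis. Excess kurtosis
is required for negative kurtosis cutoffs to be meaningful. Entropy is
histogram-dependent; the default width is 1 HU for unfiltered CT
(naturally integer-quantised) and sample-range/128 otherwise, and the
width used is recorded on every feature vector. When a sample has no
positive pixel, MPP is reported absent (NaN) and the subject is dropped
for that marker — never imputed as zero. A single-pixel sample gets
SD 0 and absent skewness/kurtosis.

## PET quantification

The measurement box is an input (it models manual placement). The VOI is
every in-box voxel ≥ 0.40 × the in-box maximum (≥, so the peak voxel is
always included). SUVmean is the arithmetic mean over the VOI, MTV
counts whole voxels × voxel volume (no partial-volume weighting), and
TLG = SUVmean × MTV. The "most metabolically active slice" is the axial
index with maximal in-VOI summed SUV (ties to the lowest index); a
max-single-voxel criterion is available as an option.

## Survival primitives

Kaplan–Meier, the two-group log-rank and Cox proportional hazards are
implemented from first principles because the discovery engine reuses
them everywhere, including a vectorised all-candidates log-rank scan
whose row-wise equality with the scalar test is itself under test.
Conventions: censored subjects sharing a time with deaths count as at
risk for those deaths; tied deaths are pooled within a time point
(log-rank, hypergeometric variance with the (n−d)/(n−1) correction) and
handled with the Efron correction in Cox (Breslow by option — monthly
resolution makes ties likely). The Cox fit is damped Newton–Raphson with
step halving, convergence at max|score| < 1e−8 or 50 iterations;
monotone likelihoods (perfect separation) are detected by a runaway
coefficient (|β| > 20) and flagged non-converged rather than reported.
Confidence intervals and per-covariate p-values are two-sided 95% Wald.
Binary stratifications are reported in the conventional pairing: HR and
CI from a one-covariate Cox fit, p from the log-rank test.

On tie-free data the log-rank chi-square equals the Cox score test at
β = 0 exactly; this identity is a regression test. The Cox
implementation is cross-checked against lifelines (agreement ~1e−6,
bounded by the external optimiser's tolerance), which is never on the
implementation path.

## Cutoff discovery

Candidates are midpoints between consecutive sorted unique marker
values whose split leaves at least `min_group_size` (default 2 —
observed discovery tables contain 2/64 splits) subjects on each side.
Both directions are implicit in the two-sided statistic; the reported
poor side is the one with more deaths than expected. Ties in p break
toward the most balanced split, then the lower cutoff. Cutoffs are
displayed at 3 dp but stored at full precision; p-values display as
"<0.0001" below 1e−4 but compare at full precision. Subjects missing a
marker are dropped per marker; m for Benjamini–Hochberg counts the
markers actually tested (45 in the canonical table: 36 CTTA + 3 PET +
6 PTA). Whether the original iterative search scanned observed values
or a grid, and its group-size floor, are unstated upstream; both are
configuration here, with the midpoint scan as default.

The median-split check refits the log-rank at the unoptimised sample
median (a subject exactly at the median falls on the "≥" side) as a
robustness filter: an effect visible at the median is not an artefact of
the search.

## Cross-validation

Folds are event-stratified: events and non-events are shuffled
separately (seeded) and dealt round-robin in one continuing deal, so
fold sizes and per-fold event counts each differ by at most one. For
each held-out fold the cutoff *and its direction* are re-derived on the
other two folds and applied to the held-out subjects; every subject is
labelled exactly once, and one log-rank — the same operation used in
discovery — tests the recombined labels. Folds that disagree on
direction are flagged unstable but still evaluated with each fold's own
direction. If the transferred cutoffs put the whole cohort in one group
(rare, null cohorts only), the result is p = 1 with a `degenerate` flag
rather than an error, keeping calibration simulations well defined.

**What the calibration simulations show.** Under a global null
(66 subjects, ~19 events, 45 independent markers) the naive optimised
search yields at least one raw p < 0.05 in essentially every replicate —
the inflation the guards exist for. The recombined cross-validated test
removes almost all of that optimism but is *not* exactly nominal: its
measured size is ≈ 0.09 at the 0.05 level (2,000 replicates), because
out-of-fold labels are mutually correlated through shared training
subjects — the known mild anti-conservativeness of pre-validated tests.
Consumers should read recombined p-values near 0.05 with that in mind;
a permutation wrapper would calibrate them exactly but is out of scope.

**Minimum-p cutpoint imprecision.** On planted cohorts the optimised
cutoff's *grouping* is recovered only approximately: the scan almost
always finds a strictly smaller p by moving the cutoff a few subjects
into a cluster to capture early deaths. At n = 200, HR 4, ~30% events
the exact planted gap is recovered in ~12% of replicates (≈46% even
with near-complete follow-up). Because the log-rank depends only on
marker ranks, no marker-geometry choice changes this; it is intrinsic
to minimum-p estimation, and one more reason the cutoff is validated by
transfer rather than taken at face value.

## Synthetic data

*Phantoms* are Gaussian-smoothed white noise (correlation length in mm)
affinely rescaled post hoc to the exact target in-ROI mean and marginal
SD, with the field covering the whole slice and a centred disc ROI;
`sd_hu = 0` degenerates to a constant slice. Because the construction is
symmetric under field negation, the signed in-ROI mean of any band-pass
response is symmetric about zero; what distinguishes correlation lengths
at SSF = 6 is the *dispersion* of that mean (≈20× variance ratio for
8 mm vs 1 mm fields), i.e. coarse structure surviving the 6 mm
band-pass. *PET lesions* are Gaussian radial profiles scaled so the 40%
contour sits at the requested radius, peak exactly at SUVmax, plus mild
background noise kept out of the lesion core.

*Cohorts* default to the target study shape: 66 subjects, 19 expected
deaths, baseline median survival 90 months, planted hazard ratio 3.4, a
120-month administrative horizon. Markers are a 50/50 two-normal
mixture straddling the cut (component SD = 10% of the separation,
separation 10 units), and the hazard follows the side of the cut the
marker lands on; additional "linked" markers tag the same subgroup and
null markers are outcome-independent. Survival is exponential per group
(memoryless, analytically checkable). Censoring is the minimum of the
horizon and a uniform-accrual follow-up whose window is solved in
closed form so the *expected* event count equals the target — the
group hazards are fixed by the median and the hazard ratio, so the
event fraction must be tuned through follow-up; if the target exceeds
what horizon-only censoring allows, the generator warns and censors at
the horizon. All generators take one integer seed and are
bit-reproducible.

What passing these simulations does *not* show: robustness to
non-proportional hazards, informative censoring, correlated marker
families, scanner noise, partial-volume effects, or anatomically
realistic texture — real cohorts are harder than these phantoms.

## Problem sizes

The shipped simulations use 100-replicate recovery/coverage studies,
500 replicates for the null calibration of the cross-validated test,
60 replicates × 45 markers for the naive-inflation demonstration, 20
paired seeds for the filtration contrast, and 64×64 phantoms /
24³-voxel PET volumes; the whole suite and the acceptance script each
complete in well under a minute on one core.
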