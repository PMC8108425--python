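# Methods

## The problem

Quantitative tissue properties (T1, T2 relaxation) differentiate diseased
from healthy brain tissue, including in white matter that looks normal on
clinical scans ("normal-appearing white matter", NAWM).  Measuring them
directly requires specialized acquisitions.  Routine clinical T1-weighted
and FLAIR images carry the same contrast information, but in arbitrary
scanner units that are not comparable across subjects or scanners.  This
package standardizes those units statistically, so that signal means and
spreads of each tissue class become quantitative biomarkers, and provides
the statistical machinery to relate them to clinical group and disability
in a multiple-sclerosis (MS) setting.

## Pipeline

### Bivariate intensity histograms

For every subject the in-brain (T1w, FLAIR) voxel intensity pairs are
histogrammed on a fixed 2D grid (default 256 x 256 bins).  Tissue classes
appear as modes: in a typical control, marginal peaks sit near T1w
200/600/1000 scanner units (CSF/GM/WM) and FLAIR 200/700/1100
(CSF/WM/GM).  The bin ranges are frozen when the normative atlas is
built: [0, 1.6 x P99.9] of the pooled control intensities per contrast.
The 1.6 head-room factor is deliberate — subjects from other scanners can
be globally brighter than every control, and mass clipped into the
boundary bin is unrecoverable by any affine registration, so the
reference grid must leave room above the control range.

### Normative atlas

The reference is the arithmetic mean of the normalized control
histograms (each control contributes equally regardless of brain size; a
median reference would also be defensible but the mean is the simplest
consistent estimator).  CSF/GM/WM centroids are local maxima of the
Gaussian-smoothed (sigma = 2 bins) reference, hill-climbed from seeds at
the normative loci above.  Lesions have no mode in a control reference;
the lesion centroid is a prior placed at (midpoint of GM/WM on T1w,
GM FLAIR + 1.5 x the GM-WM FLAIR gap) — hyperintense on FLAIR with
intermediate T1w — and is user-overridable.

### Histogram registration (intensity standardization)

Each subject's histogram is registered to the reference with a full
6-parameter planar affine x' = Ax + b, det(A) > 0.  The dissimilarity
functional is the sum of squared differences between normalized,
Gaussian-smoothed (sigma = 2 bins), square-root-transformed histograms.
The square root damps the dominant CSF/WM peaks so GM structure
influences the fit; smoothing makes the landscape well-behaved for a
derivative-free optimizer.  During optimization the subject histogram is
pushed through the candidate transform by evaluating it as a density at
inverse-mapped bin centers (bilinear interpolation) with a 1/det(A)
Jacobian correction, which conserves mass under the change of variables.

Optimization is Nelder-Mead from a fixed list of diagonal-scaling
multistarts (identity plus +-10% combinations), keeping the best optimum;
there is no randomness anywhere, so registration is bit-reproducible.
The functional value at the optimum is the *alignment error*, which
doubles as the quality-control statistic: subjects whose histograms
cannot be brought close to the reference by any affine map (non-affine
acquisition artifacts, segmentation failures upstream) are flagged.  The
default QC criterion is median + 4 x MAD of the cohort's error
distribution, a reproducible robust-outlier surrogate for a visually
chosen fixed threshold; a numeric override is always available.

The recovered affine is applied voxelwise to the image pair, yielding
standardized volumes whose histograms approximate the reference.

### Tissue classification

In standardized space, voxels are assigned to CSF/GM/WM/lesion by a
k-means-like iteration: nearest centroid under a bin-width-scaled
Euclidean distance (so neither contrast dominates), with CSF/GM/WM
centroids re-estimated from assignments and the lesion centroid frozen
at the atlas prior (lesions are rare or absent in many subjects; a free
lesion centroid collapses onto WM).  Convergence: maximum centroid
motion <= 1e-3 bin widths or 100 iterations.  Assignment ties break
toward the lower class code (CSF < GM < WM < lesion).

A conservative lesion rule then relabels FLAIR-hyperintense, ambiguous
voxels as lesion so that the surviving WM is unconfounded NAWM: a voxel
becomes lesion when its FLAIR exceeds the WM centroid by more than 50%
of the WM-to-lesion-centroid FLAIR gap *and* the ratio of its distances
to the two nearest centroids exceeds 0.8.  Both margins are exposed in
configuration; lowering the FLAIR fraction is monotonically more
conservative (never loses lesion voxels).  No spatial regularization is
applied by default (classification is intensity-only); an optional
26-connectivity minimum-component filter exists behind a flag.

Lesion burden is summarized by lesion volume (voxel count x voxel
volume) and the mean lesion score u_lv = (1/n_L) sum_L u_l, where the
per-voxel score u_l is the FLAIR elevation above the WM centroid in
units of the WM-to-lesion-centroid gap, clipped at zero.  The score is a
dimensionless elevation: 1.0 at the lesion centroid, 0 at (or below) the
WM centroid.

### Gaussian-mixture biomarkers

Each contrast's standardized intensity distribution over the in-scope
voxels is fit with a univariate Gaussian mixture seeded at the atlas
class loci — never randomly — and the per-class (mu, sigma) are the
biomarkers.  Eight are analyzed per subject: {T1w, FLAIR} x {GM, WM} x
{mu, sigma}; CSF components are fit but not analyzed.  Component
identity is fixed by mu-ordering in reference space (T1w: CSF < GM < WM;
FLAIR: CSF < WM < GM < lesion), never by fit order.

Fitting happens twice: *lesions included* (all in-brain voxels; FLAIR
uses k = 4 with a lesion component seeded at the atlas lesion locus, T1w
stays k = 3 because lesion contrast on T1w is weak) and *lesions
excluded* (lesion-labeled voxels dropped, k = 3).  The main effect of
exclusion is to shrink sigma, the within-class spread — the
lesions-excluded WM sigma is a pure NAWM heterogeneity measure.  If the
k = 4 lesion component collapses (essentially lesion-free subject), the
fit falls back to k = 3 with a warning.

EM details: log-space E step; weighted M step (the same core serves the
voxel-level fit with unit weights and a binned fast path with bin-count
weights; the two agree to well under 1% when binning resolves the
component widths); convergence at per-sample log-likelihood change
< 1e-7 or 500 iterations; sigma floored at 1e-3 of the data range; a
component weight below 1e-4 raises a degenerate-fit error; components
whose means sit closer than 0.25 of a component SD are flagged as
merged.

### Statistics

* **Group ANOVA** — one-way, group as factor, per biomarker; the
  significance level is Bonferroni-corrected for the 8 analyzed
  parameters (alpha = 0.05/8 = 0.00625).
* **Post-hoc contrasts** — all pairwise group contrasts from the fitted
  model: pooled within-group variance (ANOVA residual MSE), N - k
  degrees of freedom, unadjusted two-sided p, binned into a star scale
  (+ p<0.05, * p<1e-2, ** p<1e-3, *** p<1e-4, **** p<1e-5).  No Tukey
  adjustment: raw post-hoc thresholds are reported as such.
* **ROC** — AUC by the rank (Mann-Whitney) construction with midrank tie
  correction; the operating point maximizes Youden's J, ties broken
  toward higher specificity; direction auto-oriented so AUC >= 0.5.
* **Disability regressions** — each biomarker Z-scored over the included
  subjects, then OLS of Z(biomarker) on intercept + PDDS; slopes are
  directly comparable across biomarkers.  PDDS (an ordinal 0-8
  self-report scale) is treated as numeric — fidelity to common practice
  over ordinal-model purity, noted here deliberately.
* **PCA composites** — multi-measure instruments (neuroperformance
  tests, 12 quality-of-life domains) collapse to their first principal
  component of the standardized score matrix; sign fixed so the
  largest-magnitude loading is positive.
* **LASSO** — L1-penalized regression of PDDS on the biomarker panel,
  features Z-scored on the training split only, penalty chosen by
  seeded 10-fold cross-validation (minimum-MSE rule by default; the
  one-SE rule is available), validated on a held-out 10%: the hold-out
  R^2 is the squared correlation between predicted and observed PDDS.
  Missing clinical data are handled complete-case per analysis.

## The synthetic-data generator

No suitable clinical dataset is publicly available, so validation runs
on phantoms that emulate the *statistical* structure the pipeline
consumes, not anatomy:

* **Geometry** — concentric ellipsoids: CSF core (10% of brain), WM
  shell (45%), GM rind (45%).  Plausible class proportions are all the
  method needs; it never uses spatial context.
* **Intensities** — each class draws (T1w, FLAIR) pairs from a bivariate
  Gaussian at the normative loci, within-class SD 40 units, plus
  additive scanner noise (SD 30 per contrast), for an effective
  within-class SD of 50.
* **Lesions** — spheres seeded inside WM; lesion intensity is
  deliberately heterogeneous (mean FLAIR elevation +750, T1w depression
  -200, SD 120), so bright cores grade into rims that overlap the WM
  tail — the regime in which lesion exclusion visibly narrows the WM
  component.
* **Diffuse NAWM pathology** — a smooth Gaussian random field added to
  WM FLAIR, rescaled to an exact per-voxel SD so the effective WM FLAIR
  sigma is known in closed form (quadrature sum).  Controls have field
  SD 0.
* **Scanner effects** — an exactly affine map of the intensity plane
  applied after noise, so inverting it recovers the reference-space
  distributions exactly and registration recovery is well-posed.  An
  optional non-affine gamma distortion stresses the QC gate.
* **Cohorts** — each subject carries a latent severity (RRMS ~ N(1,
  0.35), progressive subtypes share one profile ~ N(2, 0.45), controls
  0) and biological between-subject variation of its class mean
  intensities (SD 12 units per class and contrast; without it, mean
  parameters would discriminate groups unrealistically perfectly).
  Severity drives: lower T1w WM mean (-25/unit), small GM/WM mean shifts,
  diffuse field SD (18/unit FLAIR WM, 12/unit T1w WM), mild covariance
  widening (4%/unit), Poisson lesion counts (0.3 + 3/unit; controls'
  0.3 emulates nonspecific WM hyperintensities), PDDS (0.5 + 1.4 x
  severity + noise, rounded, clipped to 0..8), declining performance
  scores and atrophy-style covariates.  Per-subject scanner affines draw
  scales from U(0.85, 1.15), shears U(-0.03, 0.03), offsets U(-50, 50).
  Effect magnitudes were chosen once so that diffuse NAWM heterogeneity
  (FLAIR WM sigma) is the cohort's strongest control-vs-MS discriminator
  and relapsing and progressive disease remain separable, while the
  progressive subtypes are identically distributed.

What the phantoms do *not* model: partial-volume voxels at tissue
boundaries, spatially structured intensity inhomogeneity beyond the
affine term, anatomically shaped lesions (periventricular preference,
confluence), site/scanner batch structure, and any MR physics (TR/TE,
sequence effects).  Passing tests therefore show that the algorithms
recover what they claim *under the model's assumptions*; they do not
certify performance on clinical data, where partial volume and
non-affine intensity distortions will add bias the QC gate is designed
to catch only in gross cases.

## Numerical choices

* Histogram out-of-range values clip into boundary bins (voxel count is
  conserved exactly); negative post-bias-correction intensities are
  flagged at load, clipped only at histogram time.
* Registration: transforms with det(A) < 1e-3 are repelled by a penalty;
  simplex steps are ~8% on linear entries, ~3 bin widths on offsets;
  convergence at functional change < 1e-8 (parameters ~1e-3).
* The pushforward samples with nearest-mode extension over the outer
  half-bin ring and zeroes anything outside the grid, avoiding
  floating-point edge loss.
* k-means ties break toward the lower class code; empty classes warn and
  keep their previous centroid.
* All seeds derive from a single root seed via SeedSequence spawning;
  every derived seed stays below 2^31.

## Validation scale

The validation suite (tests and `scripts/acceptance.py`) runs at
desk scale, chosen to keep a full run in minutes on one CPU: 64^3-voxel
phantoms (~100k brain voxels), 128-bin histograms with three optimizer
multistarts, a 101-control atlas, 50 phantom replicates for parameter
recovery, 1000-rep null calibrations, and a 150-subject five-group
cohort (50/50/17/17/16) on 48^3 phantoms.  The default pipeline
configuration (256 bins, five multistarts) remains the production
setting.

## Known limitations

* The affine intensity model cannot correct non-linear intensity
  transfer (e.g. gamma-like distortions); such subjects are meant to be
  excluded by the QC gate, not fixed.
* Component identity by mu-ordering assumes the standardized classes
  keep the control ordering; gross pathology violating it would silently
  mislabel components (the atlas ordering check catches this at atlas
  build, not per subject).
* The conservative lesion rule trades lesion recall for NAWM purity by
  design; reported lesion volumes undercount mild rim voxels.
* PDDS-as-numeric and unadjusted post-hoc contrasts mirror common
  clinical-imaging practice rather than the strictest statistical
  treatment.
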