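# Methods

## Analysis model

The unit of replication is the lesion: all statistics pool lesions across
subjects without a within-patient clustering correction, matching the
lesion-level convention of clinical PET repeatability work. For a feature
measured on n paired lesions, relative differences use the Bland–Altman
pair-mean denominator,

    d_i = 100 · (y_retest,i − y_test,i) / ((y_test,i + y_retest,i)/2),

the within-subject CV is `wCV = √(Σ d_i²/2n)`, the repeatability
coefficient `RC = 1.96·√2·wCV`, and the 95 % limits of agreement are
`[B − RC, B + RC]` with `B = mean(d)`. The pair-mean denominator is the
single most consequential open formula choice in this family of analyses
(the cited methodology literature also admits normalising by the test
value alone); it is switchable via `denominator="test_value"` in
`petrep.repstats` and `PipelineConfig`.

ICC(A,1) is the two-way mixed-effects, absolute-agreement, single-rater
intraclass correlation computed from ANOVA mean squares with k = 2 scans:

    ICC = (MSR − MSE) / (MSR + (k−1)·MSE + (k/n)(MSC − MSE)),

with the exact F-based 95 % CI of McGraw & Wong (Satterthwaite degrees of
freedom). Reliability classes use the Koo–Li cut-points applied to the CI
lower bound: ≥ 0.90 excellent, [0.75, 0.90) good, [0.50, 0.75) moderate,
< 0.50 poor (all boundaries inclusive at the lower edge, per the half-open
intervals of that scheme). Exact test–retest equality on non-constant data
returns ICC = 1 with a degenerate (1, 1) interval; a feature constant
across lesions has no defined ICC and is flagged `icc_undefined` rather
than silently scored 0.

Relative differences are undefined for sign-crossing quantities (e.g.
skewness, cluster shade). The strict operation raises on a non-positive
pair mean; exactly equal pairs short-circuit to d = 0 so that the
zero-noise degenerate cohort is well defined for features of either sign.
In the pipeline, a feature with a non-positive pair mean and a non-zero
difference gets NaN wCV/RC/B/LOA and the flag `sign_degenerate`; its ICC
and classification are still reported.

Filter comparison uses a two-sided Wilcoxon signed-rank test of each
filter's 93-feature ICC vector against the original image's (exact null
for ≤ 25 pairs without zeros, otherwise the normal approximation with
Pratt handling of zero differences), Bonferroni-corrected with m = number
of filters; all-zero difference vectors report p = 1 with a tie flag.
Volume redundancy is the absolute Spearman rank correlation (tie-averaged
ranks) of each original-image texture feature against conventional lesion
volume.

## Imaging chain

Activity volumes convert to SUV_bw as `c[kBq/mL] · weight[g] /
injected[kBq]`. Candidate lesions are 26-connected components of
{SUV ≥ 3.0} (threshold inclusive — the common clinical-tooling
convention), and contours under 1.5 cm³ (voxel count × voxel volume) are
excluded and logged. Conventional metrics (SUVmax, SUVmean,
SUVtotal = SUVmean × volume, volume in mL) are computed on the original
grid; radiomics on a 2 mm isotropic resample — cubic B-spline for images
(an interpolating spline, so constants and linear ramps are reproduced
exactly), nearest neighbour for masks, output origin anchored to the
input origin. For throughput the pipeline crops each lesion to its
bounding box plus a 6-voxel margin before resampling; the margin keeps
the spline values at the mask border identical to a full-grid resample to
well below feature precision. Lesion matching is either `by_id` (pairing
table) or mutually-nearest-centroid within a 20 mm cap; unmatched lesions
are excluded and reported, as lesions visible on only one scan must be.

## Feature catalogue conventions

The 107-feature catalogue (14 shape + 18 first-order + 24 GLCM + 14 GLDM
+ 16 GLRLM + 16 GLSZM + 5 NGTDM) follows the public definitions of the
widely used open-source radiomics tooling, which align closely with IBSI.
Where the sources leave choices open, this package fixes:

* **Discretisation** — fixed bin width (default 0.2 SUV) with edges at
  integer multiples of the width, so bins are absolute on the calibrated
  SUV scale and the level map is invariant to shifts by whole bins.
* **Aggregation** — texture matrices use a 26-neighbourhood at distance 1
  and are direction-merged *before* feature computation (IBSI "merged");
  GLRLM run percentage divides by voxels × 13 directions.
* **GLDM** — dependence criterion |Δlevel| ≤ α with α = 0; the dependence
  size j counts the centre voxel plus its dependent neighbours, so j ≥ 1
  and small-dependence emphasis is finite.
* **Degenerate regions** — uniform regions return 0 for contrast-like
  features and 1 for uniformity/correlation-like features (GLCM
  correlation and MCC = 1, NGTDM coarseness with zero denominator = 1e6,
  busyness/strength with zero denominator = 0); first-order skewness and
  kurtosis return 0 at zero variance. Single-voxel regions return 0 for
  all pair-based families (the pipeline never produces them: the 1.5 cm³
  cut keeps ≥ 46 voxels per lesion). Every choice is unit-tested.
* **Shape** — mesh volume and surface area from a marching-cubes mesh of
  the binary support (level 0.5, physical spacing); sphericity
  `(36πV²)^{1/3}/A` therefore carries the staircase bias of binary
  meshes (≈ 0.91 rather than 1.0 for a radius-10-voxel digital ball);
  axis lengths 4·√λ from the PCA of physical voxel coordinates; 2-D
  diameters from per-slice surface-voxel point clouds.
* **Filters** — LoG in physical units (σ in mm, response in SUV/mm²,
  truncated discrete kernel, no scale normalisation); wavelets are a
  one-level undecimated separable 3-D transform, Coiflet-1, symmetric
  extension, subband letters following array axis order (x, y, z);
  intensity transforms are monotone and range-preserving with
  M = max|SUV|: square x→x²/M, square root x→sign(x)√(|x|M), logarithm
  x→sign(x)·M·log(|x|+1)/log(M+1), exponential x→exp(x·log M / M).
  Shape features are computed once on the unfiltered mask geometry.

## Synthetic paired phantom

The generator emulates the *structure* of a two-tracer test–retest study,
not scanner physics: per-subject volumes on a 4.07 × 4.07 × 2 mm grid,
6 mm FWHM isotropic Gaussian post-smoothing, additive Gaussian noise
truncated at zero, and non-overlapping ellipsoidal lesions (rejection-
sampled centroids, 1000-attempt cap) whose interior uptake is
mean SUV × a log-normal spatially correlated texture field (exponentiated
Gaussian random field, Gaussian-kernel correlation, normalised to unit
mean) — log-normal so uptake stays positive and heterogeneous. Masks are
the pre-blur ellipsoid supports and are shared between test and retest,
so phantom lesion *volume* is perfectly repeatable by construction.

Defaults, chosen once for realism and testability: background SUV 0.5
(PSMA-avid disease sits on a low soft-tissue background), lesion mean SUV
uniform in 5–12 (well above the SUV 3 segmentation threshold), semi-axes
8–15 mm (minimum sphere 2.1 cm³, safely above the 1.5 cm³ cut), texture
correlation length 8 mm with log-σ 0.3, noise SD 0.05 SUV. Setting the
correlation length (or log-σ) to zero disables heterogeneity exactly,
which the degenerate test cases rely on. No sinogram/reconstruction
simulation, motion, or CT is attempted; the magnitudes of noise and
heterogeneity in real lesions are not identifiable from published
summaries, so passing recovery tests demonstrates estimator correctness
under the stated variability model, not fidelity to any scanner.

Retest variability is injected per lesion (not per voxel), matching the
lesion-level unit of analysis: the pre-blur lesion uptake is multiplied by
`f = (1 + bias/100) · (200 + d)/(200 − d)` with `d ~ N(0, 2·wCV²)`
(clipped to |d| < 190), so the pair-mean relative difference of the
lesion uptake equals d identically and the theoretical wCV equals the
injected value by construction; with zero variability the mean relative
difference has closed form `B = bias/(1 + bias/200)` (18.18 for a 20 %
bias). Measured on SUVmean of the blurred image, observed differences are
attenuated by the background contribution inside the mask — about 3 %
under the defaults — so recovered wCVs sit slightly below the injected
value on top of the ~5 % Monte-Carlo spread of the estimator at n = 200.

## Problem sizes and numerics

The validation suites run phantom cohorts of 20 subjects × 10 lesions
(200 pairs) per injected-wCV level on 96 × 96 × 64 grids, and the
degenerate zero-noise cohort with 8 lesions and the full 107-feature
extraction; texture-matrix oracle checks use 50 random lesions of ≤ 100
voxels against brute-force enumerators at 1e-9, and the ICC against an
explicit sums-of-squares oracle on 100 random datasets at 1e-10. Matrix
constructions are exact integer counts, so tolerances only absorb
floating-point summation order. Wilcoxon p-values switch from the exact
null to the corrected normal approximation above 25 pairs for
reproducibility across implementations.

## Known limitations

* Feature values are not regression-pinned against the reference
  radiomics tool; correctness rests on the independent in-repo
  brute-force oracles and documented conventions, so individual feature
  values may differ from other tools where those conventions differ
  (e.g. per-angle-averaged vs merged texture aggregation, kurtosis
  offset, GLDM column convention).
* The phantom's intertracer "bias" is a pure multiplicative uptake shift;
  real tracer differences also change background, noise texture and
  segmentation behaviour.
* Segmentation-induced variability is absent by design (one mask per
  lesion pair); volume repeatability on phantoms is therefore perfect
  rather than realistic.
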