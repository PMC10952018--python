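# Methods

## Problem and scope

`lesionkit` quantifies the *relative positioning* of hypermetabolic lymphoma
lesions on FDG-PET — how clumped (aggregated) or spread out (disseminated)
the disease is — and evaluates the prognostic value of the derived
indicators. The chain is:

1. segment lesions from a 3D SUV volume by fractional-SUVmax thresholding;
2. convert each lesion to a watertight triangular mesh and measure volume,
   surface area, and maximum diameter;
3. derive patient-level indicators: TMTV (total metabolic tumor volume, the
   sum of lesion volumes, mm³), TTS (total tumor surface, mm²),
   TVSR = TMTV/TTS (mm), the bulky-disease flag (any mass with diameter
   > 5.0 cm) and the extra-stage flag (lesions above *and* below the
   diaphragm and more than one distinct extranodal site);
4. analyze a cohort with Kaplan–Meier curves, log-rank tests, Cox
   proportional-hazards models, Spearman correlation, and ROC analysis with
   the Youden-index cutoff.

Clinical staging, response assessment, and DICOM ingestion are out of scope;
Ann Arbor stage and per-lesion anatomical sites are inputs, never derived
from image content (a synthetic-cohort-only stage derivation exists solely
to generate internally consistent test data).

## Segmentation

The SUV threshold is a fraction (default 0.41) of SUVmax with a *strict*
inequality, `SUV > f · SUVmax`. Two reference conventions exist in practice
and both are implemented: `global` (fraction of the volume-wide SUVmax, the
default) and `per_lesion`. Re-thresholding a component at 41% of its own
SUVmax restricted to its existing voxels would be a no-op (a component's
SUVmax never exceeds the global one), so `per_lesion` is implemented as
region re-growth: each candidate component found by the global pass is
replaced by the connected component of `SUV > f · (its own SUVmax)` that
contains it. Neither convention is asserted to be "the" correct one; results
in this package default to `global`.

Connected components use 26-connectivity for the foreground and the dual
6-connectivity for background/cavity detection — the standard digital-
topology pairing that prevents a surface from being simultaneously
"connected" and "leaky". Both are configurable. Labels are renumbered in
order of each component's first voxel in a C-order scan, making labeling
deterministic across platforms.

Hole filling classifies background components by reachability from the grid
boundary (6-connectivity); unreachable pockets are cavities and are assigned
to the label owning the majority of their adjacent foreground voxels (ties
to the lower label, with a warning when a cavity touches several labels).
Components smaller than `min_voxels` (default 2) are discarded first as
noise specks; the study-scale default exists because additive noise in
phantoms otherwise produces isolated supra-threshold voxels.

## Meshing and measurement

Each cavity-free component is converted to a closed surface by marching
cubes on its 0/1 indicator at iso-level 0.5, with a one-voxel zero pad so
components touching the grid edge still close, in world millimetres
honoring anisotropic spacing. The classic Lorensen table is used: on binary
fields it produced watertight meshes for every component in extensive
randomized testing, whereas the Lewiner variant occasionally leaves open
edges on speckled components. Degenerate faces are dropped and vertices
deduplicated at 1e-9 mm before validation; every mesh must pass the
edge-to-face-incidence-2 check and has positive signed volume by
construction (orientation is flipped if needed).

Voxel jaggedness is removed by Taubin two-step (shrink-limited) smoothing
rather than plain Laplacian smoothing, which systematically shrinks volume.
Defaults are λ = 0.5, µ = −0.53, 30 iterations, chosen against the analytic
sphere oracle: across digitized spheres of radius 8–15 mm at 1 mm spacing
the smoothed-mesh volume error stays under ~2%, surface error under ~1%,
and the TVSR identity error (see below) under 2%. `smooth_mesh` refuses
parameter choices that change volume by more than 10% — smoothing is meant
to remove staircase artifacts, not to resculpt the lesion. How much
smoothing any given clinical pipeline applies is generally unreported, so
absolute TTS values are comparable only within one smoothing convention.

Measurements are computed from first principles: signed volume by the
divergence theorem, V = (1/6) Σ v₀ · (v₁ × v₂) over faces; surface as the
sum of triangle areas; maximum diameter as the 3D caliper (Feret) diameter,
i.e. the maximum pairwise vertex distance, evaluated on convex-hull
vertices (the maximum is attained there). The 3D caliper was chosen over an
axial-slice RECIST-style diameter because it is orientation-independent;
this convention choice affects which lesions are called bulky when a mass
is elongated along the scanner axis.

## Indicators

* TMTV and TTS are plain sums of per-lesion mesh volume and surface.
* TVSR = TMTV/TTS (mm); undefined (error) when TTS = 0. For a single sphere
  TVSR = r/3, which makes TVSR a monotone function of volume — the
  mechanism behind the strong TVSR–TMTV rank correlation in cohorts whose
  patients carry a few sphere-like lesions. The isoperimetric inequality
  gives the sharp bound TVSR ≤ (3·TMTV/4π)^{1/3}/3, with equality only for
  a single sphere; measured lesions must satisfy it within 1% mesh
  tolerance.
* Bulky disease: any lesion with maximum diameter strictly greater than
  50.0 mm.
* Extra stage: lesions above *and* below the diaphragm, and strictly more
  than one distinct extranodal organ involved. Sites are counted as
  distinct `organ_id` values, not lesion counts (IPI convention: one organ
  with three lesions is one site). The diaphragm is modeled as a
  configurable z-plane; side labels derive from lesion centroids against
  that plane when not supplied.
* The synergy grouping is the ordinal {neither, either, both} of the two
  flags.

## Survival statistics

Kaplan–Meier and the log-rank test are implemented directly so the exact
intermediate tables (at-risk counts, observed/expected/variance per event
time) are exposed for auditing; both are cross-checked against lifelines in
the test suite. The log-rank statistic uses the full hypergeometric
covariance of the first K−1 groups with K−1 degrees of freedom. The median
survival convention is the first time with S(t) ≤ 0.5 (undefined if the
curve never reaches 0.5).

Cox models are fitted with lifelines' `CoxPHFitter` (Efron tie handling —
less biased than Breslow with the many ties day-resolution times produce);
the package surface adds input validation (≥ 2 events, non-constant
covariates) and treats a diverging coefficient (|β| > 15) as complete
separation. The fitted coefficient is verified in tests against brute-force
maximization of the explicitly coded partial likelihood on small tie-free
data.

ROC analysis enumerates every distinct score as a candidate cutoff (plus
one below the minimum); a positive call is `score > cutoff` (strict). AUC
is the trapezoidal area over the resulting staircase, which on tie-free
data equals the Mann–Whitney U statistic divided by n₁·n₀; the Youden
cutoff maximizes sensitivity + specificity − 1 with ties broken toward the
smallest cutoff so output is deterministic. P-values are two-sided
throughout and no multiple-testing correction is applied anywhere.

## Synthetic data: what it emulates, and what it does not

No patient-level dataset for this problem is publicly deposited, so
validation rests on two generators whose ground truth is closed-form.

**Phantoms.** Lesions are uniform-intensity spheres/ellipsoids (any
threshold strictly between background and peak recovers the exact shape)
or Gaussian blobs, whose iso-contour at fraction f of the peak is the
sphere of radius r* = σ√(2 ln(1/f)) — about 8.013 mm for σ = 6 mm at
f = 0.41. Truth volumes and surfaces are analytic; ellipsoid surfaces use
the exact Legendre elliptic-integral formula rather than an approximation.
Lesion profiles are composed with the uniform background by voxelwise
maximum so the closed forms survive rasterization; noise is additive
Gaussian truncated at zero (the simplest defensible model — no scanner
physics, attenuation, or partial-volume modeling is attempted). Lesions
extending beyond the grid are rejected by name, as are overlapping lesions
with conflicting site annotations (their truth would be ambiguous). A blob
whose center falls between voxel centers has a sampled SUVmax slightly
below its analytic peak, which shifts the 41% contour outward by a
sub-voxel amount; per-lesion truth is defined against each lesion's own
peak, so phantoms mixing blobs of unequal peaks under the global reference
have no exact per-lesion truth.

**Cohorts.** Patients receive independent Bernoulli bulky/extra-stage
flags, analytic sphere lesions consistent with those flags (non-bulky radii
6–18 mm; a bulky patient adds one 28–40 mm mass; extra-stage patients get
lesions on both diaphragm sides in two distinct extranodal organs), and
progression times by the proportional-hazards inverse transform
T = −ln(U)/(h₀·exp(β_b·x_b + β_e·x_e)) with uniform administrative
censoring on (0, censor window). Defaults describe a plausible relapsed
lymphoma cohort: n = 42, P(bulky) = 0.26, P(extra) = 0.33, baseline hazard
1/500 per day (median uncensored event time ≈ 347 days), both log hazard
ratios ln(2.5), two-year censor window. Overall survival adds an
independent exponential post-progression time at half the baseline hazard
under the same linear predictor — a convenience that keeps OS ≥ PFS, not a
fitted model. Complete response is drawn from a logistic model,
logit P(CR) = 2.0 − 0.35·TVSR − 0.7·bulky − 0.7·extra, so the ROC analysis
has a discoverable signal. Effect sizes are calibration choices for the
generator, not estimates of any clinical cohort. Random streams are split
per purpose (flags / geometry / survival) via `SeedSequence.spawn`, so
changing the cohort size leaves earlier patients' flags untouched.

What passing tests therefore show: the geometry pipeline is unbiased to
within stated tolerances on shapes with analytic truth, the statistics are
correctly calibrated under the generator's null, and known effects are
recovered. What they do not show: performance on real PET data with
heterogeneous uptake, physiological background (brain/bladder), respiratory
motion, or partial-volume blur.

## Numerical choices and degenerate inputs

* Thresholding an all-zero volume is an error (SUVmax = 0 degenerates the
  threshold); an empty post-filter segmentation is a valid empty result
  with a warning.
* Voxel centers sit at `origin + index · spacing`, 0-based — pinned so mesh
  coordinates are testable; only diagonal (axis-aligned) NIfTI affines are
  accepted.
* An all-censored sample yields S ≡ 1 with undefined (NaN) median; a
  single-class label vector, a constant covariate or a constant Spearman
  input are errors rather than NaNs.
* Per-lesion mesh failures during measurement are logged and skipped so one
  pathological component cannot abort a patient; per-analysis failures in
  the study battery are collected under `errors` while the remaining
  analyses run.
* In the study battery TVSR enters the Cox model as the binary
  "above the Youden cutoff" covariate, mirroring how a continuous marker is
  dichotomized at its ROC-derived cutoff in clinical analyses.

## Problem sizes used in validation

The packaged validation suite runs on deliberately modest sizes chosen to
exercise every code path with analytic cross-checks: 32³–44³ voxel
phantoms at 1 mm spacing (50-lesion suites for the TVSR bound), 100 random
20³ masks for the flood-fill/BFS comparison, 1000 simulated cohorts of
n = 100 for null calibration of log-rank and Cox at the nominal 5% level,
200 cohorts of n = 300 for log-HR recovery (mean bias < 0.1 on ln 3), and
a demonstration cohort of n = 200 for the synergy stratification. Sphere
recovery converges with resolution (tested at 2.0/1.0/0.5 mm), so larger
grids only tighten the same comparisons.

## Known limitations

* Absolute TTS (hence TVSR) depends on the smoothing convention; only the
  package's own defaults are calibrated.
* The bulky flag is measured on the 41% iso-contour mesh; pipelines that
  measure mass diameter on CT anatomy may disagree near the 5 cm boundary.
* The extra-stage flag requires per-lesion site annotations; it is never
  inferred from image coordinates except for the diaphragm side of
  synthetic lesions.
* The cohort generator draws the two flags independently, while in real
  cohorts bulk and dissemination are correlated with tumor burden; the
  generator is a calibration instrument, not an epidemiological model.
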