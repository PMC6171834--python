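# Methods

## Scope and data model

The package quantifies inner and outer retinal layers on macular-cube
SD-OCT: a 6×6 mm raster of 512 A-scans × 128 B-scans, each A-scan
sampled axially (default 1.953125 µm/sample, i.e. a 2 mm cube depth over
1024 samples — the axial sampling of the acquisition platform is not
part of the published protocol, so it is an explicit `ScanGeometry`
parameter rather than a constant). Four interfaces are tracked per
A-scan, ordered by depth: ILM, the proximal ONL/HFL boundary (the
"inner retina" runs from the ILM to this boundary, labelled ILM–OPL),
the proximal EZ edge, and the proximal RPE edge. All downstream metrics
are deterministic functions of these four surfaces.

The lateral grid is cell-centered: A-scan *i* sits at
(*i* + ½)·(6/512) mm, so 1 mm equals 85.33 A-scan pitches and
juxtafoveal sampling must interpolate (linear interpolation between
A-scan centers is used).

## Boundary segmentation

Each B-scan is segmented independently. A boundary is the minimum-cost
left-to-right path through a cost image, found by dynamic programming
with a per-column vertical step limit of ±2 samples and a small
per-sample move penalty λ = 0.01 (in normalized-intensity units). The
step limit is calibrated to the 512-column lateral resolution, where the
steepest anatomy (the foveal pit wall) moves ≲ 2 samples per column;
coarser test grids must scale it accordingly.

Preprocessing divides each A-scan by its mean intensity and applies a
Gaussian blur of σ = 1 sample axially and 1 column laterally. Costs:

1. **ILM** — negative axial gradient plus `vitreous_penalty` (3.0) times
   the mean intensity of the 8 samples above the candidate. The penalty
   is what distinguishes the vitreoretinal interface from the deeper,
   stronger dark→bright EZ edge: only the ILM has a dark vitreous above.
2. **RPE** — negative gradient minus the mean intensity of the 8 samples
   below, searched below ILM + 60 µm: the edge onto the brightest band.
3. **EZ** — negative gradient, between ILM + 20 µm and RPE.
4. **ONL/HFL** — positive gradient (bright inner plexiform complex above,
   dark ONL below), between ILM and EZ.

The ILM and RPE costs carry regional brightness terms that localize the
correct band but bias the optimum off the edge by about one sample; a
post-DP snap to the strongest gradient within ±3 samples removes that
bias while the DP keeps the global structure. Ties break toward the
shallower position (the backtracking argmin takes the first index; the
snap prefers the deeper of exactly tied gradients, which centers the
residual error). Columns whose gradient at the chosen EZ position is
below `ez_contrast_threshold` (0.01 normalized units/sample) are encoded
as EZ = RPE — zero EZ–RPE thickness, the "total attenuation" encoding.
Scans with signal strength < 7 are rejected at the QC gate; a flat
(degenerate) cost image flags the B-scan low-confidence without
aborting. Manual corrections are applied through `SurfaceEdit` records
that re-validate the ordering and mark edited cells `corrected`.

Whether the reference tool segments the proximal or distal EZ edge is
not documented; the proximal (inner) edge is segmented here, which is
the convention consistent with EZ–RPE thickness as an outer-segment
length proxy.

## Metric engine

* **Fovea localization** is not part of the published protocol; the
  fovea is taken as the minimum of the inner-retina (ILM–OPL) thickness
  map after Gaussian smoothing (σ = 0.25 mm), restricted to the central
  3×3 mm, with ties broken toward the cube center, then smaller x, then
  smaller y. A flat inner map returns the cube center with a QC flag.
* **Point thicknesses** are read on the foveal B-scan, linearly
  interpolated along x; nasal/temporal direction is resolved from the
  eye's laterality and the `od_nasal_side` convention (default: nasal is
  +x for OD, mirrored for OS — set this consciously for real exports).
* **B-scan area** integrates the thickness profile over the full 6 mm
  extent: piecewise linear between A-scan centers with constant
  extension over the two half-cell margins, which reduces exactly to
  pitch × Σ thickness. **Volume** is midpoint quadrature, cell area ×
  thickness, so volume = mean thickness × 36 mm² identically.
* **En face attenuation** counts all 512×128 en face cells (no circular
  mask) with EZ–RPE thickness < 20 µm; **total loss** counts cells at
  zero, with a quantization guard of half an axial sample (fractional
  surfaces rarely coincide exactly). Loss cells are a subset of
  attenuation cells by construction.

## Synthetic phantom

The phantom anchors the retina at a flat-ish RPE (plus smooth
perturbation fields of configurable amplitude and 0.5 mm lateral
correlation length): a real fovea is a dip of the ILM, not a bump of the
outer bands. Inner-retina thickness is peripheral thickness (190 µm)
minus a Gaussian pit (depth 168.5 µm, e-folding radius 0.34 mm) plus a
linear nasal–temporal gradient (±40 µm at the scan edges, emulating the
thicker nasal nerve fiber layer); the outer retina (160 µm) and the
EZ–RPE band (50 µm) are laterally constant, so the generator provides
closed-form expected metrics. Rendering assigns six band reflectivities
(vitreous 0.05, inner retina 0.40, ONL/HFL 0.12, EZ–RPE 0.60, RPE 0.85,
choroid 0.30; the RPE band extends 15 µm), then applies vessel-shadow
columns (multiplying everything below the ILM), gamma multiplicative
speckle of configurable contrast, and additive Gaussian noise.

The phantom is a geometry-and-contrast model, not an optics model: no
coherent speckle statistics, no point-spread function, no motion
artifacts, no curvature of Bruch's membrane. Passing recovery tests
therefore demonstrates correctness of the path-finding and measurement
machinery under realistic layer contrast and noise amplitude, not
clinical-grade robustness on device exports.

## Synthetic cohorts

The per-eye dataset behind the published normative tables is not
redistributable, so two generators stand in for it. Both use the
normative configuration: for each of the 20 metrics the published cohort
mean, SD, range, male/female means and Pearson correlation with age
(one published male group mean is internally inconsistent with the
printed total and female means and is replaced by the value they imply;
see the configuration module). Sex effects are applied as the published
male−female gap, weighted so the cohort mean stays at the configured
total, because the printed per-sex means are rounded to 2 dp and not
exactly consistent with the printed totals.

**Stochastic sampler** (`generate_cohort`): ages uniform on 10–85 years
(the published cohort is left-skewed — median 55, mean 49.7 — and an
optional mixture reproduces that, but uniform is the default for
simplicity); each Gaussian metric is mean + sex offset + *r*·sd·z(age) +
√(1−*r*²)·sd·ε, clipped to the published [min, max]. Moments are matched
*before* clipping; the residual bias is small (largest for central
inner-retina thickness, whose min = 0 truncates ≈ 5–6 % of the normal
mass, ≈ +0.3 µm ≈ 1.7 SE at n = 5000). The attenuation percentages are
grossly non-normal (mean 0.87 %, SD 1.13 %, min 0.01 %) and use a
zero-inflated gamma marginal matched to (mean, SD) coupled to age
through a Gaussian copula; the latent correlation is calibrated by
two-dimensional Gauss–Hermite quadrature (and bisection) so the
*realized* Pearson r, including the clip, equals the configured value.
Metrics are conditionally independent given age and sex — the
within-subject covariance of the real cohort is unknown.

**Moment-matched stand-in** (`synthetic_reference_cohort`): 167 eyes,
66 M / 101 F, whose *sample* moments equal the published values exactly
— per-metric mean and SD (n−1), Pearson r with age, and sex gap — by
exact orthogonalization: ages are per-sex quantile grids (identical
group means, making the sex contrast exactly orthogonal to age), and the
noise vector is residualized against {1, z(age), sex contrast} and
standardized exactly. Skewed residuals (gamma-shaped) are used for the
attenuation metrics, but the linear mixing can produce slightly negative
attenuation values: sample moments, not marginal shapes, are this
generator's contract. This is the table every published statistic is
recomputed from; because the published group SDs cannot be matched
simultaneously with the totals (printed rounding), recomputed t-test
p-values land within rounding of the published ones (e.g. 0.005 vs
0.004 for the temporal total-thickness sex difference) rather than
exactly on them.

Demographics: sex 60.5 % female, laterality 52.1 % right, acuity
categories at the published counts, spherical equivalent normal
(−0.48 D, SD 1.8 D chosen as realistic; not published) clipped to the
published range.

## Statistics

Sample SDs use the n−1 denominator. Correlation p-values come from the
t-transform on n−2 df, two-sided. The sex comparison defaults to the
pooled-variance (Student) t-test with the Welch flavor available — the
published analysis names only "T test", and the pooled flavor reproduces
the published p-values on the stand-in. The age-band comparison is
one-way fixed-effects ANOVA over the closed integer bands 10–30, 31–50,
51–70, 71–85 (the published methods text lists an overlapping fourth
band, impossible as written; the table headers' 71–85 is used, and any
band layout can be configured). No multiple-testing correction is
applied, matching how the battery is reported; two-band ANOVA equals the
squared pooled t-test, which the tests verify. Zero-variance inputs are
errors, not NaNs.

## Problem sizes and determinism

Phantom experiments run at 512 A-scans × 8 B-scans × 320 axial samples:
full lateral resolution (which the DP step limit is calibrated to) with
a shortened slow axis and depth, keeping each cube render-and-segment
cycle around two seconds while exercising every code path; accuracy is
per-A-scan, so the shortened slow axis does not weaken the check.
Segmentation recovery is evaluated over 5 phantom seeds; cohort moment
recovery at n = 5000; the reference statistics at the study's n = 167.
All randomness flows through explicit integer seeds
(`numpy.random.default_rng`), and the pipeline writes byte-identical
CSVs for identical config + seed, with a config hash recorded in the
provenance JSON.

## Known limitations

* Single-surface-per-column DP per B-scan; no 3-D multi-surface graph
  optimization, so pathology with surface folds or detachments is out of
  scope.
* No magnification correction for refraction/axial length; nasal/temporal
  orientation of real exports must be supplied by the user.
* The cohort generators model marginals and first-order age/sex
  structure, not inter-metric covariance; statistics that pool across
  metrics should not be validated against them.
* The phantom's noise is an amplitude model only; segmentation accuracy
  on real device exports will depend on contrast and artifact content
  not represented here.
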