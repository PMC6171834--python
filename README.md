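# retmetrics

Quantitative analysis of inner and outer retinal layers on macular
SD-OCT, with a focus on the ellipsoid zone (EZ). The package is aimed at
retinal imaging researchers who need normative outer-retinal metrics:
it segments the four key interfaces of a 512×128 macular cube — the
internal limiting membrane (ILM), the proximal boundary of the outer
nuclear layer / Henle fiber layer complex (ONL/HFL), the proximal EZ
edge, and the retinal pigment epithelium (RPE) — and converts them into
the standard per-eye metric battery:

* **thicknesses** (µm): central foveal and juxtafoveal (±1 mm nasal /
  temporal on the foveal B-scan) for ILM–RPE (total retina), ILM–OPL
  (inner retina), ONL/HFL–RPE (outer retina) and EZ–RPE;
* **areas** (mm², foveal B-scan) and **volumes** (mm³, full cube) for
  ONL–EZ, EZ–RPE and ONL–RPE;
* **en face EZ mapping** (%): EZ attenuation (EZ–RPE thickness < 20 µm)
  and total attenuation (EZ–RPE thickness = 0 µm) as percentages of the
  6×6 mm macular map.

A cohort-statistics layer reproduces the analyses of a normative study
of 167 normal eyes: per-metric mean ± SD and range (overall and by sex),
Pearson correlations with age (p from *t* = *r*√(n−2)/√(1−*r*²) on n−2
df), pooled two-sample t-tests between males and females, and one-way
ANOVA across the age quartiles 10–30, 31–50, 51–70 and 71–85 years.

Because raw clinical cubes cannot ship with the code, the package
includes a first-class synthetic layer: a phantom generator (foveal pit,
nasal–temporal asymmetry, speckle, vessel shadows) that provides exact
ground truth for the segmenter and metric engine, and a cohort generator
that draws per-eye records with the published normative structure
(means, SDs, age correlations *r*, sex gaps; right-skewed zero-inflated
gamma marginals for the attenuation percentages, coupled to age through
a calibrated Gaussian copula).

## Segmentation model

Each B-scan is segmented independently as four ordered minimum-cost
paths found by dynamic programming: for surface *s* with cost image
*C*ₛ(x, z), the path *z(x)* minimizes Σₓ *C*ₛ(x, z(x)) + λ·|Δz| subject
to |z(x+1) − z(x)| ≤ 2 samples. Costs are built from per-A-scan
normalized, lightly smoothed intensity: dark→bright gradient with a
vitreous-brightness penalty (ILM), gradient onto the brightest band
(RPE), dark→bright gradient between ILM and RPE (EZ), bright→dark
gradient between ILM and EZ (ONL/HFL). Surfaces are extracted
sequentially, each confined to the band allowed by those already found,
so ILM ≤ ONL/HFL ≤ EZ ≤ RPE holds everywhere; columns with no detectable
EZ edge are encoded as EZ = RPE (zero EZ–RPE thickness). On noiseless
phantom renders every surface is recovered within 0.7 axial samples RMS,
and within 1.3 samples at speckle contrast 0.3.

## Worked example

```python
from retmetrics import (ScanGeometry, SurfaceModelParams, RenderParams,
                        generate_surfaces, render_cube, segment_boundaries,
                        compute_eye_metrics)

geo = ScanGeometry(n_ascans_x=512, n_bscans_y=8, n_axial_z=320)
truth = generate_surfaces(geo, SurfaceModelParams(seed=0))
cube = render_cube(truth, geo, RenderParams(speckle_contrast=0.0,
                                            additive_noise_sd=0.0))
surfaces, qc = segment_boundaries(cube)
m = compute_eye_metrics(surfaces, laterality="OD")
print(f"CFT {m.ilm_rpe_central_um:.1f} um, EZ-RPE {m.ez_rpe_central_um:.1f} um,"
      f" EZ-RPE volume {m.ez_rpe_volume_mm3:.2f} mm3,"
      f" attenuation {m.ez_attenuation_pct:.2f} %")
```

prints

```
CFT 261.7 um, EZ-RPE 52.7 um, EZ-RPE volume 1.80 mm3, attenuation 0.00 %
```

i.e. for this phantom eye the central foveal ILM–RPE thickness is
261.7 µm (high relative to a clinical fovea because this demo cube has
only 8 B-scans, so the foveal row misses the exact pit center), the
photoreceptor outer-segment (EZ–RPE) band measures 52.7 µm at the fovea
and 1.80 mm³ over the 6×6 mm cube, and no en face cell falls below the
20 µm attenuation threshold. The statistics layer
runs the same way on any per-eye table:

```python
from retmetrics import synthetic_reference_cohort, summarize, pearson_with_covariate
t = synthetic_reference_cohort(seed=0)            # 167 eyes, 66 M / 101 F
print(summarize(t).loc["ilm_rpe_central_um"])      # mean 200.58, sd 19.22
print(pearson_with_covariate(t, "ez_attenuation_pct", "age").r_value)  # -0.48
```

The numbered scripts under `analysis/` run the same computations as a
narrative sequence (simulate cohorts → phantom segmentation accuracy →
cohort statistics tables and plots → end-to-end pipeline) and write
their tables under `results/`. A `retmetrics` CLI wraps the pipeline
stages (`simulate`, `segment`, `metrics`, `cohort-stats`, `run`) for
shell use.

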