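# socmetrics

Quantitative analysis for organ-on-chip endothelial lumen experiments — in
particular synovium-on-chip devices in which an endothelial tube forms in a
~1300 µm wide microfluidic channel and progressively remodels (narrows)
under co-culture with migrating fibroblast-like synoviocytes.

The package implements the three quantitative stages of such a study, plus
synthetic-data generators so that every stage is testable without raw
microscopy:

1. **Projected lumen width** (`socmetrics.lumen`). Top-down fluorescence
   images of the RFP-labeled endothelium are sampled with evenly spaced
   cross-channel intensity profiles (default 25 µm spacing, 100 µm edge
   margins). A per-image Otsu threshold, scaled by an empirical correction
   factor, marks the lumen band on each profile; the projected width is
   the distance between the outermost supra-threshold runs,
   `w = (right − left) · pixel_size`, and the per-chip value is the mean
   over valid profiles.
2. **Cell morphometry** (`socmetrics.morphometry`). From integer label
   masks of the VE-cadherin-segmented endothelium: area, moment-ellipse
   aspect ratio (major/minor), and the maximum Feret diameter and its
   angle relative to the chip horizontal. Border-touching cells are
   removed; regions smaller than 200 µm² are filtered out as segmentation
   artifacts.
3. **Longitudinal statistics** (`socmetrics.stats`). Per-chip widths over
   the culture days are modeled with a repeated-measures linear mixed
   model: saturated day × group fixed effects, no random effects, and a
   shared *unstructured* covariance Σ across days, fitted by REML with
   chips that drop out contributing their observed days through the
   direct likelihood. Group divergence is declared at the first day whose
   95 % confidence intervals no longer overlap. Morphometric descriptors
   are compared with a tie-corrected Kruskal–Wallis ANOVA and Dunn's
   post-hoc test (Bonferroni-adjusted).

The model for chip *i* in group *g* with observed day set *O<sub>i</sub>* is

&nbsp;&nbsp;&nbsp;&nbsp;**y**<sub>i</sub> ~ N( **μ**<sub>g</sub>[O<sub>i</sub>], Σ[O<sub>i</sub>, O<sub>i</sub>] ),

with one free mean per (day, group) cell and one free covariance parameter
per day pair — the "time, group, time×group, unstructured covariance"
specification familiar from SPSS/SAS repeated-measures MIXED analyses.

## Worked example

```python
from socmetrics import (SceneConfig, generate_lumen_scene, measure_image,
                        CohortDesign, generate_cohort, fit_lmm,
                        ci_divergence_day, describe_widths)

# Render a noisy day-10 co-culture scene (true width 1023 µm) and measure it
cfg = SceneConfig(lumen_width_um=1023.0, noise_sd=18.0, seed=42,
                  chip_id="chip-17", day=10, group="co-culture")
image, truth = generate_lumen_scene(cfg)
m = measure_image(image)
print(f"true mean width : {truth.mean_width_um:.2f} um")
print(f"measured width  : {m.mean_width_um:.2f} um ...")

# Simulate the study-sized cohort and fit the repeated-measures model
cohort = generate_cohort(CohortDesign(seed=1))
fit = fit_lmm(cohort)
div = ci_divergence_day(fit)
```

prints

```
true mean width : 1023.00 um
measured width  : 1020.41 um (148/148 valid profiles, threshold 109.1)
cohort          : 450 chip-day records
day 10 co-culture: 1008.97 +/- 82.49 um (n=26)
day 10 control   : 1323.22 +/- 62.19 um (n=6)
first day with non-overlapping 95% CIs: day 5
```

The measured width sits within one pixel (3.25 µm) of the rendered truth;
the cohort reproduces the designed endpoint means (control holding the
~1300 µm channel width, co-culture remodeled to ~1023 µm) and the
confidence-interval overlap rule localizes the onset of the group
difference.

A command-line interface mirrors the library:

```bash
socmetrics simulate-cohort --out cohort.csv --seed 1
socmetrics stats-lmm --cohort cohort.csv --out stats/
socmetrics measure-width --images images/ --out widths/
socmetrics run-all --config pipeline.yaml
```

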