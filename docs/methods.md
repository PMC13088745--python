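# Methods

## Projected lumen width

The lumen formed in the bottom channel is imaged top-down; its projected
width is the footprint of the fluorescent endothelium along a
cross-channel intensity profile. The measurement chain is:

1. **Orientation.** The channel runs along image rows; the leftmost wall
   is selected manually (`WallCalibration`) or proposed automatically as
   the center of the leftmost dark band of the brightfield column-mean
   profile. Automatic detection is a convenience; the manual mode is
   authoritative.
2. **Threshold.** One Otsu threshold per image, computed on a 256-bin
   histogram of the full fluorescence raster and multiplied by an
   empirical `correction_factor` (default 1.0, always surfaced in the
   output tables). A per-image rather than per-profile threshold is used
   because single-profile histograms (a few hundred pixels) are too
   sparse for a stable two-class split.
3. **Profiles.** Grid positions `margin, margin+spacing, …, extent−margin`
   with spacing 25 µm and margin 100 µm by default; `extent` is the
   physical position of the last image row. The margin excludes edge
   regions where the lumen leaves the field of view. The profile count is
   therefore a function of image extent, not a constant.
4. **Edges.** On each profile, the left edge is the start of the first
   run of ≥ `min_run_px` (default 3) pixels strictly above threshold and
   the right edge the inclusive end of the last such run. The run-length
   requirement rejects hot pixels. Profiles with no qualifying run are
   flagged invalid and counted, never silently dropped; an image with no
   valid profile raises.
5. **Width.** `(right − left) · pixel_size`. Profiles are perpendicular
   to the channel axis, so the Euclidean distance between the edge points
   reduces to this 1-D separation. Edge localization is at pixel
   resolution (±1 px error budget); sub-pixel interpolation was
   considered and rejected as spurious precision given that the dominant
   errors (blur, threshold placement) exceed a pixel.

The per-chip value is the mean over the valid profiles of the image;
multiple images of one chip would be averaged with equal weights.

## Synthetic scenes

`generate_lumen_scene` renders what the measurement assumes: a band of
`intensity_lumen` between per-row continuous edges centered between the
walls, over `intensity_background`, then Gaussian blur (σ default 1 px),
an optional multiplicative illumination ramp, and additive Gaussian noise
(default σ = 5 on a 180-unit contrast, ≈3 %). Additive Gaussian noise is
the simplest model adequate for recovery testing; shot-noise or
camera-specific models can be slotted in where the noise is applied. The
default geometry is 1200×600 px at 3.25 µm/px with walls at columns 100
and 500 — i.e. a 1300 µm channel with margin, matching the device
description; field-of-view and bit depth of the original acquisitions are
not public, so these defaults are declared, not inferred.

Ground truth stores the *continuous* requested edges (µm), so the true
mean width equals the configured width exactly; rasterization rounds each
edge to the nearest pixel column (band inclusive of both edge columns),
which keeps the identity exact when edges fall on pixel columns (the
wall-attached case) and bounds the error by one pixel otherwise.

What the simulator does not emulate: vignetting beyond a linear ramp,
out-of-focus lumen edges, debris, membrane pores, or partial detachment
where the band is discontinuous along a profile. Passing recovery tests
therefore demonstrate correctness of the measurement logic, not
robustness to every real-world artifact.

## Morphometry

Given an integer label mask (0 = background, one id per cell):

* **Border removal** zeroes every label with a pixel on the outermost
  rows/columns (ids preserved; idempotent).
* **Area** = pixel count × pixel_size². The default 200 µm² filter uses
  strict "smaller than" semantics: a region of exactly 200 µm² is kept.
* **Aspect ratio** = major/minor axis of the moment-matched ellipse
  (ImageJ convention). Bounding-box ratios were rejected because they are
  rotation-dependent. Degenerate regions (minor axis 0) report 1.
* **Feret diameter/angle**: each pixel contributes its four corner
  points; the maximum pairwise distance over the convex hull of those
  corners is the diameter, and the angle of that chord from the image
  horizontal (y up), folded into [0, 180), is the Feret angle. For a
  single pixel the diameter is the pixel diagonal. Note the maximum
  chord of a *rectangle* is its corner diagonal, and the two diagonals
  tie — Feret angles are only sharply defined for shapes whose maximum
  chord is unique (elongated cells qualify; near-squares and discs do
  not). Tie-break: first maximal pair in scan order.
* **Summaries**: group sizes, medians and quartiles (linear-interpolation
  quantiles) per day × location.

The synthetic mask generator places ellipses or rectangles by rejection
sampling with a per-run retry budget, enforcing at least `min_gap_px`
(Chebyshev) background pixels between labels; exhausting the budget
yields a partial mask plus a warning. Defaults (768×768 px at 0.5 µm/px,
60 cells of ~600 ± 150 µm², aspect 2.0 ± 0.5) emulate a confluent
monolayer at roughly 24 % area fraction, where packing succeeds reliably.

## Repeated-measures model

Let y_i be the width series of chip i (group g, observed days O_i). The
model is y_i ~ N(μ_g[O_i], Σ[O_i,O_i]) with a free mean per (day, group)
cell (equivalent to day + group + day×group with days categorical) and a
single unstructured Σ shared across chips and groups. Missingness is
assumed ignorable (MAR); the simulator produces monotone dropout, but the
fitter accepts arbitrary patterns.

Estimation is REML via an EM iteration: given Σ, the cell means are GLS
(grouping chips by observation pattern for speed); the covariance update
averages completed residual outer products, where unobserved days are
imputed from their conditional distribution and, for REML, the
fixed-effect uncertainty term X V X′ is added. On balanced complete data
the fixed point is exactly the pooled within-group sample covariance with
an N − G denominator and cell means equal to sample means — both used as
closed-form test oracles; on unbalanced monotone data the fit matches
`nlme::gls` (corSymm + varIdent, REML) to ≲0.05 µm in means and standard
errors (cross-checked in the test suite).

Numerical choices: convergence when the maximum absolute change of Σ per
iteration falls below 1e-7 relative to its largest entry (≈1e-3 µm² at
the ~1e4 µm² scale of these data — far below statistical precision, since
terminal EM convergence is slow); at most 10 000 iterations, otherwise an
explicit convergence error. Singular covariance blocks raise; no
regularization is applied. Confidence intervals are Wald with normal
quantiles (the common default of the repeated-measures software this
mirrors); with the study's smallest cells (n = 6) the normal-vs-t
difference is partially offset by covariance pooling across 30+ chips,
and empirical coverage on correctly specified simulations stays within
[0.90, 0.99] (checked in the acceptance suite at 200 replicates).

**Divergence day**: the first day whose two group CIs fail to overlap,
with closed intervals (exact touching counts as overlap — conservative).
This is an interval-overlap heuristic, not a formal test; the test suite
characterizes it empirically (recovery when groups separate strongly,
rare false alarms under the null).

## Kruskal–Wallis and Dunn

The global H statistic and chi-square p-value are tie-corrected (via
scipy). Dunn's pairwise z statistics use pooled mid-ranks with the tie
term Σ(t³−t)/(12(N−1)) in the standard error and two-sided normal
p-values, Bonferroni-adjusted by default (unadjusted values are always
reported too, since the multiplicity convention of the original analysis
software is undocumented). Stars follow the 0.05/0.01/0.001 convention.
All-identical data raise a degenerate-data error (the tie-corrected
variance vanishes).

## Cohort simulator

Chips are drawn per group from a multivariate normal with the group's
mean trajectory and the shared Σ, then truncated by a per-day retained
count (chip j observed on day d iff j < schedule[d]) — monotone dropout
matching the declining per-day Ns of the study design (co-culture
68→26, control 12→6 over days 2–10). Default trajectories hold the
control near 1300 µm and remodel the co-culture group from ~1296 µm to
~1023 µm; default Σ has per-day SDs growing 10→100 µm with AR(1)-like
correlation 0.6, reflecting increasing between-chip spread as remodeling
progresses. These defaults define the simulated study conditions used
throughout the tests.

## Known limitations

* The width method measures a projected footprint; it cannot distinguish
  narrowing from vertical remodeling (no 3-D reconstruction).
* The empirical correction factor of the original analysis is unknown;
  the default 1.0 is a declared choice and the parameter is prominent in
  the configuration and outputs.
* Feret angles of near-isotropic shapes are tie-dominated and should not
  be interpreted.
* The divergence-day rule inherits the conservatism of CI-overlap
  comparisons; it under-calls differences relative to a formal contrast.
* Problem sizes in the test suite (image 1200×600 px, cohorts of 80
  chips, 200 Monte-Carlo replicates) were chosen as the package's own
  desk-scale defaults; the generators accept arbitrary sizes.
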