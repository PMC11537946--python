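# Methods

## Scope and model

`octaquant` quantifies how faithfully one arm of en-face OCTA projection
maps (the "translated" TR arm) reproduces a reference arm (GT) in terms of
vascular morphometry, image quality and cohort-level statistics. It does
not model image acquisition or perform any translation itself; the two arms
are inputs (or are synthesized).

## Synthetic vasculature generator

GT maps are produced by a stochastic branching random walk. Each of
`n_seeds` root vessels starts at a uniformly random interior position with a
uniform heading and takes unit-length steps; the heading diffuses by
`Normal(0, tortuosity_amp)` radians per step. With probability
`branch_prob` per step (allowed only after `min_branch_len_px` steps, so
branches have substance) the vessel bifurcates into two children whose
headings split symmetrically by ±π/7 and whose radius is
`caliber_decay` × the parent's. A branch ends at the frame boundary, at a
bifurcation, or at a step cap; children below 0.4 px radius or beyond depth
12 are not spawned, and networks are capped at 4096 branches.

Rasterization paints a disc of the branch radius at each (rounded) step
point with no anti-aliasing, so the binary "truth" mask has exact pixel
counts; the grayscale arm applies a thin Gaussian intensity profile
(σ = 0.6 px) to the mask and scales to 8 bits. The generator returns the
exact centerline polylines and radii (the geometry record), which the test
suite uses as an oracle: skeleton branch counts, arc/chord tortuosity and
Otsu mask overlap (Jaccard ≥ 0.95) are all checked against it.

Defaults (256 px frame, 8 seeds, branch_prob 0.04, tortuosity 0.15 rad,
root caliber 2.2 px, decay 0.8) give dense capillary-like maps with vessel
density ≈ 0.3–0.5, in the range of real macular scans. The `fov_label`
("3mm"/"6mm") is metadata: a 6 mm scan covers twice the width on the same
grid, i.e. half the sampling density; no other physics is attached to it.

The degradation model stands in for translation artifacts: Gaussian blur
(`blur_sigma_px`), random removal of a fraction of small-caliber branches
(`dropout_frac` of branches with radius ≤ 1.5 px, re-rasterized from the
geometry), multiplicative caliber jitter (zero-mean, SD `caliber_jitter`)
plus an optional systematic `caliber_scale` bias, a `contrast_gain`, and
additive Gaussian pixel noise (`noise_sd`, 8-bit units). An all-identity
spec returns the GT pixels bit-for-bit, which anchors the statistical
null. Severity defaults used by the demo cohort and the acceptance script
(blur 0.8 px, dropout 0.15, jitter 0.08, noise 4) are calibration choices
producing a visibly-degraded but recognizable TR arm — moderate SSIM,
near-ideal PCQI ordering — not measurements of any particular translation
model.

What the generator does **not** emulate: real capillary topology (laminar
plexuses, foveal avascular zone), flow-signal texture and speckle,
projection artifacts, motion artifacts, or disease-specific lesion
morphology. Passing tests therefore demonstrate the *estimators and
statistics* are correct and well calibrated on controllable vasculature-like
inputs, not that any clinical claim transfers.

## Morphometry estimators

* **Binarization** — global Otsu on the grayscale map by default;
  fixed-threshold and local-adaptive variants are available and the method +
  threshold are recorded on the mask. Constant images yield an empty mask
  with a warning.
* **Skeleton and branches** — topological thinning to an 8-connected 1-px
  centerline. Junctions are connected clusters of skeleton pixels with ≥ 3
  skeleton neighbours (clustering prevents a thick crossing counting twice);
  branches are walked junction-to-junction or junction-to-endpoint; pure
  cycles are kept as flagged loops. Terminal spurs shorter than 3 px
  (default `prune_len_px`) are thinning artifacts and are dropped before any
  feature computation. Chain-code geodesic lengths weigh orthogonal steps 1
  and diagonal steps √2.
* **BVD** is the exact integer ratio of mask pixels to frame pixels.
* **BVC** divides mask area by the summed chain-code length of retained
  branches. On a 5 × 100 px bar this gives ≈ 5 px within end effects.
* **BVT** measures each branch's along-vessel length on a lightly smoothed
  copy of its pixel path (moving average, window 5, endpoints pinned) and
  divides by the endpoint chord. Raw chain-code length overestimates smooth
  digital curves by up to ~8% depending on orientation; smoothing removes
  that staircase bias so a straight bar scores 1.000 and a rasterized
  quarter-circle scores π/(2√2) ≈ 1.111 within ±0.03, while pinned endpoints
  keep every ratio ≥ 1 by the triangle inequality. Closed loops and
  branches with chord < 1 px are excluded from the mean (counted and
  reported) since their chord would blow the ratio up.
* **VPI** extracts marching-squares iso-contours at level 0.5 on the
  zero-padded mask (holes included), smooths each closed contour with a
  circular window-5 moving average for the same anti-staircase reason, and
  divides total length by mask area. The estimator meets the rectangle
  (2(w+h)/wh) and disc (2/r) limits within 5% and is exactly invariant to
  duplicating a component disjointly.

Degenerate inputs never raise inside a cohort run: empty masks or
zero-length skeletons produce NaN sentinels with warnings, and the report
counts exclusions per feature.

## Quality metrics

SSIM uses the canonical 11-px Gaussian-weighted window (σ 1.5), K1 = 0.01,
K2 = 0.03, population (N-normalized) moments; a uniform-window option exists
so single-window values can be verified by hand. PCQI follows the
three-term multiplicative construction on local patches (default 11-px
patches, stride 4, stabilizer c = 3, dynamic range 255): patch similarity
`(σ_xy + c)/(σ_x σ_y + c)`, contrast distortion `(4/π) atan((σ_xy + c)/(σ_x² + c))`,
mean-luminance change `exp(−|μ_x − μ_y|/L)`. Identical inputs score exactly
1; a pure intensity offset moves only the luminance term and a pure contrast
stretch only the contrast term, which the tests audit per term.

The Fréchet distance between arms is
`‖μ_A − μ_B‖² + Tr(Σ_A + Σ_B − 2(Σ_A Σ_B)^{1/2})` on Gaussian fits to
embedded image sets, covariances regularized by 1e−6·I, matrix square root
via SciPy. The default embedding is a 28-dimensional deterministic
descriptor (intensity moments, 16-bin histogram, gradient-magnitude moments,
8-bin radially averaged log power spectrum): it makes set-level distances
fully offline and reproducible. A pretrained Inception pool3 embedding is
the conventional choice where weights are available; requesting it without
weights raises an error that names the fallback. Absolute distances are
embedding-specific and are only compared within one embedding.

## Statistics

Per (group, arm, FoV, feature): n, mean, sample SD (ddof = 1), NaN
sentinels excluded listwise with counts. The TR-vs-GT comparison reports
both readings of a "two-tailed t-test": unpaired Welch
(unequal variances, Welch–Satterthwaite df) as the headline, and the paired
test, which is the more powerful choice given per-subject pairs; both appear
in the JSON report. The degenerate zero-variance equal-mean case returns
t = 0, p = 1 so an identity degradation yields p = 1 exactly. No
multiple-testing correction is applied; the report records the number of
tests so users can correct externally. Simulation tests check calibration:
across 200 null cohorts (both arms from the same generator spec, independent
seeds, 8 subjects per arm) each feature's empirical type-I rate lies in the
95% binomial interval around 0.05, and a systematic 15% caliber thinning at
n = 30 is detected in BVC in ≥ 4 of 5 replicate cohorts.

## Problem sizes and determinism

Tests run on 96–192 px frames with sparse networks (tens of branches) where
many replicates are needed, and on the full 256-px default where single
images suffice; the demo cohort is 2 groups × 5 subjects at 256 px and the
acceptance script uses 20 subjects. Every stochastic step flows from one
master seed: per-subject seeds are derived by CRC-32 hashing of
`master_seed:subject_id(:arm)`, so unbalanced cohorts reproduce exactly and
adding a group never reshuffles existing subjects. Reruns at a fixed seed
are byte-identical down to the output CSVs.

## Known limitations

* Branch decomposition near dense junction clusters depends on thinning
  artifacts; counts are only guaranteed against geometry within ±1 per
  junction on sparse, non-overlapping networks.
* Feature magnitudes are reported in the literal pixel-based definitions
  above; published tables sometimes use instrument- or vendor-specific
  scalings, so an optional per-feature report scale factor is provided
  (default 1) rather than guessing units.
* BVC uses centerline (skeleton) length as "vascular length"; other length
  conventions exist.
* The Fréchet distance on 28-dimensional descriptors of 10–20 images is a
  high-variance estimate; it is meaningful for ordering degradation
  severities, not as an absolute quality score.
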