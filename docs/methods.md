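# Methods

This note documents the models and conventions implemented in `tacerad`,
the defaults and why they were chosen, and what the synthetic phantom can
and cannot demonstrate.

## Quantization

Texture matrices need discrete gray levels. In-mask intensities are
re-binned into `G` equal-width levels spanning `[in-mask min, in-mask
max]` (default `G = 64`, configurable). This is the most common radiomics
convention and bounds every matrix at `G × G` regardless of the intensity
units. Consequences worth knowing:

* quantization is *range-relative*: adding a constant to, or rescaling, a
  phase volume leaves its quantized levels — and therefore all texture
  features — unchanged;
* a constant VOI (zero range) maps entirely to level 1 rather than
  erroring, so downstream features stay defined (entropy 0, histogram
  energy 1);
* re-quantizing an already-discrete grid whose levels span 1..G is the
  identity.

No fixed-bin-width or HU-calibrated variant is provided; the phantom and
the feature definitions only require relative levels.

## Per-phase features (12 + 24 + 7 = 43)

**First-order (12):** mean, median, minimum, maximum, range, variance,
skewness, kurtosis, energy, entropy, uniformity, mean absolute deviation.
Moments use the population (biased) convention; skewness and excess
kurtosis of a constant sample are defined as 0. Energy, entropy and
uniformity are statistics of the normalized gray-level histogram
(entropies in bits throughout). Note that histogram energy and uniformity
are the same classical quantity Σp²; the registry keeps both names
because the fixed 12-member taxonomy lists both, and the correlation
filter removes the redundancy downstream.

**Texture (24):** computed *per axial slice* at in-plane unit offset and
accumulated over slices before normalization (a 2.5D scheme matching the
four stated angles 0°/45°/90°/135°), then averaged over the four
directions.

* GLCM (9): energy, contrast, correlation, entropy, homogeneity,
  dissimilarity, sum entropy, cluster shade, cluster prominence.
  Symmetric accumulation (each pair counted in both orders), distance
  fixed at 1 voxel, levels enter formulas with their 1-based values. A
  zero-variance matrix has correlation 1 by convention; a direction with
  no valid pair yields the degenerate limits (energy 0, entropy 0, …).
* GLRLM (11): short/long-run emphasis, gray-level and run-length
  non-uniformity, run percentage, and the low/high gray × short/long run
  emphasis quartet. Runs are maximal same-level segments of each scan
  line, broken by the mask.
* GLZSM (4): high/low-intensity emphasis and their large-area variants.
  Zones are maximal 3D 26-connected components of equal level; the matrix
  is direction-free and is replicated across the four directions so the
  directional accounting (24 × 4 = 96 evaluations per phase) and the
  averaging no-op stay exact.

The 9 + 11 + 4 split is this package's completion of the 24-feature
taxonomy: the smallest standard sets that contain the canonically named
members (sum entropy, cluster shade, run-length non-uniformity, the
high-intensity zone emphases) and sum to 24.

**Morphology (7):** volume (voxel count × voxel volume), surface area
(exposed voxel faces × face area), density (mean in-mask intensity),
maximum diameter (largest pairwise distance between surface-voxel
centers, in mm; computed on convex-hull vertices when the surface is
large), sphericity π^{1/3}(6V)^{2/3}/A, compactness V/(√π·A^{3/2}), and
surface-to-volume ratio. Compactness is deliberately *not* sphericity³ so
the two shape features are not deterministic transforms of each other.
Face-counted surface area overestimates smooth surfaces (a voxelized
sphere's sphericity plateaus around 0.67 rather than 1); features are
compared within a cohort processed identically, where this bias cancels.

## Multiphase assembly (115 static + 108 delta)

The static vector counts first-order and morphology once and texture per
phase: 12 + 24×4 + 7 = 115. Tumor geometry is phase-invariant, so
morphology is taken from the reference (arterial-early) phase; the
first-order block of the same reference phase anchors the static intensity
description. This is the only accounting under which the fixed feature
totals (115 static, 108 delta, 108 dynamic static columns, 223 overall)
are mutually consistent, and it is adopted as the rule.

Delta features apply x̃ = (x_l − x_r)/x_r to all 36 dynamic features
(first-order + texture, *per phase*) over the 3 adjacent transitions in
acquisition order: 36 × 3 = 108. A reference value within 1e-12 of zero
returns 0 with a logged warning instead of ±∞ — zero denominators occur
only for degenerate inputs, and keeping the design matrix finite is worth
the small bias. Deltas are antisymmetric under phase swap in the sense
x̃_{l−r} = −x̃_{r−l}/(1 + x̃_{r−l}).

Five nested feature sets are exposed: S1 morphology (7), S2 static
dynamic (108), S3 delta (108), S4 all static (115), S5 everything (223).

## Selection cascade

Fixed order, each stage only removes columns; the full decision trail is
serialized.

1. **Correlation filter** (default |r| ≥ 0.9): greedy pass in column
   order; the earlier column of an over-correlated pair is kept. The
   threshold is a conventional redundancy cut-off; greedy keep-first makes
   the result deterministic. Zero-variance columns (undefined r) are kept
   and flagged.
2. **Welch t-screen** (default α = 0.05): unequal-variance two-sample t
   per column; keep p < α. No multiple-testing correction — the screen is
   a pre-filter before the multivariate stage, not an inference; this is
   scientifically debatable but matches common radiomics practice.
3. **LASSO logistic** : λ grid log-spaced over three decades down from
   λ_max (the smallest penalty that zeroes all coefficients), deviance
   estimated by stratified CV with standardization computed inside each
   training fold, λ chosen by the 1-SE rule (sparsest model within one
   standard error of the minimum). Selected = nonzero coefficients of the
   full-data refit at that λ. The inner solver is liblinear coordinate
   descent with a fixed seed.

If the cascade eliminates every column (possible on permuted labels), the
pipeline falls back to the unselected table rather than failing, so
permutation controls remain runnable.

## SVM

The classifier is the soft-margin kernel machine: primal
½‖N‖² + CΣθ_r subject to y_r(Nᵀφ(x_r)+a) ≥ 1−θ_r, solved in the dual
(box constraints 0 ≤ β_r ≤ C, equality Σβ_r y_r = 0) by sequential
minimal optimization with max-violating-pair working-set selection. The
stopping rule is the violation gap m(β) − M(β) ≤ tol (default 1e-3 for
pipeline use; tests tighten it). The bias averages y_r − Σβ_l y_l K(r,l)
over free support vectors, falling back to the gap midpoint when none are
free. Degenerate pair curvature is floored at 1e-12. The solver is
deterministic; iteration is capped at max(20000, 200·m) with a
convergence flag. Kernels: linear, polynomial (u·v + c₀)^d, RBF
exp(−γ‖u−v‖²) with γ defaulting to 1/(n_features · var(X)). A decision
value of exactly 0 predicts +1. Class weighting is not implemented (the
target design is balanced); C is the only capacity knob, default 1.0
after per-fold standardization.

## Evaluation

Positive class = response (ease). ROC by threshold sweep over unique
scores (ties step diagonally), AUC by trapezoid — identical to the
tie-halved concordant-pair probability. Operating point by Youden's J
with ties resolved to the lower threshold. AUC bands: excellent (> 0.9),
good (0.7–0.9), average (< 0.7). Splits: stratified hold-out, stratified
k-fold (default 5), or bootstrap with out-of-bag testing (expected OOB
fraction (1−1/n)^n ≈ 0.368). The default evaluation refits the entire
selection cascade inside each training split; `paper_mode` selects once
on all data first, reproducing the leakage-prone design often seen in the
literature — the two modes exist precisely so their gap can be measured.

## Phantom generator

Each case: an ellipsoidal mask (radii uniform in 8–15 mm per axis,
jittered center) in a 48³ grid at 1 mm spacing; each phase volume is
μ_p + σ·field, where field is unit-variance Gaussian-filtered white
noise. Class parameters:

| parameter | responders (CR/PR) | non-responders (SD/PD) |
|---|---|---|
| μ profile (4 phases) | 100, 165, 130, 108 | 100, 118, 112, 106 |
| texture σ | 12 | 24 |
| correlation length (voxels) | 1.0 | 2.2 |

plus per-case multiplicative jitter (5% on the profile, 10% on σ). The
profiles emulate the classic hypervascular wash-in/wash-out of viable HCC
versus a hypovascular non-responding lesion; the σ and correlation-length
multipliers plant heterogeneity and zone-structure differences. Signal is
planted through these generative dials, not by targeting specific feature
values, so recovery genuinely exercises the extraction code. Effect sizes
are deliberately strong — the cohort is a correctness instrument, not a
difficulty benchmark.

What the phantom does **not** emulate: liver background anatomy, partial
volume effects at the tumor rim, CT noise physics (beam hardening,
iodized-oil artifacts), inter-phase misregistration, segmentation
variability, label noise, or realistic tumor shapes. Passing the phantom
tests therefore demonstrates that the pipeline computes what it claims
and can recover planted multiphase signal; it says nothing about effect
sizes, attainable AUC, or feature stability on real cohorts.

A separate tabular simulator (class-shifted normal columns + noise +
optional duplicated columns) exercises the selection and SVM stages
without image extraction.

## Numerical conventions and degenerate inputs

* log base 2 for every entropy; 0·log0 = 0.
* constant sample: skewness = kurtosis = 0; zero-variance GLCM
  correlation = 1; empty texture direction → degenerate-limit features.
* empty masks, single-class labels, non-finite inputs, unknown RECIST
  codes and mismatched shapes raise typed errors naming the offender.
* all stochastic stages (splits, LASSO CV, phantom) are driven by
  explicit seeds; identical config + seed reproduces every artifact
  bit-for-bit.

## Problem sizes

Default study conditions: 24 + 24 cases, 48³ voxels, G = 64, 5-fold
nested cross-validation; the full run (generation, extraction of
43 × 4 features per case, selection and SVM per fold, permutation
control, LASSO recovery at 5 + 200 columns, 1000-column t-screen
calibration) completes in well under a minute on one CPU. Unit tests use
smaller grids (24³–32³, G = 16–32) chosen to keep the suite fast while
still exercising 3D geometry.

## Known limitations

* 2.5D texture only; the 13-direction 3D variants are out of scope.
* Surface-area bias of face counting (above).
* The LASSO stage's λ path uses a fixed three-decade grid; extremely
  ill-conditioned tables may need a custom grid.
* `paper_mode` exists for comparison but is not the recommended analysis.
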