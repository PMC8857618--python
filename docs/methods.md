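# Methods

This note documents the models, conventions and numerical choices behind
`meaningmaps`, in the order the pipeline runs.

## Geometry and patch grids

All pixel coordinates are 0-based with the origin at the top-left; a
pixel `(col, row)` occupies `[col, col+1) × [row, row+1)` with its centre
at `(col+0.5, row+0.5)`. Region boxes are half-open, so boundary points
at `x0`/`y0` are inside and at `x1`/`y1` outside; fixations exactly on a
region's leading edge therefore count as hits. A pixel belongs to a
circular patch iff its centre lies within `diameter/2` of the patch
centre — an orientation-free rule that makes every area computation an
exact integer count.

Grid construction takes a target density in patches/deg² and searches all
`(n_cols, n_rows)` layouts with `1 ≤ n ≤ 64`. A layout is admissible when
its horizontal/vertical centre spacing ratio (in pixels) lies in
`[0.8, 1.25]` — the near-equidistance constraint; among admissible
layouts the one minimising the absolute density error wins, with ties
broken by the spacing ratio closest to 1, then by more columns. Centres
are cell-centred: inset by half a spacing from each edge, so patches
partially overlap and jointly cover the image. On the default geometry
(688 × 524 px, 19.7° × 15°) this yields 9 × 7 = 63 coarse and
15 × 11 = 165 fine patches, densities 0.213 and 0.558 p/deg².

The patch diameters are taken as authoritative in pixels (187 coarse, 79
fine at full scale). Converting the nominal 5.26° via the horizontal
pixels-per-degree of the default geometry gives ≈ 184 px, a ~2%
discrepancy inherent to mixing rounded degree and pixel specifications;
since every analysis operates in pixel space, the pixel value governs.

Extracted patches are square crops with pixels outside the inscribed
circle (and off-image parts of clipped footprints) set to a configurable
background fill, mid-grey by default.

## Meaning-map assembly

Per grid level, each patch's ratings (nominally 3) are averaged; every
pixel covered by at least one footprint receives the mean of the covering
patches' averages. Pixels no patch covers — possible at image corners —
are filled with the nearest covered pixel's value and smoothed with a
Gaussian of σ = 1% of the image width; covered pixels keep their exact
covering means, so the assembly is bit-reproducible and directly
testable against a per-pixel enumeration. The fine and coarse maps are
averaged pixel-wise without per-level rescaling (both live on the same
1–6 rating scale, so rescaling would only inject the levels' incidental
min/max into the result; a user who wants a different convention can
rescale before combining).

**Centre bias.** The packaged weight field is a parametric surrogate:
`w = cos²(π/2 · min(ρ, 1))` with `ρ` the elliptical radius normalised so
`ρ = 1` at 0.7 of the image half-extent per axis. It is 1 at the centre,
monotonically non-increasing along every ray, 0 at the far corners, and
peak-normalised after sampling. Empirical weight fields (e.g. exported
from a saliency toolbox) can be loaded from plain-text matrices and are
bilinearly resampled to the image; loading rejects negative weights and
rescales by the maximum. The bias is applied as a pixel-wise product,
once — a second application raises an error.

**Histogram matching.** The map is matched to a reference distribution
(the smoothed fixation map of the same image) by exact sorting: the i-th
smallest map pixel receives the i-th smallest reference value, with ties
in the map resolved stably by row-major pixel index. The output's sorted
values equal the reference's exactly and the operation is idempotent.
This is the ordering convention of discrete histogram specification
without binning; a bin-based CDF variant would differ only within
quantisation bins. Matching runs *after* the centre bias, so the bias
shapes the ranks but the final value scale is entirely the reference's.

## Smoothed fixation maps

Fixations are pooled across observers (the analyses are group-level),
binned at the containing pixel, convolved with an isotropic Gaussian and
divided by the maximum. The Gaussian is specified by the frequency at
which its amplitude response reaches −6 dB: from
`G(f) = exp(−2π²σ²f²)`, `σ_px = sqrt(ln 10^{0.3}/2)/(π f_c) · W` for a
cutoff of `f_c` cycles per image width `W`. The default cutoff is 8
cycles/image (σ ≈ 2.3% of the image width, ≈ 16 px at full scale), a
mid-range choice for free-viewing fixation maps; it is a parameter of
every smoothing call and recorded in output metadata by the CLI. The
kernel is truncated at 6.5σ (relative truncation error < 1e−9) and the
image boundary is zero-padded, which preserves the reflection symmetries
the tests rely on.

## Survey design and rater screening

Scenes are split into two seeded halves and crossed with condition to
form two patch subsets: subset A holds the consistent patches of one
half and the inconsistent patches of the other; subset B the complement.
Rating sets are seeded shuffles of one subset chunked to the set size
(304 at full scale), so no rater ever sees a scene in both conditions
while every rater sees both conditions.

Krippendorff's α is computed from the definitional coincidence matrix
(interval metric by default, ordinal available). A rater's `R_α` is the
mean of their pairwise α values with all co-raters of the same set;
raters are retained iff `R_α` exceeds the threshold (default 0.40).
Pairs are formed over all co-raters, including ones later excluded —
screening is a single pass, not iterative. Raters with no co-raters
cannot be screened and are excluded with `R_α = NaN`.

The follow-up (patch-role) design excludes coarse locations overlapping
the critical region, averages each remaining location's ratings across
conditions, sorts ascending and takes the 2 lowest (L), the highest (H)
and the 3 closest to the median (M); median-distance ties break toward
the lower rating, then lexicographic patch id. L/M/H patches pair with
both context conditions; the Con/Incon patches (containing the
manipulated object) pair only with their own condition. With 36 scenes
this yields 14 pairs/scene = 504 pairs, split into two blinded subsets
of 252.

## Statistics

* **Mixed 2 × 2 ANOVA** — classical sums-of-squares decomposition; the
  between effect is tested against subjects-within-groups, the within
  effect and interaction against the within-by-subject residual. ω² uses
  the classical estimator `(SS_eff − df_eff·MS_err)/(SS_tot + MS_err)`
  with each effect's own error term; statistical packages differ in the
  mixed-design ω² variant they print, so cross-package parity of ω² is
  approximate (F, df and p are exact and are cross-checked against an
  independent implementation in the tests).
* **2 × 3 repeated-measures ANOVA** — full within decomposition;
  Greenhouse–Geisser ε per effect from orthonormal contrast scores,
  `ε = tr(S)²/(m·tr(S²))`, clipped to `[1/m, 1]`, applied to the dfs of
  effects involving the 3-level factor.
* **Wilcoxon signed-rank** — zeros dropped, midranks for ties, exact
  enumeration for n ≤ 25, otherwise normal approximation with continuity
  correction. Bonferroni factors are always explicit arguments and cap
  the p value at 1.
* **Page's test** — within-row midranks, `L = Σ_j j·R_j`. Exact p by
  convolving the per-row distribution of `Σ j·r_j` over all `k!` rank
  permutations for `n ≤ 8, k ≤ 4` and tie-free rows; otherwise the
  normal approximation `z = (L − nk(k+1)²/4)/sqrt(n·(k³−k)²/(144(k−1)))`
  without continuity correction (ties shrink the true variance slightly,
  making the approximation mildly conservative near the maximum).
* **Cook-screened correlation** — OLS of y on x, exclusion above 3× the
  mean Cook's distance, Pearson r with Fisher-z CI on the retained
  points, the unscreened r reported alongside. A (near-)perfect fit
  leaves only round-off in the residuals, so screening is skipped when
  the residual sum of squares is ≤ 1e−12 of the total.
* **Power** — the minimal detectable `D_z` of a two-tailed paired t test
  is root-found (Brent) on the noncentral-t power function, which is
  strictly increasing in `D_z`.

## Synthetic data

The generator reproduces the *statistical structure* the analyses
assume, not photographs. Scenes are band-limited noise backgrounds with
parameterised disc objects; the consistent/inconsistent renders differ
exactly on the critical region (different object shape/shading on a
slightly re-lit region background, emulating that a re-photographed
region never matches pixel-for-pixel). Each scene carries a smooth
ground-truth meaning field in [1, 6] with bumps at object locations,
including one inside the critical region.

* **Gaze model** — each fixation comes from a central Gaussian
  (σ = 3.3° × 2.5°, probability 0.4) or from the meaning-field-
  proportional pixel distribution; in the inconsistent condition the
  critical region's field weight is multiplied by `1 + b`. Defaults
  mirror the emulated study: 20 observers × 25 fixations (≈ 3.5
  fixations/s over a 7-s trial), boost b = 1.5.
* **Rater model** — latent rating = footprint mean of the meaning field
  − `s·δ` for patches showing the inconsistent object (strategy weight
  `s ~ U[0,1]` per rater, penalty δ = 0.3 by default) + Gaussian noise
  (σ = 0.7 Likert units), rounded and clamped to 1..6. The uniform
  strategy weight produces the rater heterogeneity the screening and
  correlation analyses need; δ > 0 encodes that inconsistent objects are
  rated slightly *less* meaningful.

What passing tests show — and what they do not: the generator has no
photographic content, no saccade dynamics, no fixation durations, no
serial dependence between a rater's judgements, and its meaning field is
smooth by construction. Results on synthetic data therefore validate the
*pipeline arithmetic and its statistical behaviour* (calibration, power,
parameter recovery, the gaze-up/ratings-not-up dissociation), not any
empirical claim about real scenes or raters.

## Problem sizes

The default simulation scale mirrors the emulated study (36 scenes, 20
observers, 3 raters/patch, 122 follow-up raters). Pipeline-level tests
and the acceptance script run the full 36 scenes on a reduced raster
(scale 0.2: 138 × 105 px for the same 19.7° × 15° field of view, patch
diameters scaled accordingly) — patch counts and densities are
unchanged because the field of view is, and the scene count (the unit of
analysis) is kept at 36 so the statistics run at their design n.
Monte-Carlo calibration uses 2,000 null replicates; detection and
recovery use 40 and 200 simulation replicates with fixed seed schedules.

## Known limitations

* The centre-bias surrogate is parametric; analyses that depend on the
  exact shape of an empirical bias field should load it explicitly.
* ω² printed by other software for mixed designs may differ from the
  classical estimator used here.
* Page's exact p is limited to small tie-free designs; larger or tied
  designs use the normal approximation.
* The grid search assumes near-square pixels; exotic aspect ratios can
  leave no admissible layout, which raises an error rather than
  silently relaxing the equidistance constraint.
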