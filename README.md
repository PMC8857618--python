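# meaningmaps

Tools for building **contextualized meaning maps** from crowd-sourced
patch ratings and comparing them against human fixation behaviour in the
**object-scene consistency** paradigm — scenes photographed twice,
identical except for one object that is either semantically consistent
(a hair brush on a bathroom sink) or inconsistent (a shoe on the sink).

The package is aimed at eye-movement and scene-perception researchers who
want to (re)run this kind of analysis, or to probe the meaning-map method
itself with simulated ground truth: every stage of the pipeline is backed
by a synthetic-data generator (scenes, observers, raters), so the whole
analysis can be exercised and validated without any external data.

## What it computes

**Meaning maps.** An image is tiled with circular, partially overlapping
patches on two grids — coarse (diameter 5.26°, density ≈ 0.21 patches/deg²)
and fine (2.26°, ≈ 0.56 p/deg²), with patch centres equidistant
horizontally and vertically. Raters judge each patch's *meaningfulness*
on a 6-point Likert scale while seeing the full scene alongside (the
"contextualized" variant). Per level, patch means are averaged into each
pixel they cover and interpolated; the two level maps are averaged,
multiplied by a centre-bias weight field `w(x, y) ∈ [0, 1]`, and finally
histogram-matched to the smoothed fixation map of the same image so both
distributions share one value scale.

**Smoothed fixation maps.** Fixations pooled over observers are convolved
with an isotropic Gaussian whose amplitude response is −6 dB at a cutoff
frequency `f_c` (cycles/image width), i.e.
`σ = sqrt(ln 10^{0.3} / 2) / (π f_c)` in image-width units, then
max-normalised to [0, 1].

**Comparison statistics.** For a critical region *R* (the union bounding
box of the two objects), the *mass density* of a map `M` is
`Σ_{(x,y)∈R} M(x,y) / |R|`. Mass densities are compared with a mixed
2 × 2 ANOVA (scene as "subject"; condition within, distribution source
between; ω² effect sizes) and paired Wilcoxon post-hocs (Bonferroni ×2).
The raw-rating analyses use overlap-percentage thresholds (34th/67th
percentiles of above-zero overlaps), paired and Welch t tests, Page's
trend test (`L = Σ_j j·R_j`, max `14n` for `k = 3`), Krippendorff's α for
rater screening (mean pairwise α per rater, exclusion below 0.40),
Cook's-distance-screened correlation, and the minimal detectable Cohen's
`D_z` of a paired t test at given power.

## Worked example

Build the coarse grid for a 688 × 524 px image spanning 19.7° × 15°:

```bash
$ meaningmaps grid --width-px 688 --height-px 524 --width-deg 19.7 \
    --height-deg 15 --diameter-px 187 --density 0.21 --out /dev/null
9 x 7 = 63 patches, achieved density 0.2132 p/deg^2
```

The search over near-equidistant layouts lands on 9 × 7 = 63 coarse
patches (165 for the fine grid), the closest achievable densities to the
targets.

Run the simulated study end to end — synthetic scene pairs, 20 observers
× 25 fixations with an inconsistency-driven gaze boost (b = 1.5), 3
raters per patch with a mild inconsistency rating penalty (δ = 0.3) —
and compare region mass between conditions:

```bash
$ meaningmaps dissociation --scenes 12 --scale 0.25 --seed 0
smoothed_fixations: mean incon-con difference +0.1380, Wilcoxon p = 0.006836
meaning_map: mean incon-con difference -0.0076, Wilcoxon p = 1
```

Observers fixate the critical region more when it holds an inconsistent
object (+0.138 mass density, significant), while the meaning maps built
from the very same ground truth assign it no extra meaning (−0.008, not
significant) — the qualitative dissociation the pipeline is designed to
measure, here reproduced from known generating parameters.

`meaningmaps simulate` writes synthetic images (PNG), fixation tables
(CSV), critical regions (JSON) and a patch manifest to disk;
`meaningmaps analyze` and `meaningmaps screen-raters` run the gaze and
rater-screening analyses on such files.

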