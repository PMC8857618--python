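"""End-to-end simulated study: scenes -> gaze + ratings -> maps -> statistics.

Glues the synthetic generators to the analysis pipeline so the full
design can be exercised at any scale: build the coarse/fine grids, render
scene pairs, sample observers' fixations and raters' patch ratings,
assemble contextualized meaning maps (centre bias + histogram matching
against the smoothed fixations), and compute the mass-in-region
comparison between the two distribution sources.

The study-scale constants (grid diameters/densities and the rating-set
size) follow the emulated design: 187 px / 0.21 p/deg² coarse and
79 px / 0.56 p/deg² fine grids on a 688 x 524 px (19.7 x 15 deg) display,
rating sets of 304 patches with 3 raters each.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import stats as mstats
from .gaze import DEFAULT_CUTOFF, mass_in_region, smooth_fixations
from .geometry import (
    Condition,
    GridLevel,
    PatchGrid,
    ScreenGeometry,
    build_grid,
    grid_patches,
)
from .mapgen import build_meaning_map, make_center_bias
from .survey import partition_patches
from .synth import (
    DEFAULT_GEOMETRY,
    GazeModel,
    RaterModel,
    SceneSpec,
    generate_fixations,
    generate_ratings,
    make_scene_specs,
)

__all__ = [
    "StudyDesign",
    "COARSE_DIAMETER_PX",
    "FINE_DIAMETER_PX",
    "COARSE_DENSITY",
    "FINE_DENSITY",
    "SET_SIZE",
    "RATERS_PER_SET",
    "study_grids",
    "study_patches",
    "auto_set_size",
    "simulate_mass_table",
    "dissociation_tests",
]

COARSE_DIAMETER_PX = 187
FINE_DIAMETER_PX = 79
COARSE_DENSITY = 0.21
FINE_DENSITY = 0.56
SET_SIZE = 304
RATERS_PER_SET = 3


@dataclass(frozen=True)
class StudyDesign:
    geometry: ScreenGeometry
    coarse: PatchGrid
    fine: PatchGrid


def study_grids(geometry: ScreenGeometry = DEFAULT_GEOMETRY, scale: float = 1.0) -> StudyDesign:
    """Coarse and fine study grids, optionally at reduced pixel scale.

    ``scale`` shrinks the pixel raster while keeping the field of view in
    degrees (so densities, and with them patch counts, are unchanged);
    patch diameters scale with the raster.
    """
    g = geometry if scale == 1.0 else geometry.scaled(scale)
    coarse = build_grid(
        g, COARSE_DENSITY, max(1, round(COARSE_DIAMETER_PX * scale)), GridLevel.COARSE
    )
    fine = build_grid(
        g, FINE_DENSITY, max(1, round(FINE_DIAMETER_PX * scale)), GridLevel.FINE
    )
    return StudyDesign(geometry=g, coarse=coarse, fine=fine)


def study_patches(design: StudyDesign, specs: list[SceneSpec]) -> list:
    """All patches of all scene/condition images on both grids."""
    patches = []
    for spec in specs:
        for cond in (Condition.CONSISTENT, Condition.INCONSISTENT):
            for grid in (design.coarse, design.fine):
                patches.extend(grid_patches(grid, design.geometry, spec.scene_id, cond))
    return patches


def auto_set_size(n_subset: int, target: int = SET_SIZE) -> int:
    """Divisor of ``n_subset`` closest to ``target`` (rating-set size)."""
    divisors = [d for d in range(1, n_subset + 1) if n_subset % d == 0]
    return min(divisors, key=lambda d: (abs(d - target), -d))


def simulate_mass_table(
    n_scenes: int = 36,
    scale: float = 1.0,
    seed: int = 0,
    gaze: GazeModel | None = None,
    rater: RaterModel | None = None,
    with_maps: bool = True,
    cutoff: float = DEFAULT_CUTOFF,
) -> pd.DataFrame:
    """Simulate the study and return per-scene mass-in-region densities.

    One row per scene x condition x distribution source, with the
    distribution mass falling inside the critical region divided by the
    region area — the region-level comparison statistic.  Meaning maps
    are histogram-matched to the smoothed fixations of the same image
    before the mass is taken, so the two sources share a value scale.
    """
    design = study_grids(scale=scale)
    g = design.geometry
    specs = make_scene_specs(n_scenes, geometry=g, seed=seed)
    gaze = gaze or GazeModel(seed=seed + 1)
    rater = rater or RaterModel(seed=seed + 2)

    ratings = None
    if with_maps:
        patches = study_patches(design, specs)
        n_subset = len(patches) // 2
        sets = partition_patches(patches, auto_set_size(n_subset), seed=seed + 3)
        fields = {s.scene_id: s.meaning_field for s in specs}
        regions = {s.scene_id: s.critical_region for s in specs}
        ratings = generate_ratings(
            patches, fields, regions, rater, sets, raters_per_set=RATERS_PER_SET
        )
        by_image: dict[tuple[str, Condition], dict[GridLevel, list]] = {}
        for p in patches:
            by_image.setdefault((p.scene_id, p.condition), {}).setdefault(
                p.level, []
            ).append(p)
        cbm = make_center_bias(g)

    rows = []
    for i, spec in enumerate(specs):
        region = spec.critical_region
        for cond in (Condition.CONSISTENT, Condition.INCONSISTENT):
            obs_model = GazeModel(
                center_bias_sd=gaze.center_bias_sd,
                center_weight=gaze.center_weight,
                region_boost=gaze.region_boost,
                n_observers=gaze.n_observers,
                n_fixations=gaze.n_fixations,
                seed=gaze.seed + 1000 * i + (0 if cond == Condition.CONSISTENT else 1),
            )
            seqs = generate_fixations(spec, cond, obs_model)
            fixmap = smooth_fixations(seqs, g, cutoff)
            rows.append(
                {
                    "scene_id": spec.scene_id,
                    "condition": cond.value,
                    "source": "smoothed_fixations",
                    "mass_density": mass_in_region(fixmap.values, region),
                }
            )
            if with_maps:
                groups = by_image[(spec.scene_id, cond)]
                mmap = build_meaning_map(
                    fine_patches=groups[GridLevel.FINE],
                    coarse_patches=groups[GridLevel.COARSE],
                    ratings=ratings,
                    geometry=g,
                    reference=fixmap.values,
                    center_bias=cbm,
                    image_id=f"{spec.scene_id}_{cond.value}",
                )
                rows.append(
                    {
                        "scene_id": spec.scene_id,
                        "condition": cond.value,
                        "source": "meaning_map",
                        "mass_density": mass_in_region(mmap.values, region),
                    }
                )
    return pd.DataFrame(rows)


def dissociation_tests(mass_table: pd.DataFrame) -> dict:
    """The region-mass comparison: mixed ANOVA plus per-source Wilcoxons.

    Scenes act as "subjects"; condition is the within factor and the
    distribution source the between factor.  Post-hoc paired Wilcoxon
    tests (Bonferroni x2) contrast inconsistent vs consistent mass per
    source.  Returns the ANOVA and, per source, the test result and the
    mean inconsistent-minus-consistent difference.
    """
    out: dict = {}
    sources = sorted(mass_table["source"].unique())
    anova_in = mass_table.rename(
        columns={"scene_id": "subject", "source": "between", "condition": "within",
                 "mass_density": "value"}
    )
    if len(sources) == 2:
        out["anova"] = mstats.mixed_anova_2x2(anova_in)
    for source in sources:
        sub = mass_table[mass_table["source"] == source]
        wide = sub.pivot(index="scene_id", columns="condition", values="mass_density")
        incon = wide[Condition.INCONSISTENT.value].to_numpy()
        con = wide[Condition.CONSISTENT.value].to_numpy()
        out[source] = {
            "wilcoxon": mstats.paired_wilcoxon(incon, con, n_comparisons=2),
            "mean_difference": float(np.mean(incon - con)),
        }
    return out
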