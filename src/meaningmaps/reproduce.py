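"""Re-running the analyses on the original study data.

The eye-movement records, patch ratings, and scene photographs of the
study this pipeline models are distributed separately (Zenodo records
3490434 and 5999046 and the SCEGRAM database) and are not bundled here.
Users who fetch them can convert the records into the package's standard
formats and point :func:`reproduce` at the directory:

``<data_dir>/fixations.csv``
    columns ``observer_id, image_id, index, x_px, y_px``; ``image_id``
    must be ``<scene>_consistent`` / ``<scene>_inconsistent``.
``<data_dir>/ratings.csv``
    columns ``rater_id, patch_id, value, set_id``.
``<data_dir>/patches.csv``
    the patch manifest (``patch_id, scene_id, condition, level, cx, cy,
    diameter_px, clipped``).
``<data_dir>/regions.json``
    critical-region boxes per scene.

:func:`reproduce` then rebuilds the meaning maps, smooths the fixations,
and recomputes the per-image map/gaze correlations, the region-mass
table with its mixed ANOVA and post-hoc Wilcoxons, and the raw-rating
region analysis.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from . import io as mio
from .gaze import (
    DEFAULT_CUTOFF,
    map_correlation,
    mass_in_region,
    patch_rating_region_analysis,
    smooth_fixations,
)
from .geometry import Condition, GridLevel, ScreenGeometry
from .mapgen import build_meaning_map, make_center_bias
from .study import dissociation_tests
from .synth import DEFAULT_GEOMETRY

__all__ = ["REQUIRED_FILES", "reproduce"]

REQUIRED_FILES = ("fixations.csv", "ratings.csv", "patches.csv", "regions.json")


def reproduce(
    data_dir: str | Path,
    geometry: ScreenGeometry = DEFAULT_GEOMETRY,
    cutoff: float = DEFAULT_CUTOFF,
) -> dict:
    """Run the full analysis suite on a directory of converted study data.

    Returns a dict with the per-image correlation table, the region-mass
    table and its tests, and the raw-rating region summary.  Raises
    ``FileNotFoundError`` naming every missing input file.
    """
    data_dir = Path(data_dir)
    missing = [f for f in REQUIRED_FILES if not (data_dir / f).exists()]
    if missing:
        raise FileNotFoundError(
            f"{data_dir} is missing {missing}; download the study records "
            "(eye movements: zenodo.org/record/3490434, ratings: "
            "zenodo.org/record/5999046, images: scenegrammarlab.com/research/"
            "scegram-database) and convert them to the documented CSV/JSON "
            "layout first"
        )
    seqs = mio.read_fixations_csv(data_dir / "fixations.csv")
    ratings = pd.read_csv(data_dir / "ratings.csv")
    patches = mio.read_patch_manifest(data_dir / "patches.csv")
    regions = mio.read_regions_json(data_dir / "regions.json")

    by_image: dict[str, list] = {}
    for s in seqs:
        by_image.setdefault(s.image_id, []).append(s)
    patch_groups: dict[str, dict[GridLevel, list]] = {}
    for p in patches:
        image_id = f"{p.scene_id}_{Condition(p.condition).value}"
        patch_groups.setdefault(image_id, {}).setdefault(p.level, []).append(p)

    cbm = make_center_bias(geometry)
    corr_rows, mass_rows = [], []
    for image_id in sorted(by_image):
        scene_id, cond = image_id.rsplit("_", 1)
        fixmap = smooth_fixations(by_image[image_id], geometry, cutoff)
        groups = patch_groups[image_id]
        mmap = build_meaning_map(
            fine_patches=groups[GridLevel.FINE],
            coarse_patches=groups[GridLevel.COARSE],
            ratings=ratings,
            geometry=geometry,
            reference=fixmap.values,
            center_bias=cbm,
            image_id=image_id,
        )
        r, r2 = map_correlation(mmap.values, fixmap)
        corr_rows.append(
            {"image_id": image_id, "condition": cond, "r": r, "r2": r2}
        )
        region = regions[scene_id]
        for source, values in (
            ("smoothed_fixations", fixmap.values),
            ("meaning_map", mmap.values),
        ):
            mass_rows.append(
                {"scene_id": scene_id, "condition": cond, "source": source,
                 "mass_density": mass_in_region(values, region)}
            )
    mass_table = pd.DataFrame(mass_rows)
    rating_summary, rating_dropped = patch_rating_region_analysis(
        ratings, patches, regions
    )
    return {
        "correlations": pd.DataFrame(corr_rows),
        "mass_table": mass_table,
        "mass_tests": dissociation_tests(mass_table),
        "rating_region_summary": rating_summary,
        "rating_region_dropped": rating_dropped,
    }
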