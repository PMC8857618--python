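"""Synthetic scenes, gaze, and raters with the structure the analyses assume.

The generator emulates the object-scene consistency paradigm: pairs of
images identical except inside a *critical region* (where a consistent or
an inconsistent object appears), free-viewing observers whose fixations
mix a central-bias component with a meaning-driven component — the
critical region attracting extra gaze in the inconsistent condition — and
Likert raters whose latent rating tracks the local meaning field, with a
per-rater penalty for patches showing the inconsistent object.

Everything is deterministic under a fixed seed, and every scale parameter
(scene count, observers, raters, image size) is configurable so the full
pipeline can run at reduced size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .gaze import FixationSequence
from .geometry import (
    Condition,
    Patch,
    RegionBox,
    ScreenGeometry,
    circle_pixel_mask,
    overlap_percentage,
)
from .survey import Exp2Design, RaterSet

__all__ = [
    "DEFAULT_GEOMETRY",
    "SceneSpec",
    "ScenePair",
    "GazeModel",
    "RaterModel",
    "make_scene_specs",
    "generate_scene_pair",
    "generate_fixations",
    "footprint_mean",
    "generate_ratings",
    "generate_exp2_ratings",
]

#: study screen geometry: 688 x 524 px spanning 19.7 x 15 degrees
DEFAULT_GEOMETRY = ScreenGeometry(688, 524, 19.7, 15.0)


@dataclass(frozen=True)
class SceneSpec:
    """Ground-truth description of one synthetic scene pair."""

    scene_id: str
    geometry: ScreenGeometry
    seed: int
    objects: tuple[tuple[tuple[float, float], float, float], ...]  # (center, size, intensity)
    critical_region: RegionBox
    meaning_field: np.ndarray  # (H, W) in [1, 6]


@dataclass(frozen=True)
class ScenePair:
    spec: SceneSpec
    image_consistent: np.ndarray
    image_inconsistent: np.ndarray

    @property
    def region(self) -> RegionBox:
        return self.spec.critical_region


@dataclass(frozen=True)
class GazeModel:
    """Free-viewing gaze generator parameters.

    ``center_bias_sd`` is the sd of the central Gaussian component in
    degrees; ``center_weight`` the probability a fixation comes from it.
    ``region_boost`` multiplies the critical region's sampling weight by
    ``1 + b`` in the inconsistent condition only.
    """

    center_bias_sd: tuple[float, float] = (3.3, 2.5)
    center_weight: float = 0.4
    region_boost: float = 1.5
    n_observers: int = 20
    n_fixations: int = 25
    seed: int = 0


@dataclass(frozen=True)
class RaterModel:
    """Latent-rating model for synthetic raters.

    latent = footprint mean of the meaning field
             - strategy_weight * penalty_delta * [patch shows the inconsistent object]
             + N(0, noise_sd),
    discretised by rounding and clamping to 1..6.  ``strategy_weight`` is
    drawn once per rater, uniform on [0, 1], emulating individual
    differences in how much the inconsistency lowers a rater's judgement.
    """

    penalty_delta: float = 0.3
    noise_sd: float = 0.7
    seed: int = 0


# ---------------------------------------------------------------------------
# scenes


def _smooth_noise(rng: np.random.Generator, shape: tuple[int, int], sigma: float) -> np.ndarray:
    """Band-limited noise in [0, 1]."""
    z = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma)
    z -= z.min()
    rng_span = z.max() or 1.0
    return z / rng_span


def make_scene_specs(
    n_scenes: int,
    geometry: ScreenGeometry = DEFAULT_GEOMETRY,
    seed: int = 0,
    region_frac: float = 0.22,
) -> list[SceneSpec]:
    """Draw scene specs: objects, a critical region, and a meaning field.

    The critical region is a box of side ``region_frac`` of the image
    width placed away from the borders.  The meaning field is smooth
    background texture plus bumps at object locations (objects are
    meaningful), scaled into the Likert range [1, 6].
    """
    h, w = geometry.height_px, geometry.width_px
    rng = np.random.default_rng(seed)
    specs = []
    for s in range(n_scenes):
        scene_seed = int(rng.integers(2**31 - 1))
        srng = np.random.default_rng(scene_seed)
        side = max(4, int(region_frac * w))
        x0 = int(srng.integers(w // 10, w - side - w // 10))
        y0 = int(srng.integers(h // 10, h - side * 3 // 4 - h // 10))
        region = RegionBox(f"scene{s:02d}", x0, y0, x0 + side, y0 + side * 3 // 4)

        n_obj = int(srng.integers(2, 5))
        objects = []
        for _ in range(n_obj):
            cx = float(srng.uniform(0.1 * w, 0.9 * w))
            cy = float(srng.uniform(0.1 * h, 0.9 * h))
            size = float(srng.uniform(0.04, 0.10) * w)
            intensity = float(srng.uniform(0.3, 0.9))
            objects.append(((cx, cy), size, intensity))

        base = _smooth_noise(srng, (h, w), sigma=0.05 * w)  # [0, 1]
        fieldm = 1.0 + 2.0 * base  # background meaning 1..3
        yy, xx = np.mgrid[0:h, 0:w]
        for (cx, cy), size, _ in objects:
            bump = np.exp(-(((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * size**2)))
            fieldm += 2.5 * bump
        # the manipulated object sits in the critical region: meaningful spot
        rcx, rcy = (region.x0 + region.x1) / 2.0, (region.y0 + region.y1) / 2.0
        rsize = 0.3 * (region.x1 - region.x0)
        fieldm += 2.5 * np.exp(
            -(((xx - rcx) ** 2 + (yy - rcy) ** 2) / (2 * rsize**2))
        )
        fieldm = np.clip(fieldm, 1.0, 6.0)
        specs.append(
            SceneSpec(
                scene_id=region.scene_id,
                geometry=geometry,
                seed=scene_seed,
                objects=tuple(objects),
                critical_region=region,
                meaning_field=fieldm,
            )
        )
    return specs


def generate_scene_pair(spec: SceneSpec) -> ScenePair:
    """Render the consistent/inconsistent image pair for a scene spec.

    Outside the critical region the two renders are bit-identical.  Inside
    it, the consistent render shows a disc-shaped object and the
    inconsistent render a differently shaded rectangular object on a
    slightly re-lit region background (the re-photographed region never
    matches pixel-for-pixel), so the pixel-difference support is exactly
    the critical region.
    """
    g = spec.geometry
    h, w = g.height_px, g.width_px
    region = spec.critical_region
    if not (0 <= region.x0 < region.x1 <= w and 0 <= region.y0 < region.y1 <= h):
        raise ValueError("critical region outside image")
    srng = np.random.default_rng(spec.seed + 1)
    base = _smooth_noise(srng, (h, w), sigma=0.03 * w) * 0.5 + 0.25
    yy, xx = np.mgrid[0:h, 0:w]
    for (cx, cy), size, intensity in spec.objects:
        disc = (xx - cx) ** 2 + (yy - cy) ** 2 <= size**2
        base[disc] = intensity

    img_con = base.copy()
    img_incon = base.copy()
    sl = np.s_[region.y0 : region.y1, region.x0 : region.x1]
    rh, rw = region.y1 - region.y0, region.x1 - region.x0
    ryy, rxx = np.mgrid[0:rh, 0:rw]
    # consistent object: centred disc
    disc = (rxx - rw / 2) ** 2 + (ryy - rh / 2) ** 2 <= (min(rh, rw) / 3.0) ** 2
    img_con[sl][disc] = 0.85
    # inconsistent object: rectangle on re-lit background
    img_incon[sl] = np.clip(img_incon[sl] * 0.92 + 0.03, 0.0, 1.0)
    rect = (
        (rxx >= rw // 4) & (rxx < 3 * rw // 4) & (ryy >= rh // 4) & (ryy < 3 * rh // 4)
    )
    img_incon[sl][rect] = 0.15
    return ScenePair(spec=spec, image_consistent=img_con, image_inconsistent=img_incon)


# ---------------------------------------------------------------------------
# gaze


def generate_fixations(
    spec: SceneSpec,
    condition: Condition | str,
    model: GazeModel,
) -> list[FixationSequence]:
    """Sample fixation sequences for all observers on one image.

    Each fixation independently comes from the central Gaussian (with
    probability ``center_weight``) or from the meaning-field-proportional
    pixel distribution; in the inconsistent condition the critical
    region's field weights are multiplied by ``1 + region_boost``.
    """
    condition = Condition(condition)
    g = spec.geometry
    h, w = g.height_px, g.width_px
    weightmap = spec.meaning_field.astype(float).copy()
    if condition == Condition.INCONSISTENT and model.region_boost > 0:
        r = spec.critical_region
        weightmap[r.y0 : r.y1, r.x0 : r.x1] *= 1.0 + model.region_boost
    flat = weightmap.ravel()
    cdf = np.cumsum(flat)
    cdf /= cdf[-1]
    sx = g.deg_to_px_x(model.center_bias_sd[0])
    sy = g.deg_to_px_y(model.center_bias_sd[1])
    rng = np.random.default_rng(model.seed)

    image_id = f"{spec.scene_id}_{condition.value}"
    seqs = []
    for obs in range(model.n_observers):
        pts = []
        for _ in range(model.n_fixations):
            if rng.uniform() < model.center_weight:
                x = np.clip(rng.normal(w / 2.0, sx), 0, w - 1e-6)
                y = np.clip(rng.normal(h / 2.0, sy), 0, h - 1e-6)
            else:
                idx = int(np.searchsorted(cdf, rng.uniform()))
                ry, rx = divmod(idx, w)
                x = rx + rng.uniform()
                y = ry + rng.uniform()
            pts.append((float(x), float(y)))
        seqs.append(
            FixationSequence(
                observer_id=f"obs{obs:02d}", image_id=image_id, fixations=tuple(pts)
            )
        )
    return seqs


# ---------------------------------------------------------------------------
# ratings


def footprint_mean(field: np.ndarray, patch: Patch) -> float:
    """Mean of a dense field under the patch's circular footprint."""
    mask = circle_pixel_mask(patch.center, patch.diameter_px, field.shape)
    if not mask.any():
        raise ValueError("patch footprint covers no pixels")
    return float(field[mask].mean())


def _latent_to_rating(latent: np.ndarray) -> np.ndarray:
    return np.clip(np.rint(latent), 1, 6).astype(int)


def generate_ratings(
    patches: Sequence[Patch],
    fields: Mapping[str, np.ndarray],
    regions: Mapping[str, RegionBox],
    model: RaterModel,
    sets: Sequence[RaterSet],
    raters_per_set: int = 3,
) -> pd.DataFrame:
    """Simulate the patch-rating crowd task over pre-partitioned sets.

    ``fields`` maps scene_id to the ground-truth meaning field.  Each set
    is rated by ``raters_per_set`` unique raters.  A patch "shows the
    inconsistent object" iff it comes from the inconsistent condition and
    its footprint overlaps the scene's critical region.

    Returns a tidy table with columns rater_id, patch_id, value, set_id.
    """
    rng = np.random.default_rng(model.seed)
    base: dict[str, float] = {}
    penalized: dict[str, bool] = {}
    for p in patches:
        base[p.patch_id] = footprint_mean(fields[p.scene_id], p)
        penalized[p.patch_id] = (
            p.condition == Condition.INCONSISTENT
            and overlap_percentage(p, regions[p.scene_id]) > 0
        )
    rows: dict[str, list] = {"rater_id": [], "patch_id": [], "value": [], "set_id": []}
    rater_counter = 0
    for rset in sets:
        for _ in range(raters_per_set):
            rid = f"rater{rater_counter:03d}"
            rater_counter += 1
            sw = rng.uniform()
            mu = np.array(
                [
                    base[pid] - sw * model.penalty_delta * penalized[pid]
                    for pid in rset.patch_ids
                ]
            )
            vals = _latent_to_rating(mu + rng.normal(0, model.noise_sd, mu.size))
            rows["rater_id"].extend([rid] * len(rset.patch_ids))
            rows["patch_id"].extend(rset.patch_ids)
            rows["value"].extend(vals.tolist())
            rows["set_id"].extend([rset.set_id] * len(rset.patch_ids))
    return pd.DataFrame(rows)


def generate_exp2_ratings(
    design: Exp2Design,
    patch_lookup: Mapping[str, Patch],
    fields: Mapping[str, np.ndarray],
    n_raters: int,
    model: RaterModel,
) -> pd.DataFrame:
    """Simulate the follow-up rating task over the L/M/H/Con/Incon design.

    Raters alternate between the two condition-blinded subsets.  Only
    Incon presentations attract the inconsistency penalty (L/M/H patches
    are content-identical across context conditions; Con shows the
    consistent object).

    Returns columns rater_id, subset, patch_id, context_condition, role, value.
    """
    rng = np.random.default_rng(model.seed)
    role_of: dict[str, str] = {}
    scene_of: dict[str, str] = {}
    for scene, roles in design.roles.items():
        for role, pids in roles.items():
            for pid in pids:
                role_of[pid] = role
                scene_of[pid] = scene
    base = {
        pid: footprint_mean(fields[scene_of[pid]], patch_lookup[pid])
        for pid in role_of
    }
    rows: dict[str, list] = {
        "rater_id": [], "subset": [], "patch_id": [],
        "context_condition": [], "role": [], "value": [],
    }
    labels = sorted(design.subsets)
    for i in range(n_raters):
        label = labels[i % len(labels)]
        sw = rng.uniform()
        pair_idx = design.subsets[label]
        mu = np.empty(len(pair_idx))
        for j, k in enumerate(pair_idx):
            pid, cond = design.pairs[k]
            mu[j] = base[pid] - sw * model.penalty_delta * (role_of[pid] == "Incon")
        vals = _latent_to_rating(mu + rng.normal(0, model.noise_sd, mu.size))
        for j, k in enumerate(pair_idx):
            pid, cond = design.pairs[k]
            rows["rater_id"].append(f"rater{i:03d}")
            rows["subset"].append(label)
            rows["patch_id"].append(pid)
            rows["context_condition"].append(Condition(cond).value)
            rows["role"].append(role_of[pid])
            rows["value"].append(int(vals[j]))
    return pd.DataFrame(rows)
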