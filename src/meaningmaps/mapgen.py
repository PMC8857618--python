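"""Assembling meaning maps from patch ratings.

The pipeline: per grid level, average each patch's ratings and spread the
averages over the patch footprints (pixels covered by several patches get
the mean of the covering patches); fill pixels no patch covers by
nearest-covered-pixel interpolation plus a light Gaussian smooth; average
the fine and coarse level maps; down-weight the image borders with a
centre-bias model; finally histogram-match the map to a reference
distribution (in the study design, the smoothed fixation map of the same
image) so the two are on a common value scale.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .geometry import GridLevel, Patch, ScreenGeometry, circle_pixel_mask

__all__ = [
    "MeaningMap",
    "CenterBiasModel",
    "assemble_level_map",
    "combine_levels",
    "make_center_bias",
    "load_center_bias",
    "apply_center_bias",
    "histogram_match",
    "build_meaning_map",
]


@dataclass(frozen=True)
class MeaningMap:
    """A dense per-pixel meaning distribution for one image."""

    image_id: str
    level: str  # "fine" | "coarse" | "combined"
    values: np.ndarray  # (H, W) float
    center_bias_applied: bool = False
    histogram_matched: bool = False

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values)):
            raise ValueError("meaning map contains non-finite values")


@dataclass(frozen=True)
class CenterBiasModel:
    """Pixel weights in [0, 1], highest in the interior, low at the edges."""

    weights: np.ndarray  # (H, W)

    def __post_init__(self) -> None:
        w = self.weights
        if w.min() < 0 or w.max() > 1:
            raise ValueError("centre-bias weights must lie in [0, 1]")


def assemble_level_map(
    patches: Sequence[Patch],
    ratings: pd.DataFrame,
    geometry: ScreenGeometry,
    image_id: str = "",
    fill_sigma_frac: float = 0.01,
) -> MeaningMap:
    """Average ratings per patch and spread them over the image.

    Each pixel covered by at least one patch footprint receives the mean
    of the covering patches' average ratings.  Uncovered pixels are filled
    with the value of the nearest covered pixel and then smoothed with a
    Gaussian of sigma ``fill_sigma_frac * width_px``; covered pixels keep
    their exact covering means.  The output is *not* normalised — its
    scale is set later by histogram matching.
    """
    if not patches:
        raise ValueError("no patches given")
    means = ratings.groupby("patch_id")["value"].mean()
    missing = [p.patch_id for p in patches if p.patch_id not in means.index]
    if missing:
        raise ValueError(f"patches without ratings: {missing[:10]}")
    if not ratings["value"].between(1, 6).all():
        raise ValueError("ratings must lie in 1..6")

    h, w = geometry.height_px, geometry.width_px
    total = np.zeros((h, w))
    count = np.zeros((h, w))
    for p in patches:
        mask = circle_pixel_mask(p.center, p.diameter_px, (h, w))
        total[mask] += means[p.patch_id]
        count[mask] += 1
    covered = count > 0
    values = np.zeros((h, w))
    values[covered] = total[covered] / count[covered]
    if not covered.all():
        if not covered.any():
            raise ValueError("no pixel covered by any patch footprint")
        # nearest-covered fill, then smooth only the filled-in pixels
        _, (iy, ix) = ndimage.distance_transform_edt(
            ~covered, return_indices=True
        )
        filled = values[iy, ix]
        blurred = ndimage.gaussian_filter(filled, sigma=fill_sigma_frac * w)
        values = np.where(covered, values, blurred)
    level = patches[0].level
    return MeaningMap(image_id=image_id, level=GridLevel(level).value, values=values)


def combine_levels(fine: MeaningMap, coarse: MeaningMap) -> MeaningMap:
    """Pixel-wise average of the fine- and coarse-level maps."""
    if fine.values.shape != coarse.values.shape:
        raise ValueError("level maps have different shapes")
    if fine.center_bias_applied or coarse.center_bias_applied:
        raise ValueError("combine before applying centre bias")
    return MeaningMap(
        image_id=fine.image_id,
        level="combined",
        values=(fine.values + coarse.values) / 2.0,
    )


def make_center_bias(
    geometry: ScreenGeometry, half_width_frac: tuple[float, float] = (0.7, 0.7)
) -> CenterBiasModel:
    """Parametric centre-bias surrogate: anisotropic squared-cosine falloff.

    The weight at normalised elliptical radius rho (1 at ``half_width_frac``
    of the image half-extent) is ``cos^2(pi/2 * min(rho, 1))`` — 1 at the
    image centre, monotonically non-increasing along every ray, 0 beyond
    the falloff ellipse.  A smooth stand-in for empirical centre-bias
    weight fields; :func:`load_center_bias` accepts an external field when
    fidelity to a specific model is needed.
    """
    h, w = geometry.height_px, geometry.width_px
    y = (np.arange(h) + 0.5 - h / 2.0) / (h / 2.0 * half_width_frac[1])
    x = (np.arange(w) + 0.5 - w / 2.0) / (w / 2.0 * half_width_frac[0])
    rho = np.sqrt(x[None, :] ** 2 + y[:, None] ** 2)
    weights = np.cos(np.pi / 2.0 * np.minimum(rho, 1.0)) ** 2
    weights /= weights.max()  # peak-normalise the sampled field
    return CenterBiasModel(weights=weights)


def load_center_bias(path: str, geometry: ScreenGeometry) -> CenterBiasModel:
    """Load an external weight matrix (plain text) and resample to the image."""
    raw = np.loadtxt(path)
    if raw.ndim != 2:
        raise ValueError("centre-bias file must hold a 2-D matrix")
    if raw.min() < 0:
        raise ValueError("centre-bias weights negative after load")
    if raw.max() > 0:
        raw = raw / raw.max()
    h, w = geometry.height_px, geometry.width_px
    zoom = (h / raw.shape[0], w / raw.shape[1])
    weights = np.clip(ndimage.zoom(raw, zoom, order=1), 0.0, 1.0)
    if weights.shape != (h, w):  # zoom rounding
        weights = weights[:h, :w]
    return CenterBiasModel(weights=weights)


def apply_center_bias(mmap: MeaningMap, cbm: CenterBiasModel) -> MeaningMap:
    """Pixel-wise product of the map with the centre-bias weights."""
    if mmap.center_bias_applied:
        raise ValueError("centre bias already applied to this map")
    if mmap.values.shape != cbm.weights.shape:
        raise ValueError("map and centre-bias shapes differ")
    return replace(
        mmap, values=mmap.values * cbm.weights, center_bias_applied=True
    )


def histogram_match(mmap: MeaningMap, reference: np.ndarray) -> MeaningMap:
    """Rank-preserving reassignment of the reference's value distribution.

    The i-th smallest map pixel receives the i-th smallest reference
    value; ties in the map are resolved stably by pixel index (row-major).
    The output's sorted values therefore equal the reference's sorted
    values exactly, and the operation is idempotent.
    """
    values = mmap.values
    ref = np.asarray(reference, dtype=float)
    if values.size == 0 or ref.size == 0:
        raise ValueError("empty input to histogram matching")
    if values.size != ref.size:
        raise ValueError("map and reference must have the same pixel count")
    flat = values.ravel()
    order = np.argsort(flat, kind="stable")
    out = np.empty_like(flat)
    out[order] = np.sort(ref, axis=None)
    return replace(mmap, values=out.reshape(values.shape), histogram_matched=True)


def build_meaning_map(
    fine_patches: Sequence[Patch],
    coarse_patches: Sequence[Patch],
    ratings: pd.DataFrame,
    geometry: ScreenGeometry,
    reference: np.ndarray | None = None,
    center_bias: CenterBiasModel | None = None,
    image_id: str = "",
) -> MeaningMap:
    """Full pipeline: level maps -> combine -> centre bias -> histogram match.

    ``center_bias=None`` builds the parametric surrogate; pass a model with
    all-ones weights to disable re-weighting.  ``reference=None`` skips
    histogram matching (leaving the map on the raw rating scale).
    """
    fine = assemble_level_map(fine_patches, ratings, geometry, image_id)
    coarse = assemble_level_map(coarse_patches, ratings, geometry, image_id)
    combined = combine_levels(fine, coarse)
    if center_bias is None:
        center_bias = make_center_bias(geometry)
    out = apply_center_bias(combined, center_bias)
    if reference is not None:
        out = histogram_match(out, reference)
    return out
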