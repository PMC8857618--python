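"""Fixation maps and region-based gaze/map comparison measures.

Discrete fixation locations, pooled across observers, are turned into a
continuous distribution by Gaussian smoothing and max-normalisation to
[0, 1].  The Gaussian's width is specified through the frequency at which
its amplitude response has fallen to -6 dB (half amplitude), expressed in
cycles per image width: for a Gaussian filter the transfer function is
``G(f) = exp(-2 pi^2 sigma^2 f^2)``, so

    sigma_px = sqrt(ln(10^(6/20)) / 2) / (pi * f_c) * width_px.

Maps (smoothed fixations or meaning maps) are compared to critical
regions through the mass-in-region density — distribution mass inside the
region divided by the region's pixel area — and to each other through
per-pixel Pearson correlation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal, stats

from .geometry import Condition, Patch, RegionBox, ScreenGeometry, overlap_percentage

__all__ = [
    "FixationSequence",
    "SmoothedFixationMap",
    "sigma_for_cutoff",
    "smooth_fixations",
    "mass_in_region",
    "map_correlation",
    "ordinal_first_fixation",
    "patch_rating_region_analysis",
]

#: default -6 dB cutoff of the smoothing kernel, in cycles per image width
DEFAULT_CUTOFF = 8.0


@dataclass(frozen=True)
class FixationSequence:
    """Ordered fixations of one observer on one image (pixel coordinates)."""

    observer_id: str
    image_id: str
    fixations: tuple[tuple[float, float], ...]


@dataclass(frozen=True)
class SmoothedFixationMap:
    image_id: str
    values: np.ndarray  # (H, W), max 1 when any fixation present

    def __post_init__(self) -> None:
        if self.values.min() < 0:
            raise ValueError("smoothed fixation map must be non-negative")


def sigma_for_cutoff(cutoff_cycles_per_image: float, width_px: int) -> float:
    """Gaussian sigma (pixels) whose amplitude response is -6 dB at the cutoff."""
    if cutoff_cycles_per_image <= 0:
        raise ValueError("cutoff must be > 0")
    target = 10.0 ** (-6.0 / 20.0)  # amplitude ratio at the cutoff
    f = cutoff_cycles_per_image / width_px  # cycles / pixel
    return float(np.sqrt(-np.log(target) / 2.0) / (np.pi * f))


def smooth_fixations(
    seqs: Sequence[FixationSequence],
    geometry: ScreenGeometry,
    cutoff_cycles_per_image: float = DEFAULT_CUTOFF,
) -> SmoothedFixationMap:
    """Pool fixations across observers, smooth, and normalise to [0, 1].

    Fixations are binned at the pixel containing them, convolved with the
    isotropic Gaussian defined by the -6 dB cutoff (kernel truncated at
    6.5 sigma, zero-padded boundaries), and divided by the maximum.
    """
    h, w = geometry.height_px, geometry.width_px
    counts = np.zeros((h, w))
    n = 0
    image_ids = set()
    for s in seqs:
        image_ids.add(s.image_id)
        for x, y in s.fixations:
            c = min(int(x), w - 1)
            r = min(int(y), h - 1)
            if not (0 <= c < w and 0 <= r < h):
                raise ValueError(f"fixation ({x}, {y}) outside image {w}x{h}")
            counts[r, c] += 1
            n += 1
    if n == 0:
        raise ValueError("no fixations to smooth")
    if len(image_ids) > 1:
        raise ValueError(f"sequences from multiple images: {sorted(image_ids)}")

    sigma = sigma_for_cutoff(cutoff_cycles_per_image, w)
    rad = int(np.ceil(6.5 * sigma))
    ax = np.arange(-rad, rad + 1)
    kern1d = np.exp(-(ax**2) / (2.0 * sigma**2))
    kernel = np.outer(kern1d, kern1d)
    dense = signal.oaconvolve(counts, kernel, mode="same")
    dense = np.maximum(dense, 0.0)  # guard fft round-off
    return SmoothedFixationMap(
        image_id=next(iter(image_ids)), values=dense / dense.max()
    )


def mass_in_region(map_values: np.ndarray, region: RegionBox) -> float:
    """Distribution mass inside the region divided by the region's area."""
    h, w = map_values.shape
    if not (0 <= region.x0 < region.x1 <= w and 0 <= region.y0 < region.y1 <= h):
        raise ValueError("region extends outside the map")
    block = map_values[region.y0 : region.y1, region.x0 : region.x1]
    if block.size == 0:
        raise ValueError("empty region")
    return float(block.sum() / block.size)


def map_correlation(
    map_values: np.ndarray, smoothed: SmoothedFixationMap | np.ndarray
) -> tuple[float, float]:
    """Per-pixel Pearson r between a map and smoothed fixations, plus r²."""
    other = smoothed.values if isinstance(smoothed, SmoothedFixationMap) else smoothed
    if map_values.shape != other.shape:
        raise ValueError("maps must have the same shape")
    a, b = map_values.ravel(), np.asarray(other, dtype=float).ravel()
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("correlation undefined for a constant map")
    r = float(stats.pearsonr(a, b).statistic)
    return r, r * r


def ordinal_first_fixation(
    seq: FixationSequence, region: RegionBox, include_first: bool = True
) -> int | None:
    """1-based index of the first fixation landing in the region, or None.

    ``include_first=False`` drops the first recorded fixation (typically
    the screen-centre fixation at image onset) before counting.
    """
    fixations = seq.fixations if include_first else seq.fixations[1:]
    for i, (x, y) in enumerate(fixations, start=1):
        if region.contains(x, y):
            return i
    return None


def patch_rating_region_analysis(
    ratings: pd.DataFrame,
    patches: Sequence[Patch],
    regions: Mapping[str, RegionBox],
    threshold: float = 0.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean rating of region-overlapping patches per scene/condition/level.

    Retains patches whose overlap percentage with their scene's critical
    region is above zero and at least ``threshold`` (so ``threshold=0``
    keeps every patch touching the region by at least one pixel), then
    averages the retained patches' mean ratings per scene x condition x
    level.  Scene/condition/level cells where no patch survives the
    threshold are returned separately in a ``dropped`` table.
    """
    means = ratings.groupby("patch_id")["value"].mean()
    rows = []
    for p in patches:
        ov = overlap_percentage(p, regions[p.scene_id])
        if ov > 0 and ov >= threshold and p.patch_id in means.index:
            rows.append(
                {
                    "scene_id": p.scene_id,
                    "condition": Condition(p.condition).value,
                    "level": p.level.value,
                    "patch_id": p.patch_id,
                    "overlap": ov,
                    "mean_rating": means[p.patch_id],
                }
            )
    retained = pd.DataFrame(
        rows,
        columns=["scene_id", "condition", "level", "patch_id", "overlap", "mean_rating"],
    )
    summary = (
        retained.groupby(["scene_id", "condition", "level"])["mean_rating"]
        .mean()
        .reset_index()
    )
    # cells present in the patch list but absent after filtering
    all_cells = pd.DataFrame(
        sorted(
            {(p.scene_id, Condition(p.condition).value, p.level.value) for p in patches}
        ),
        columns=["scene_id", "condition", "level"],
    )
    dropped = all_cells.merge(
        summary[["scene_id", "condition", "level"]],
        how="left",
        indicator=True,
    )
    dropped = dropped[dropped["_merge"] == "left_only"].drop(columns="_merge")
    return summary, dropped.reset_index(drop=True)
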