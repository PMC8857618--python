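"""Patch grids, circular patches, and critical-region geometry.

Meaning maps are built from ratings of circular, partially overlapping
patches laid out on a regular grid over the image.  Two grid levels are
used: *coarse* (larger, sparser patches) and *fine* (smaller, denser).
The grid is specified in degrees of visual angle — a patch diameter and a
target patch density in patches/deg² — and realised in pixels for a given
screen geometry.

Coordinate conventions: pixel indices are 0-based with the origin at the
top-left; a pixel ``(col, row)`` occupies the unit square
``[col, col+1) x [row, row+1)`` and its centre sits at
``(col + 0.5, row + 0.5)``.  Region boxes are half-open,
``[x0, x1) x [y0, y1)``.  A pixel belongs to a circular patch iff its
centre lies within ``diameter / 2`` of the patch centre.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np

__all__ = [
    "ScreenGeometry",
    "GridLevel",
    "Condition",
    "PatchGrid",
    "Patch",
    "RegionBox",
    "build_grid",
    "extract_patch",
    "circle_pixel_mask",
    "overlap_percentage",
    "select_overlap_thresholds",
]


class GridLevel(str, Enum):
    COARSE = "coarse"
    FINE = "fine"


class Condition(str, Enum):
    CONSISTENT = "consistent"
    INCONSISTENT = "inconsistent"


@dataclass(frozen=True)
class ScreenGeometry:
    """Pixel <-> visual-degree mapping for a displayed image."""

    width_px: int
    height_px: int
    width_deg: float
    height_deg: float

    def __post_init__(self) -> None:
        for name in ("width_px", "height_px", "width_deg", "height_deg"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and > 0, got {v!r}")

    @property
    def px_per_deg_x(self) -> float:
        return self.width_px / self.width_deg

    @property
    def px_per_deg_y(self) -> float:
        return self.height_px / self.height_deg

    @property
    def area_deg2(self) -> float:
        return self.width_deg * self.height_deg

    def deg_to_px_x(self, deg: float) -> float:
        return deg * self.px_per_deg_x

    def deg_to_px_y(self, deg: float) -> float:
        return deg * self.px_per_deg_y

    def scaled(self, factor: float) -> "ScreenGeometry":
        """Same field of view rendered at ``factor`` times the pixel count."""
        return ScreenGeometry(
            width_px=max(1, round(self.width_px * factor)),
            height_px=max(1, round(self.height_px * factor)),
            width_deg=self.width_deg,
            height_deg=self.height_deg,
        )


@dataclass(frozen=True)
class PatchGrid:
    """A rectangular layout of circular-patch centres at one grid level."""

    level: GridLevel
    diameter_px: int
    n_cols: int
    n_rows: int
    centers: tuple[tuple[float, float], ...]
    achieved_density: float

    def __len__(self) -> int:
        return len(self.centers)


@dataclass(frozen=True)
class Patch:
    """One circular patch instance, tied to a scene and condition."""

    patch_id: str
    scene_id: str
    condition: Condition
    level: GridLevel
    center: tuple[float, float]
    diameter_px: int
    clipped: bool = False


@dataclass(frozen=True)
class RegionBox:
    """Half-open pixel bounding box ``[x0, x1) x [y0, y1)``."""

    scene_id: str
    x0: int
    y0: int
    x1: int
    y1: int

    def __post_init__(self) -> None:
        if not (self.x1 > self.x0 and self.y1 > self.y0):
            raise ValueError("RegionBox requires x1 > x0 and y1 > y0")

    @property
    def area_px(self) -> int:
        return (self.x1 - self.x0) * (self.y1 - self.y0)

    def contains(self, x: float, y: float) -> bool:
        """Half-open point-in-box test (boundary at x0/y0 counts as inside)."""
        return (self.x0 <= x < self.x1) and (self.y0 <= y < self.y1)


def build_grid(
    geometry: ScreenGeometry,
    target_density: float,
    diameter_px: int,
    level: GridLevel | str = GridLevel.COARSE,
    max_n: int = 64,
    spacing_ratio_bounds: tuple[float, float] = (0.8, 1.25),
) -> PatchGrid:
    """Lay out patch centres so the achieved density best matches the target.

    Candidate layouts are all ``(n_cols, n_rows)`` pairs with
    ``1 <= n <= max_n`` whose horizontal/vertical centre spacing ratio (in
    pixels) lies within ``spacing_ratio_bounds`` — the near-equidistance
    constraint.  Among them the layout minimising
    ``|n_cols * n_rows / image_area_deg2 - target_density|`` wins; ties are
    broken by the spacing ratio closest to 1, then by larger ``n_cols``.
    Centres are cell-centred (inset by half a spacing from each edge) and
    listed row-major.

    Parameters
    ----------
    geometry
        Image size in pixels and degrees of visual angle.
    target_density
        Desired number of patches per squared degree.
    diameter_px
        Patch diameter in pixels; carried through to the grid, not used in
        the layout search.
    """
    if target_density <= 0:
        raise ValueError("target_density must be > 0")
    if diameter_px < 1:
        raise ValueError("diameter_px must be >= 1")
    level = GridLevel(level)

    lo, hi = spacing_ratio_bounds
    best = None  # (|density err|, |log spacing ratio|, -n_cols, n_cols, n_rows)
    for n_cols, n_rows in itertools.product(range(1, max_n + 1), repeat=2):
        sx = geometry.width_px / n_cols
        sy = geometry.height_px / n_rows
        ratio = sx / sy
        if not (lo <= ratio <= hi):
            continue
        density = n_cols * n_rows / geometry.area_deg2
        key = (abs(density - target_density), abs(np.log(ratio)), -n_cols)
        if best is None or key < best[0]:
            best = (key, n_cols, n_rows)
    if best is None:
        raise ValueError("no admissible grid layout under the spacing constraint")
    _, n_cols, n_rows = best

    sx = geometry.width_px / n_cols
    sy = geometry.height_px / n_rows
    centers = tuple(
        ((c + 0.5) * sx, (r + 0.5) * sy)
        for r in range(n_rows)
        for c in range(n_cols)
    )
    return PatchGrid(
        level=level,
        diameter_px=int(diameter_px),
        n_cols=n_cols,
        n_rows=n_rows,
        centers=centers,
        achieved_density=n_cols * n_rows / geometry.area_deg2,
    )


def is_clipped(center: tuple[float, float], diameter_px: int, shape_wh: tuple[int, int]) -> bool:
    """True iff the circular footprint extends past any image edge."""
    cx, cy = center
    r = diameter_px / 2.0
    w, h = shape_wh
    return cx - r < 0 or cy - r < 0 or cx + r > w or cy + r > h


def grid_patches(
    grid: PatchGrid,
    geometry: ScreenGeometry,
    scene_id: str,
    condition: Condition | str,
) -> list[Patch]:
    """Instantiate one :class:`Patch` per grid centre for a scene/condition."""
    condition = Condition(condition)
    out = []
    for i, (cx, cy) in enumerate(grid.centers):
        out.append(
            Patch(
                patch_id=f"{scene_id}_{condition.value[:3]}_{grid.level.value}_{i:03d}",
                scene_id=scene_id,
                condition=condition,
                level=grid.level,
                center=(cx, cy),
                diameter_px=grid.diameter_px,
                clipped=is_clipped((cx, cy), grid.diameter_px, (geometry.width_px, geometry.height_px)),
            )
        )
    return out


def circle_pixel_mask(
    center: tuple[float, float], diameter_px: float, shape_hw: tuple[int, int]
) -> np.ndarray:
    """Boolean (H, W) mask of pixels whose centres fall inside the circle."""
    h, w = shape_hw
    cy, cx = np.arange(h) + 0.5, np.arange(w) + 0.5
    dy = (cy - center[1])[:, None]
    dx = (cx - center[0])[None, :]
    return dx * dx + dy * dy <= (diameter_px / 2.0) ** 2


def extract_patch(
    image: np.ndarray, patch: Patch, background: float = 0.5
) -> np.ndarray:
    """Crop a square of side ``diameter_px`` around the patch centre.

    Pixels outside the inscribed circle — and any part of the footprint
    lying off the image (clipping) — are set to ``background``
    (mid-grey by default, on whatever intensity scale the image uses).
    """
    h, w = image.shape[:2]
    cx, cy = patch.center
    if not (0 <= cx <= w and 0 <= cy <= h):
        raise ValueError(f"patch centre {patch.center} outside image {w}x{h}")
    d = patch.diameter_px
    out = np.full((d, d) + image.shape[2:], background, dtype=float)

    # top-left pixel index of the crop in image coordinates
    x0 = int(np.floor(cx - d / 2.0))
    y0 = int(np.floor(cy - d / 2.0))
    ys, xs = np.arange(y0, y0 + d), np.arange(x0, x0 + d)
    in_y = (ys >= 0) & (ys < h)
    in_x = (xs >= 0) & (xs < w)
    dy = (ys + 0.5 - cy)[:, None]
    dx = (xs + 0.5 - cx)[None, :]
    in_circle = dx * dx + dy * dy <= (d / 2.0) ** 2
    valid = in_circle & in_y[:, None] & in_x[None, :]
    src = image[np.clip(ys, 0, h - 1)[:, None], np.clip(xs, 0, w - 1)[None, :]]
    out[valid] = src[valid]
    return out


def overlap_percentage(
    patch: Patch, region: RegionBox, shape_hw: tuple[int, int] | None = None
) -> float:
    """Percent of the patch's circle pixels lying inside the region box.

    The circle is rasterised by the centre-of-pixel rule over its own
    bounding box (the footprint may extend past the image; those pixels
    still belong to the circle for area purposes, matching clipped-patch
    handling).  Deterministic: pure integer pixel counting.
    """
    cx, cy = patch.center
    d = patch.diameter_px
    x0 = int(np.floor(cx - d / 2.0))
    y0 = int(np.floor(cy - d / 2.0))
    xs = np.arange(x0, x0 + d + 1)
    ys = np.arange(y0, y0 + d + 1)
    dx = (xs + 0.5 - cx)[None, :]
    dy = (ys + 0.5 - cy)[:, None]
    circle = dx * dx + dy * dy <= (d / 2.0) ** 2
    n_circle = int(circle.sum())
    if n_circle == 0:
        raise ValueError("degenerate patch: no pixels inside circle")
    in_box = (
        (xs >= region.x0) & (xs < region.x1))[None, :] & (
        (ys >= region.y0) & (ys < region.y1))[:, None]
    return 100.0 * int((circle & in_box).sum()) / n_circle


def select_overlap_thresholds(overlaps: Sequence[float]) -> tuple[float, float]:
    """34th and 67th percentiles of the above-zero overlap percentages.

    Filtering patches at these thresholds retains roughly 66% / 33% of the
    patches that touch the region at all.
    """
    pos = np.asarray([o for o in overlaps if o > 0], dtype=float)
    if pos.size == 0:
        raise ValueError("no above-zero overlap percentages")
    t34, t67 = np.percentile(pos, [34.0, 67.0])
    return float(t34), float(t67)
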