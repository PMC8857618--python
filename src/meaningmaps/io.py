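"""Readers and writers for the pipeline's tabular and image formats.

All tables are plain CSV; critical regions travel as JSON; dense maps are
stored as NumPy ``.npy`` files with an optional 8-bit grayscale PNG
render for quick inspection.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .gaze import FixationSequence
from .geometry import Condition, GridLevel, Patch, RegionBox

__all__ = [
    "write_fixations_csv",
    "read_fixations_csv",
    "write_regions_json",
    "read_regions_json",
    "write_patch_manifest",
    "read_patch_manifest",
    "save_map",
    "load_map",
    "write_map_png",
    "write_image_png",
]


def write_fixations_csv(seqs: Iterable[FixationSequence], path: str | Path) -> None:
    rows = [
        {"observer_id": s.observer_id, "image_id": s.image_id, "index": i,
         "x_px": x, "y_px": y}
        for s in seqs
        for i, (x, y) in enumerate(s.fixations, start=1)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_fixations_csv(path: str | Path) -> list[FixationSequence]:
    df = pd.read_csv(path)
    seqs = []
    for (obs, img), g in df.groupby(["observer_id", "image_id"], sort=True):
        g = g.sort_values("index")
        seqs.append(
            FixationSequence(
                observer_id=str(obs),
                image_id=str(img),
                fixations=tuple(zip(g["x_px"].astype(float), g["y_px"].astype(float))),
            )
        )
    return seqs


def write_regions_json(regions: Mapping[str, RegionBox], path: str | Path) -> None:
    payload = {
        sid: {"x0": r.x0, "y0": r.y0, "x1": r.x1, "y1": r.y1}
        for sid, r in regions.items()
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_regions_json(path: str | Path) -> dict[str, RegionBox]:
    payload = json.loads(Path(path).read_text())
    return {
        sid: RegionBox(sid, int(d["x0"]), int(d["y0"]), int(d["x1"]), int(d["y1"]))
        for sid, d in payload.items()
    }


def write_patch_manifest(patches: Iterable[Patch], path: str | Path) -> None:
    rows = [
        {"patch_id": p.patch_id, "scene_id": p.scene_id,
         "condition": Condition(p.condition).value, "level": GridLevel(p.level).value,
         "cx": p.center[0], "cy": p.center[1],
         "diameter_px": p.diameter_px, "clipped": p.clipped}
        for p in patches
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_patch_manifest(path: str | Path) -> list[Patch]:
    df = pd.read_csv(path)
    return [
        Patch(
            patch_id=str(r.patch_id), scene_id=str(r.scene_id),
            condition=Condition(r.condition), level=GridLevel(r.level),
            center=(float(r.cx), float(r.cy)),
            diameter_px=int(r.diameter_px), clipped=bool(r.clipped),
        )
        for r in df.itertuples()
    ]


def save_map(values: np.ndarray, path: str | Path) -> None:
    np.save(path, np.asarray(values, dtype=float))


def load_map(path: str | Path) -> np.ndarray:
    return np.load(path)


def _to_uint8(values: np.ndarray) -> np.ndarray:
    v = np.asarray(values, dtype=float)
    span = np.ptp(v)
    norm = (v - v.min()) / span if span > 0 else np.zeros_like(v)
    return (norm * 255).round().astype(np.uint8)


def write_map_png(values: np.ndarray, path: str | Path) -> None:
    """8-bit grayscale render of a dense map (for inspection only)."""
    iio.imwrite(path, _to_uint8(values))


def write_image_png(image: np.ndarray, path: str | Path) -> None:
    """Write a [0, 1] float image as 8-bit grayscale PNG."""
    iio.imwrite(path, (np.clip(image, 0, 1) * 255).round().astype(np.uint8))
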