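"""Whole-slide tessellation into non-overlapping tiles.

A region of interest (ROI) mask over a slide-scale RGB image is cut into
non-overlapping ``tile_size`` squares on a grid anchored at the top-left of
the ROI bounding box.  A grid cell becomes a tile iff it lies fully inside
the image and at least ``min_roi_coverage`` of its pixels are inside the
mask.  Output order is row-major, so tessellation is deterministic.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Optional, Union

import numpy as np
import pandas as pd
from PIL import Image

from .records import (
    DEFAULT_RESOLUTION_MPP,
    MANIFEST_COLUMNS,
    TILE_SIZE,
    TileRecord,
    parse_tile_filename,
    tile_filename,
)


def tessellate(
    slide_image: np.ndarray,
    roi_mask: np.ndarray,
    tile_size: int = TILE_SIZE,
    min_roi_coverage: float = 0.5,
    *,
    slide_id: str = "slide",
    patient_id: str = "unknown",
    label: int = 0,
    resolution: float = DEFAULT_RESOLUTION_MPP,
) -> list[TileRecord]:
    """Cut the masked region of a slide into grid tiles.

    An empty mask yields an empty list; a mask whose shape differs from the
    image raises ``ValueError``.
    """
    if slide_image.ndim != 3 or slide_image.shape[2] != 3:
        raise ValueError(f"slide image must be HxWx3, got shape {slide_image.shape}")
    if roi_mask.shape != slide_image.shape[:2]:
        raise ValueError(
            f"mask shape {roi_mask.shape} does not match image shape {slide_image.shape[:2]}"
        )
    if tile_size < 1:
        raise ValueError("tile_size must be >= 1")

    inside = roi_mask > 0
    if not inside.any():
        return []
    rows = np.flatnonzero(inside.any(axis=1))
    cols = np.flatnonzero(inside.any(axis=0))
    y_anchor, x_anchor = int(rows[0]), int(cols[0])

    height, width = slide_image.shape[:2]
    tiles: list[TileRecord] = []
    min_pixels = min_roi_coverage * tile_size * tile_size
    for y in range(y_anchor, height - tile_size + 1, tile_size):
        for x in range(x_anchor, width - tile_size + 1, tile_size):
            coverage = int(inside[y : y + tile_size, x : x + tile_size].sum())
            if coverage >= min_pixels:
                tiles.append(
                    TileRecord(
                        pixels=np.ascontiguousarray(slide_image[y : y + tile_size, x : x + tile_size]),
                        slide_id=slide_id,
                        patient_id=patient_id,
                        origin=(x, y),
                        label=label,
                        resolution=resolution,
                    )
                )
    return tiles


def write_tiles(tiles: Iterable[TileRecord], directory: Union[str, Path]) -> Path:
    """Write tiles as PNGs named ``{slide_id}_x{X}_y{Y}.png`` plus a manifest CSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for tile in tiles:
        name = tile_filename(tile.slide_id, tile.origin[0], tile.origin[1])
        Image.fromarray(tile.pixels).save(directory / name)
        rows.append(
            {
                "tile_path": name,
                "patient_id": tile.patient_id,
                "slide_id": tile.slide_id,
                "x_origin": tile.origin[0],
                "y_origin": tile.origin[1],
                "label": tile.label,
            }
        )
    manifest_path = directory / "manifest.csv"
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(manifest_path, index=False)
    return manifest_path


def read_tiles(manifest_path: Union[str, Path]) -> list[TileRecord]:
    """Load tiles referenced by a manifest; a missing PNG raises an error naming it."""
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise FileNotFoundError(f"manifest not found: {manifest_path}")
    frame = pd.read_csv(manifest_path)
    base = manifest_path.parent
    tiles = []
    for row in frame.itertuples():
        path = base / str(row.tile_path)
        if not path.exists():
            raise FileNotFoundError(f"tile image missing: {path}")
        pixels = np.asarray(Image.open(path).convert("RGB"))
        tiles.append(
            TileRecord(
                pixels=pixels,
                slide_id=str(row.slide_id),
                patient_id=str(row.patient_id),
                origin=(int(row.x_origin), int(row.y_origin)),
                label=int(row.label),
            )
        )
    return tiles
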