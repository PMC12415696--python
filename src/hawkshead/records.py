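"""Core data records shared across the pipeline.

A *tile* is a 512x512 RGB sub-image cut from a whole-slide image (WSI)
region of interest; every tile carries the identity of the slide and
patient it came from, its origin in slide pixel coordinates, and a binary
class label (0 = reactive lymphoid hyperplasia-like, 1 = large-cell
lymphoma-like).  Tiles are the unit of training; predictions are the unit
of evaluation and overlay.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

#: Default tile edge length in pixels.
TILE_SIZE = 512

#: Default slide resolution in micrometres per pixel (20x magnification scan).
DEFAULT_RESOLUTION_MPP = 0.22

#: Columns of the tile manifest CSV, the inter-stage hand-off format.
MANIFEST_COLUMNS = [
    "tile_path",
    "patient_id",
    "slide_id",
    "x_origin",
    "y_origin",
    "label",
]


@dataclass
class TileRecord:
    """One tile with its provenance.

    ``origin`` is 0-based slide pixel coordinates of the top-left corner;
    the tile extent is the half-open square ``[x, x+size) x [y, y+size)``.
    """

    pixels: np.ndarray  # (H, W, 3) uint8
    slide_id: str
    patient_id: str
    origin: tuple[int, int]
    label: int
    resolution: float = DEFAULT_RESOLUTION_MPP

    def __post_init__(self) -> None:
        x, y = self.origin
        if x < 0 or y < 0:
            raise ValueError(f"tile origin must be non-negative, got {self.origin}")
        if self.label not in (0, 1):
            raise ValueError(f"tile label must be 0 or 1, got {self.label}")

    @property
    def tile_id(self) -> str:
        """Stable identity: slide id plus grid origin."""
        return tile_filename(self.slide_id, self.origin[0], self.origin[1], suffix="")

    def with_pixels(self, pixels: np.ndarray) -> "TileRecord":
        return replace(self, pixels=pixels)


@dataclass
class PredictionRecord:
    """A tile-level model output: score ``y_hat`` in [0, 1] plus identity."""

    tile_id: str
    slide_id: str
    origin: tuple[int, int]
    score: float
    label: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"prediction score must lie in [0, 1], got {self.score}")


def tile_filename(slide_id: str, x: int, y: int, suffix: str = ".png") -> str:
    """File-name convention ``{slide_id}_x{X}_y{Y}.png`` (bit-exact contract)."""
    return f"{slide_id}_x{x}_y{y}{suffix}"


def parse_tile_filename(name: str) -> tuple[str, int, int]:
    """Invert :func:`tile_filename`; raises ``ValueError`` on malformed names."""
    stem = Path(name).name
    if stem.endswith(".png"):
        stem = stem[:-4]
    try:
        head, ytxt = stem.rsplit("_y", 1)
        slide_id, xtxt = head.rsplit("_x", 1)
        return slide_id, int(xtxt), int(ytxt)
    except (ValueError, IndexError) as exc:
        raise ValueError(f"not a tile file name: {name!r}") from exc


def predictions_to_frame(records: Iterable[PredictionRecord]) -> pd.DataFrame:
    rows = [
        {
            "tile_id": r.tile_id,
            "slide_id": r.slide_id,
            "x": r.origin[0],
            "y": r.origin[1],
            "score": r.score,
            "label": r.label,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=["tile_id", "slide_id", "x", "y", "score", "label"])


def frame_to_predictions(frame: pd.DataFrame) -> list[PredictionRecord]:
    return [
        PredictionRecord(
            tile_id=str(row.tile_id),
            slide_id=str(row.slide_id),
            origin=(int(row.x), int(row.y)),
            score=float(row.score),
            label=int(row.label),
        )
        for row in frame.itertuples()
    ]
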