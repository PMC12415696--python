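"""Whole-slide prediction overlays.

Tile-level scores are mapped back to their slide coordinates as a
blue-to-red probability heatmap (0 = blue = non-neoplastic-like,
1 = red = neoplastic-like) and exported as GeoJSON polygons for viewers
that consume vector annotations (pixel coordinates, y increasing downward,
the convention of slide viewers such as QuPath).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Union

import numpy as np

from .records import TILE_SIZE, PredictionRecord


@dataclass
class OverlayMap:
    """Per-slide grid of (origin, score) cells on the tessellation grid."""

    slide_id: str
    tile_size: int
    cells: list[tuple[int, int, float]]  # (x, y, score)

    def __post_init__(self) -> None:
        seen = set()
        for x, y, score in self.cells:
            if not 0.0 <= score <= 1.0:
                raise ValueError(f"cell score {score} outside [0, 1]")
            if (x, y) in seen:
                raise ValueError(f"duplicate overlay cell origin {(x, y)}")
            seen.add((x, y))


def build_overlay(predictions: Sequence[PredictionRecord], tile_size: int = TILE_SIZE) -> OverlayMap:
    """One overlay cell per prediction of a single slide."""
    slide_ids = {p.slide_id for p in predictions}
    if len(slide_ids) > 1:
        raise ValueError(f"predictions span multiple slides: {sorted(slide_ids)}")
    slide_id = slide_ids.pop() if slide_ids else "empty"
    cells = [(p.origin[0], p.origin[1], float(p.score)) for p in predictions]
    return OverlayMap(slide_id=slide_id, tile_size=tile_size, cells=cells)


def probability_color(score: float) -> tuple[int, int, int]:
    """Linear blue (0, 0, 255) -> red (255, 0, 0) map, round-half-up."""
    if not 0.0 <= score <= 1.0:
        raise ValueError(f"score {score} outside [0, 1]")
    red = int(np.floor(255.0 * score + 0.5))
    blue = int(np.floor(255.0 * (1.0 - score) + 0.5))
    return red, 0, blue


def render_overlay(overlay: OverlayMap, base: np.ndarray, opacity: float = 0.4) -> np.ndarray:
    """Alpha-blend cell tints onto the base slide; returns RGBA uint8.

    Pixels outside any cell are untouched (alpha 255, base colour).
    """
    if base.ndim != 3 or base.shape[2] != 3:
        raise ValueError("base image must be HxWx3 RGB")
    if not 0.0 <= opacity <= 1.0:
        raise ValueError("opacity must lie in [0, 1]")
    h, w = base.shape[:2]
    out = np.empty((h, w, 4), dtype=np.uint8)
    out[..., :3] = base
    out[..., 3] = 255
    ts = overlay.tile_size
    for x, y, score in overlay.cells:
        if x + ts > w or y + ts > h:
            raise ValueError(f"cell at {(x, y)} (size {ts}) exceeds base extent {(w, h)}")
        tint = np.array(probability_color(score), dtype=np.float64)
        region = out[y : y + ts, x : x + ts, :3].astype(np.float64)
        blended = (1.0 - opacity) * region + opacity * tint
        out[y : y + ts, x : x + ts, :3] = np.clip(np.rint(blended), 0, 255).astype(np.uint8)
    return out


def export_geojson(overlay: OverlayMap) -> dict:
    """One closed-ring polygon feature per cell, full-resolution pixel coords."""
    ts = overlay.tile_size
    features = []
    for x, y, score in overlay.cells:
        ring = [[x, y], [x + ts, y], [x + ts, y + ts], [x, y + ts], [x, y]]
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Polygon", "coordinates": [ring]},
                "properties": {"prediction": round(float(score), 6), "slide_id": overlay.slide_id},
            }
        )
    return {
        "type": "FeatureCollection",
        "properties": {
            "slide_id": overlay.slide_id,
            "tile_size": ts,
            "coordinate_space": "pixels, origin top-left, y increases downward",
        },
        "features": features,
    }


def read_geojson(doc: Union[dict, str, Path]) -> OverlayMap:
    """Inverse of :func:`export_geojson` (lossless at 6-decimal score precision)."""
    if not isinstance(doc, dict):
        doc = json.loads(Path(doc).read_text())
    props = doc.get("properties", {})
    cells = []
    for feat in doc["features"]:
        ring = feat["geometry"]["coordinates"][0]
        xs = [pt[0] for pt in ring]
        ys = [pt[1] for pt in ring]
        cells.append((min(xs), min(ys), float(feat["properties"]["prediction"])))
    return OverlayMap(
        slide_id=props.get("slide_id", "unknown"),
        tile_size=int(props.get("tile_size", TILE_SIZE)),
        cells=cells,
    )


def write_geojson(overlay: OverlayMap, path: Union[str, Path]) -> None:
    Path(path).write_text(json.dumps(export_geojson(overlay), indent=1))
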