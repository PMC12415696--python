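"""Seeded synthetic H&E-like cohort generator.

Real lymph-node whole-slide images are rarely shareable, so the pipeline is
exercised on synthetic tiles built from a Beer-Lambert stain model: each
pixel's optical density (OD) is a non-negative combination of a hematoxylin
and an eosin stain vector, ``OD = c_H * S_H + c_E * S_E``, and transmitted
intensity is ``I = 255 * 10**(-OD)``.  Nuclei are high-hematoxylin ellipses
on a uniform eosin background.  The two classes mimic the morphological
contrast between reactive lymphoid hyperplasia (many small nuclei) and
large-cell lymphoma (fewer, larger, monomorphic nuclei).

Per-patient staining variation (rotated stain vectors, concentration and
brightness scaling) emulates inter-slide stain inconsistency, the problem
stain normalisation exists to remove.  Everything is deterministic given the
cohort seed: patient and tile random streams are spawned from
``numpy.random.SeedSequence`` keys, so the same arguments always produce
byte-identical images.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterator, Optional, Sequence, Union

import numpy as np
import pandas as pd
from PIL import Image

from .records import (
    DEFAULT_RESOLUTION_MPP,
    MANIFEST_COLUMNS,
    TILE_SIZE,
    TileRecord,
    tile_filename,
)

#: Ruifrok & Johnston's published H&E optical-density vectors, unit-normalised
#: columns (hematoxylin first).  The canonical reference pair for H&E
#: colour deconvolution; also the rendering basis of the synthetic cohort.
RUIFROK_HE = np.array(
    [
        [0.650, 0.072],
        [0.704, 0.990],
        [0.286, 0.105],
    ]
)
RUIFROK_HE = RUIFROK_HE / np.linalg.norm(RUIFROK_HE, axis=0, keepdims=True)

#: Additive Gaussian pixel noise (8-bit scale) applied after rendering.
PIXEL_NOISE_SD = 3.0


@dataclass(frozen=True)
class MorphologyParams:
    """Nuclear morphology of one tile class.

    ``nucleus_density`` is the Poisson mean number of nuclei per 512x512
    tile; OD values are decadic optical densities.
    """

    nucleus_radius_mean: float  # px
    nucleus_radius_sd: float  # px
    nucleus_density: float  # nuclei per 512x512 tile
    hematoxylin_od_peak: float = 0.9
    eosin_od_background: float = 0.25

    def __post_init__(self) -> None:
        if self.nucleus_radius_mean <= 0:
            raise ValueError("nucleus_radius_mean must be > 0")
        if self.nucleus_density < 0:
            raise ValueError("nucleus_density must be >= 0")
        if self.hematoxylin_od_peak < 0 or self.eosin_od_background < 0:
            raise ValueError("optical densities must be >= 0")


#: Default class morphologies: label 0 = RLH-like (small dense nuclei),
#: label 1 = cDLBCL-like (large sparse monomorphic nuclei).
RLH_LIKE = MorphologyParams(nucleus_radius_mean=4.0, nucleus_radius_sd=0.8, nucleus_density=180.0)
DLBCL_LIKE = MorphologyParams(nucleus_radius_mean=9.0, nucleus_radius_sd=1.2, nucleus_density=60.0)


@dataclass(frozen=True)
class StainJitter:
    """Per-patient staining variation.

    ``vector_rotation_sd`` rotates both stain vectors within their OD plane
    by a patient-specific angle drawn from a normal truncated at three
    standard deviations (so the deviation from the canonical pair is bounded
    by ``3 * vector_rotation_sd`` radians by construction).
    """

    vector_rotation_sd: float = 0.05  # radians
    concentration_scale_range: tuple[float, float] = (0.85, 1.15)
    brightness_scale_range: tuple[float, float] = (0.9, 1.1)

    def __post_init__(self) -> None:
        if self.vector_rotation_sd < 0:
            raise ValueError("vector_rotation_sd must be >= 0")
        for name, (lo, hi) in (
            ("concentration_scale_range", self.concentration_scale_range),
            ("brightness_scale_range", self.brightness_scale_range),
        ):
            if not (0 < lo <= hi):
                raise ValueError(f"{name} must be a positive, ordered interval")


NO_JITTER = StainJitter(vector_rotation_sd=0.0, concentration_scale_range=(1.0, 1.0), brightness_scale_range=(1.0, 1.0))


@dataclass(frozen=True)
class PatientStain:
    """Realised staining of one patient: jittered vectors + scalar factors."""

    stain_vectors: np.ndarray  # (3, 2), unit columns
    concentration_scale: float
    brightness_scale: float
    rotation: float  # radians actually applied


@dataclass
class PatientCase:
    patient_id: str
    slide_id: str
    label: int
    n_tiles: int
    morphology: MorphologyParams
    stain: PatientStain
    seed_key: tuple[int, ...]  # SeedSequence spawn key under the cohort seed


@dataclass
class SyntheticCohort:
    patients: list[PatientCase]
    seed: int
    class_params: tuple[MorphologyParams, MorphologyParams]
    jitter: StainJitter

    def __post_init__(self) -> None:
        ids = [p.patient_id for p in self.patients]
        if len(set(ids)) != len(ids):
            raise ValueError("patient ids must be unique")

    @property
    def n_tiles(self) -> int:
        return sum(p.n_tiles for p in self.patients)

    def manifest(self) -> pd.DataFrame:
        """Tile metadata table (tile_path is the conventional file name).

        Carries an extra ``tile_index`` column so rows can be re-rendered
        lazily after capping/splitting.
        """
        rows = []
        for p in self.patients:
            for j in range(p.n_tiles):
                x, y = _tile_grid_origin(j)
                rows.append(
                    {
                        "tile_path": tile_filename(p.slide_id, x, y),
                        "patient_id": p.patient_id,
                        "slide_id": p.slide_id,
                        "x_origin": x,
                        "y_origin": y,
                        "label": p.label,
                        "tile_index": j,
                    }
                )
        return pd.DataFrame(rows, columns=MANIFEST_COLUMNS + ["tile_index"])

    def render_tile(self, patient: PatientCase, index: int, size: int = TILE_SIZE) -> TileRecord:
        """Render tile ``index`` of ``patient`` (deterministic in cohort seed)."""
        if not 0 <= index < patient.n_tiles:
            raise ValueError(f"tile index {index} out of range for {patient.patient_id}")
        rng = _spawn_rng(self.seed, patient.seed_key + (2, index))
        pixels = render_field(patient.morphology, patient.stain, (size, size), rng)
        x, y = _tile_grid_origin(index)
        return TileRecord(
            pixels=pixels,
            slide_id=patient.slide_id,
            patient_id=patient.patient_id,
            origin=(x, y),
            label=patient.label,
        )

    def iter_tiles(self, patient: PatientCase) -> Iterator[TileRecord]:
        for j in range(patient.n_tiles):
            yield self.render_tile(patient, j)

    def patient(self, patient_id: str) -> PatientCase:
        for p in self.patients:
            if p.patient_id == patient_id:
                return p
        raise KeyError(patient_id)


TilesPerPatient = Union[int, tuple[int, int], Callable[[np.random.Generator], int]]


def _spawn_rng(seed: int, key: tuple[int, ...]) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def _tile_grid_origin(index: int, columns: int = 100) -> tuple[int, int]:
    return TILE_SIZE * (index % columns), TILE_SIZE * (index // columns)


def _draw_tile_count(spec: TilesPerPatient, rng: np.random.Generator) -> int:
    if callable(spec):
        n = int(spec(rng))
    elif isinstance(spec, tuple):
        lo, hi = spec
        n = int(rng.integers(lo, hi + 1))
    else:
        n = int(spec)
    if n <= 0:
        raise ValueError(f"tiles-per-patient spec produced non-positive count {n}")
    return n


def jitter_stain(jitter: StainJitter, rng: np.random.Generator, base: np.ndarray = RUIFROK_HE) -> PatientStain:
    """Draw one patient's staining realisation."""
    theta = float(np.clip(rng.normal(0.0, jitter.vector_rotation_sd), -3 * jitter.vector_rotation_sd, 3 * jitter.vector_rotation_sd)) if jitter.vector_rotation_sd > 0 else 0.0
    vectors = rotate_in_stain_plane(base, theta)
    conc = float(rng.uniform(*jitter.concentration_scale_range))
    bright = float(rng.uniform(*jitter.brightness_scale_range))
    return PatientStain(stain_vectors=vectors, concentration_scale=conc, brightness_scale=bright, rotation=theta)


def rotate_in_stain_plane(vectors: np.ndarray, theta: float) -> np.ndarray:
    """Rotate both stain vectors by ``theta`` within the plane they span."""
    u1 = vectors[:, 0] / np.linalg.norm(vectors[:, 0])
    v = vectors[:, 1] - (vectors[:, 1] @ u1) * u1
    u2 = v / np.linalg.norm(v)
    basis = np.stack([u1, u2], axis=1)  # (3, 2)
    coords = basis.T @ vectors  # (2, 2) coordinates in the plane
    c, s = math.cos(theta), math.sin(theta)
    rot = np.array([[c, -s], [s, c]])
    out = basis @ (rot @ coords)
    out = np.clip(out, 0.0, None)
    return out / np.linalg.norm(out, axis=0, keepdims=True)


def render_field(
    morphology: MorphologyParams,
    stain: PatientStain,
    shape: tuple[int, int],
    rng: np.random.Generator,
    noise_sd: float = PIXEL_NOISE_SD,
) -> np.ndarray:
    """Render an RGB image of the given shape under the Beer-Lambert model.

    Nucleus centres follow a stationary Poisson process: they are sampled on
    a margin-expanded canvas so the expected hematoxylin OD per pixel equals
    the closed form ``density * od_peak * mean_ellipse_area / 512**2``
    everywhere, including near the borders.
    """
    h, w = shape
    margin = int(math.ceil(morphology.nucleus_radius_mean + 3 * morphology.nucleus_radius_sd)) + 1
    lam = morphology.nucleus_density * (h + 2 * margin) * (w + 2 * margin) / (TILE_SIZE**2)
    n_nuclei = int(rng.poisson(lam)) if lam > 0 else 0

    c_h = np.zeros(shape, dtype=np.float64)
    for _ in range(n_nuclei):
        cy = rng.uniform(-margin, h + margin)
        cx = rng.uniform(-margin, w + margin)
        radius = max(float(rng.normal(morphology.nucleus_radius_mean, morphology.nucleus_radius_sd)), 0.5)
        ratio = float(rng.uniform(0.7, 1.0))
        angle = float(rng.uniform(0.0, math.pi))
        _paint_ellipse(c_h, cy, cx, radius, radius * ratio, angle, morphology.hematoxylin_od_peak)

    c_h *= stain.concentration_scale
    c_e = morphology.eosin_od_background * stain.concentration_scale
    od = c_h[..., None] * stain.stain_vectors[:, 0] + c_e * stain.stain_vectors[:, 1]
    intensity = 255.0 * np.power(10.0, -od) * stain.brightness_scale
    if noise_sd > 0:
        intensity = intensity + rng.normal(0.0, noise_sd, size=intensity.shape)
    return np.clip(np.rint(intensity), 0, 255).astype(np.uint8)


def _paint_ellipse(canvas: np.ndarray, cy: float, cx: float, a: float, b: float, angle: float, value: float) -> None:
    """Add ``value`` inside an ellipse (overlaps accumulate OD)."""
    h, w = canvas.shape
    r = max(a, b)
    y0, y1 = max(int(cy - r) - 1, 0), min(int(cy + r) + 2, h)
    x0, x1 = max(int(cx - r) - 1, 0), min(int(cx + r) + 2, w)
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dy, dx = yy - cy, xx - cx
    c, s = math.cos(angle), math.sin(angle)
    u = c * dx + s * dy
    v = -s * dx + c * dy
    mask = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    canvas[y0:y1, x0:x1][mask] += value


def expected_mean_od(morphology: MorphologyParams, stain_vectors: np.ndarray = RUIFROK_HE) -> np.ndarray:
    """Closed-form expected per-pixel OD vector of a rendered field.

    The ellipse area has mean ``pi * E[r^2] * E[axis ratio]`` with
    ``E[r^2] = mean^2 + sd^2`` and axis ratio uniform on [0.7, 1.0].
    """
    mean_area = math.pi * (morphology.nucleus_radius_mean**2 + morphology.nucleus_radius_sd**2) * 0.85
    e_ch = morphology.nucleus_density * morphology.hematoxylin_od_peak * mean_area / (TILE_SIZE**2)
    return e_ch * stain_vectors[:, 0] + morphology.eosin_od_background * stain_vectors[:, 1]


def generate_cohort(
    n_patients_per_class: int,
    tiles_per_patient: TilesPerPatient,
    class_params: tuple[MorphologyParams, MorphologyParams] = (RLH_LIKE, DLBCL_LIKE),
    jitter: StainJitter = StainJitter(),
    seed: int = 0,
) -> SyntheticCohort:
    """Build a two-class cohort of patients with per-patient staining.

    Pixels are rendered lazily via :meth:`SyntheticCohort.render_tile`, so
    large cohorts cost nothing until tiles are actually materialised.
    """
    if n_patients_per_class < 1:
        raise ValueError("n_patients_per_class must be >= 1")
    patients: list[PatientCase] = []
    for label in (0, 1):
        for i in range(n_patients_per_class):
            key = (label, i)
            rng = _spawn_rng(seed, key + (0,))
            n_tiles = _draw_tile_count(tiles_per_patient, rng)
            stain = jitter_stain(jitter, _spawn_rng(seed, key + (1,)))
            pid = f"p{label}_{i:03d}"
            patients.append(
                PatientCase(
                    patient_id=pid,
                    slide_id=f"{pid}_s0",
                    label=label,
                    n_tiles=n_tiles,
                    morphology=class_params[label],
                    stain=stain,
                    seed_key=key,
                )
            )
    return SyntheticCohort(patients=patients, seed=seed, class_params=class_params, jitter=jitter)


def generate_slide(
    cohort: SyntheticCohort,
    patient: PatientCase,
    roi: Union[str, dict, np.ndarray] = "full",
    slide_shape: tuple[int, int] = (1536, 1536),
    seed: Optional[int] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Render a slide-scale image plus a binary ROI mask for one patient.

    ``roi`` is ``"full"``, a dict like ``{"kind": "rect", "x":, "y":, "w":, "h":}``
    or ``{"kind": "ellipse", "cx":, "cy":, "rx":, "ry":}``, or a ready 0/255
    mask of the slide shape.  The slide shares the patient's stain
    realisation, so tiles cut from it look like the patient's tiles.
    """
    mask = _build_mask(roi, slide_shape)
    rng = _spawn_rng(seed if seed is not None else cohort.seed, patient.seed_key + (3,))
    slide = render_field(patient.morphology, patient.stain, slide_shape, rng)
    return slide, mask


def _build_mask(roi: Union[str, dict, np.ndarray], shape: tuple[int, int]) -> np.ndarray:
    h, w = shape
    if isinstance(roi, np.ndarray):
        if roi.shape != shape:
            raise ValueError(f"ROI mask shape {roi.shape} does not match slide shape {shape}")
        return np.where(roi > 0, 255, 0).astype(np.uint8)
    mask = np.zeros(shape, dtype=np.uint8)
    if roi == "full":
        mask[:] = 255
        return mask
    if not isinstance(roi, dict):
        raise ValueError(f"unrecognised ROI spec: {roi!r}")
    kind = roi.get("kind")
    if kind == "rect":
        x, y, rw, rh = roi["x"], roi["y"], roi["w"], roi["h"]
        if x < 0 or y < 0 or x + rw > w or y + rh > h:
            raise ValueError("rectangular ROI exceeds the slide canvas")
        mask[y : y + rh, x : x + rw] = 255
    elif kind == "ellipse":
        cx, cy, rx, ry = roi["cx"], roi["cy"], roi["rx"], roi["ry"]
        if cx - rx < 0 or cy - ry < 0 or cx + rx > w or cy + ry > h:
            raise ValueError("elliptical ROI exceeds the slide canvas")
        yy, xx = np.mgrid[0:h, 0:w]
        mask[((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2 <= 1.0] = 255
    else:
        raise ValueError(f"unrecognised ROI kind: {kind!r}")
    return mask


def estimate_mean_nucleus_radius(tile_rgb: np.ndarray, min_area: int = 4) -> float:
    """Estimate mean nucleus radius (px) from a rendered tile.

    Deconvolves the hematoxylin channel with the canonical stain matrix,
    thresholds it, and sizes connected components by equivalent-circle
    radius.  Used to verify that the two classes are morphologically
    separable in pixel space, not just by construction.
    """
    from skimage import measure

    from .stainnorm import rgb_to_od

    od = rgb_to_od(tile_rgb).reshape(-1, 3)
    conc, *_ = np.linalg.lstsq(RUIFROK_HE, od.T, rcond=None)
    c_h = conc[0].reshape(tile_rgb.shape[:2])
    binary = c_h > 0.45
    labels = measure.label(binary)
    radii = [
        math.sqrt(region.area / math.pi)
        for region in measure.regionprops(labels)
        if region.area >= min_area
    ]
    if not radii:
        raise ValueError("no nuclei detected in tile")
    return float(np.mean(radii))


def write_cohort(cohort: SyntheticCohort, directory: Union[str, Path]) -> Path:
    """Materialise every tile as an 8-bit RGB PNG plus a manifest CSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = cohort.manifest()
    for p in cohort.patients:
        for j, tile in enumerate(cohort.iter_tiles(p)):
            name = tile_filename(tile.slide_id, tile.origin[0], tile.origin[1])
            Image.fromarray(tile.pixels).save(directory / name)
    manifest_path = directory / "manifest.csv"
    manifest.to_csv(manifest_path, index=False)
    return manifest_path


def write_mask(mask: np.ndarray, path: Union[str, Path]) -> None:
    """Single-channel 0/255 PNG."""
    Image.fromarray(mask.astype(np.uint8), mode="L").save(path)
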