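"""Statistics-based H&E stain normalisation.

Four classical normalisers, each split into *fit* (learn a target profile)
and *apply* (map a source image onto that profile):

- **Reinhard**: per-channel mean/std transfer in CIELAB.
- **Macenko**: stain vectors from the extreme angles of the foreground OD
  cloud projected on its top-2 singular plane; concentrations rescaled to
  the target's 99th percentiles.
- **Ruifrok**: colour deconvolution against the fixed canonical H&E stain
  matrix; only concentrations are rescaled.
- **Vahadane**: rank-2 sparse non-negative matrix factorisation of the
  foreground OD (multiplicative concentration updates with an L1 penalty,
  projected-gradient dictionary updates, columns renormalised each
  iteration).

All methods share the Beer-Lambert optical-density convention
``OD = -log10((I + 1) / 256)`` (the +1 offset avoids log(0) at I = 0).
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence, Union

import numpy as np
import yaml

from .synthcohort import RUIFROK_HE


class InsufficientTissueError(ValueError):
    """Raised when an image has too few foreground (tissue) pixels to fit."""


# ---------------------------------------------------------------------------
# Optical density conversion


def rgb_to_od(image: np.ndarray) -> np.ndarray:
    """8-bit RGB -> decadic optical density, ``OD = -log10((I + 1) / 256)``."""
    arr = np.asarray(image, dtype=np.float64)
    return -np.log10((arr + 1.0) / 256.0)


def od_to_rgb(od: np.ndarray) -> np.ndarray:
    """Inverse of :func:`rgb_to_od`, clipped to the 8-bit range."""
    intensity = 256.0 * np.power(10.0, -np.asarray(od, dtype=np.float64)) - 1.0
    return np.clip(np.rint(intensity), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# CIELAB conversion (D65, 2-degree observer)
#
# Vectorised float32 with an 8-bit gamma lookup table; numerically matches
# skimage.color.rgb2lab/lab2rgb (verified in the test suite) but several
# times faster, which keeps the Reinhard transfer the cheapest normaliser,
# as it should be.

_SRGB_TO_XYZ = np.array(
    [
        [0.41239080, 0.35758434, 0.18048079],
        [0.21263901, 0.71516868, 0.07219232],
        [0.01933082, 0.11919478, 0.95053215],
    ],
    dtype=np.float32,
)
_XYZ_TO_SRGB = np.linalg.inv(_SRGB_TO_XYZ.astype(np.float64)).astype(np.float32)
_D65_WHITE = np.array([0.95047, 1.0, 1.08883], dtype=np.float32)
_GAMMA_LUT = np.where(
    (lut := np.arange(256) / 255.0) > 0.04045,
    ((lut + 0.055) / 1.055) ** 2.4,
    lut / 12.92,
).astype(np.float32)
del lut


def _lab_f(t: np.ndarray) -> np.ndarray:
    delta3 = (6.0 / 29.0) ** 3
    f = np.cbrt(t)
    low = t <= delta3  # rare in stained-tissue images; patch rather than branch
    if low.any():
        f[low] = t[low] / (3 * (6.0 / 29.0) ** 2) + 4.0 / 29.0
    return f


def _rgb_to_lab(image: np.ndarray) -> np.ndarray:
    linear = _GAMMA_LUT[np.asarray(image, dtype=np.uint8)]
    xyz = linear @ _SRGB_TO_XYZ.T
    f = _lab_f(xyz / _D65_WHITE)
    lab = np.empty_like(f)
    lab[..., 0] = 116.0 * f[..., 1] - 16.0
    lab[..., 1] = 500.0 * (f[..., 0] - f[..., 1])
    lab[..., 2] = 200.0 * (f[..., 1] - f[..., 2])
    return lab


# gamma-encode lookup: 65,536 knots, nearest-neighbour; worst-case error
# (max slope 12.92 x half a knot) is ~0.025 of an 8-bit step, so rounded
# bytes match the exact formula
_ENC_N = 65536
_ENC_KNOTS = np.linspace(0.0, 1.0, _ENC_N)
_ENC_TABLE = (
    np.where(_ENC_KNOTS > 0.0031308, 1.055 * np.power(_ENC_KNOTS, 1.0 / 2.4) - 0.055, 12.92 * _ENC_KNOTS)
    * 255.0
).astype(np.float32)


def _lab_to_rgb(lab: np.ndarray) -> np.ndarray:
    fy = (lab[..., 0] + 16.0) * np.float32(1.0 / 116.0)
    f = np.stack([fy + lab[..., 1] * np.float32(1.0 / 500.0), fy, fy - lab[..., 2] * np.float32(1.0 / 200.0)], axis=-1)
    delta = 6.0 / 29.0
    xyz = f * f * f
    low = f <= delta
    if low.any():
        xyz[low] = 3 * delta**2 * (f[low] - 4.0 / 29.0)
    xyz *= _D65_WHITE
    linear = np.clip(xyz @ _XYZ_TO_SRGB.T, 0.0, 1.0)
    idx = (linear * (_ENC_N - 1) + np.float32(0.5)).astype(np.int32)
    srgb255 = _ENC_TABLE[idx]
    return np.clip(np.rint(srgb255), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# Profiles


@dataclass
class ReinhardProfile:
    """Target CIELAB channel statistics."""

    means: np.ndarray  # (3,) L*, a*, b*
    stds: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=np.float64)
        self.stds = np.asarray(self.stds, dtype=np.float64)
        if np.any(self.stds < 0):
            raise ValueError("channel standard deviations must be >= 0")


@dataclass
class StainMatrixProfile:
    """Fitted stain matrix (unit columns: hematoxylin, eosin) plus the
    target's 99th-percentile concentration per stain."""

    stain_matrix: np.ndarray  # (3, 2)
    max_concentration: np.ndarray  # (2,)
    converged: bool = True

    def __post_init__(self) -> None:
        self.stain_matrix = np.asarray(self.stain_matrix, dtype=np.float64)
        self.max_concentration = np.asarray(self.max_concentration, dtype=np.float64)
        if self.stain_matrix.shape != (3, 2):
            raise ValueError("stain matrix must be 3x2")
        norms = np.linalg.norm(self.stain_matrix, axis=0)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("stain matrix columns must be unit-norm")
        if np.any(self.stain_matrix < -1e-9):
            raise ValueError("stain matrix entries must be non-negative")


# ---------------------------------------------------------------------------
# Reinhard


def fit_reinhard(target: np.ndarray) -> ReinhardProfile:
    if target.size == 0:
        raise ValueError("target image is empty")
    flat = _rgb_to_lab(target).reshape(-1, 3)
    means = flat.mean(axis=0, dtype=np.float64)
    return ReinhardProfile(means=means, stds=np.sqrt(flat.var(axis=0, dtype=np.float64)))


def apply_reinhard(source: np.ndarray, profile: ReinhardProfile) -> np.ndarray:
    """Z-score the source in CIELAB, rescale by target std, shift to target mean.

    A source channel with zero spread is shifted only (no rescale), so
    constant-colour images map onto the target means.
    """
    if source.size == 0:
        raise ValueError("source image is empty")
    lab = _rgb_to_lab(source)
    flat = lab.reshape(-1, 3)
    smean = flat.mean(axis=0, dtype=np.float64)
    sstd = np.sqrt(flat.var(axis=0, dtype=np.float64))
    out = np.empty_like(lab)
    for ch in range(3):
        if sstd[ch] > 1e-6:
            out[..., ch] = (lab[..., ch] - smean[ch]) / sstd[ch] * profile.stds[ch] + profile.means[ch]
        else:
            out[..., ch] = lab[..., ch] - smean[ch] + profile.means[ch]
    return _lab_to_rgb(out)


# ---------------------------------------------------------------------------
# Shared stain-matrix machinery


def _foreground_od(image: np.ndarray, beta: float, min_pixels: int = 100) -> np.ndarray:
    od = rgb_to_od(image).reshape(-1, 3)
    keep = ~np.any(od < beta, axis=1)
    fg = od[keep]
    if fg.shape[0] < min_pixels:
        raise InsufficientTissueError(
            f"insufficient tissue: only {fg.shape[0]} foreground pixels above OD {beta}"
        )
    return fg


def _order_h_before_e(matrix: np.ndarray) -> np.ndarray:
    """Column with the larger first-channel (red) OD is hematoxylin."""
    if matrix[0, 0] >= matrix[0, 1]:
        return matrix
    return matrix[:, ::-1]


def stain_concentrations(image_od: np.ndarray, stain_matrix: np.ndarray) -> np.ndarray:
    """Least-squares pixel concentrations, clipped at zero.  (2, n_pixels)."""
    flat = image_od.reshape(-1, 3)
    conc, *_ = np.linalg.lstsq(stain_matrix, flat.T, rcond=None)
    return np.clip(conc, 0.0, None)


def _max_concentration(conc: np.ndarray, percentile: float) -> np.ndarray:
    return np.percentile(conc, percentile, axis=1)


def _reconstruct(conc: np.ndarray, stain_matrix: np.ndarray, shape: tuple) -> np.ndarray:
    od = (stain_matrix @ conc).T.reshape(shape)
    return od_to_rgb(od)


def _rescale(conc: np.ndarray, source_max: np.ndarray, target_max: np.ndarray) -> np.ndarray:
    scale = np.where(source_max > 1e-8, target_max / np.where(source_max > 1e-8, source_max, 1.0), 1.0)
    return conc * scale[:, None]


# ---------------------------------------------------------------------------
# Macenko


def _extreme_angle_vectors(fg: np.ndarray, alpha: float) -> np.ndarray:
    """Unit vectors at the alpha / (100 - alpha) angle percentiles of the OD
    cloud projected onto its top-2 singular plane (the Macenko geometry)."""
    _, _, vt = np.linalg.svd(fg, full_matrices=False)
    plane = vt[:2].T  # (3, 2)
    for j in range(2):
        if plane[:, j].sum() < 0:
            plane[:, j] = -plane[:, j]
    proj = fg @ plane
    phi = np.arctan2(proj[:, 1], proj[:, 0])
    lo, hi = np.percentile(phi, [alpha, 100.0 - alpha])
    v1 = plane @ np.array([np.cos(lo), np.sin(lo)])
    v2 = plane @ np.array([np.cos(hi), np.sin(hi)])
    matrix = np.stack([v1, v2], axis=1)
    matrix = np.clip(matrix, 0.0, None)
    return matrix / np.linalg.norm(matrix, axis=0, keepdims=True)


def fit_macenko(
    target: np.ndarray,
    beta: float = 0.15,
    alpha: float = 1.0,
    conc_percentile: float = 99.0,
) -> StainMatrixProfile:
    """Stain vectors at the extreme angle percentiles of the OD cloud
    projected onto its top-2 singular plane."""
    fg = _foreground_od(target, beta)
    matrix = _order_h_before_e(_extreme_angle_vectors(fg, alpha))
    conc = stain_concentrations(fg, matrix)
    return StainMatrixProfile(stain_matrix=matrix, max_concentration=_max_concentration(conc, conc_percentile))


def apply_macenko(
    source: np.ndarray,
    profile: StainMatrixProfile,
    beta: float = 0.15,
    alpha: float = 1.0,
    conc_percentile: float = 99.0,
) -> np.ndarray:
    source_profile = fit_macenko(source, beta=beta, alpha=alpha, conc_percentile=conc_percentile)
    od = rgb_to_od(source)
    conc = stain_concentrations(od, source_profile.stain_matrix)
    conc = _rescale(conc, source_profile.max_concentration, profile.max_concentration)
    return _reconstruct(conc, profile.stain_matrix, source.shape)


# ---------------------------------------------------------------------------
# Ruifrok


def fit_ruifrok(target: np.ndarray, conc_percentile: float = 99.0) -> StainMatrixProfile:
    """The stain matrix is always the canonical published H&E pair; the fit
    only records the target's concentration percentiles."""
    od = rgb_to_od(target)
    conc = stain_concentrations(od, RUIFROK_HE)
    return StainMatrixProfile(stain_matrix=RUIFROK_HE.copy(), max_concentration=_max_concentration(conc, conc_percentile))


def apply_ruifrok(source: np.ndarray, profile: StainMatrixProfile, conc_percentile: float = 99.0) -> np.ndarray:
    od = rgb_to_od(source)
    conc = stain_concentrations(od, RUIFROK_HE)
    source_max = _max_concentration(conc, conc_percentile)
    conc = _rescale(conc, source_max, profile.max_concentration)
    return _reconstruct(conc, RUIFROK_HE, source.shape)


# ---------------------------------------------------------------------------
# Vahadane


def fit_vahadane(
    target: np.ndarray,
    sparsity_lambda: float = 0.1,
    n_iter: int = 50,
    seed: int = 0,
    beta: float = 0.15,
    conc_percentile: float = 99.0,
    rel_tol: float = 1e-4,
) -> StainMatrixProfile:
    """Rank-2 sparse NMF of the foreground OD.

    Alternating scheme: multiplicative update of the concentration matrix C
    (with L1 penalty ``sparsity_lambda``), one projected-gradient step on
    the dictionary S (step 1/L with L the spectral norm of C C^T), then
    column renormalisation.  Non-convergence after ``n_iter`` iterations
    returns the best factorisation found with ``converged=False`` and a
    warning, never silently.
    """
    fg = _foreground_od(target, beta)
    x = fg.T  # (3, n)
    # dictionary init: the extreme-angle directions of the OD cloud, lightly
    # perturbed by the seed (random init routinely lands in poor local
    # minima because the beta-masked cloud never touches the stain axes)
    rng = np.random.default_rng(seed)
    s = _extreme_angle_vectors(fg, alpha=1.0)
    s = np.clip(s + rng.normal(0.0, 0.01, size=s.shape), 0.0, None)
    s /= np.linalg.norm(s, axis=0, keepdims=True)
    c = np.clip(np.linalg.lstsq(s, x, rcond=None)[0], 1e-8, None)

    def objective(s_, c_):
        return 0.5 * np.sum((x - s_ @ c_) ** 2) + sparsity_lambda * np.sum(c_)

    prev = objective(s, c)
    converged = False
    for _ in range(n_iter):
        c = c * (s.T @ x) / (s.T @ s @ c + sparsity_lambda + 1e-12)
        grad = (s @ c - x) @ c.T
        lipschitz = np.linalg.norm(c @ c.T, 2) + 1e-12
        s = np.clip(s - grad / lipschitz, 0.0, None)
        norms = np.linalg.norm(s, axis=0, keepdims=True)
        norms[norms < 1e-12] = 1.0
        s /= norms
        c *= norms.reshape(2, 1)  # keep the product S @ C invariant
        cur = objective(s, c)
        if abs(prev - cur) <= rel_tol * max(prev, 1e-12):
            converged = True
            break
        prev = cur

    if not converged:
        warnings.warn(
            f"Vahadane NMF did not converge in {n_iter} iterations; returning best factorisation",
            RuntimeWarning,
            stacklevel=2,
        )
    matrix = _order_h_before_e(s)
    conc = stain_concentrations(fg, matrix)
    return StainMatrixProfile(
        stain_matrix=matrix,
        max_concentration=_max_concentration(conc, conc_percentile),
        converged=converged,
    )


def apply_vahadane(
    source: np.ndarray,
    profile: StainMatrixProfile,
    sparsity_lambda: float = 0.1,
    n_iter: int = 50,
    seed: int = 0,
    beta: float = 0.15,
    conc_percentile: float = 99.0,
) -> np.ndarray:
    source_profile = fit_vahadane(
        source,
        sparsity_lambda=sparsity_lambda,
        n_iter=n_iter,
        seed=seed,
        beta=beta,
        conc_percentile=conc_percentile,
    )
    od = rgb_to_od(source)
    conc = stain_concentrations(od, source_profile.stain_matrix)
    conc = _rescale(conc, source_profile.max_concentration, profile.max_concentration)
    return _reconstruct(conc, profile.stain_matrix, source.shape)


# ---------------------------------------------------------------------------
# Object façade used by the workflow / CLI

Profile = Union[ReinhardProfile, StainMatrixProfile]


class StainNormalizer:
    """fit-then-transform wrapper around one of the four methods."""

    METHODS = ("reinhard", "macenko", "ruifrok", "vahadane")

    def __init__(self, method: str, **params):
        if method not in self.METHODS:
            raise ValueError(f"unknown stain normalisation method {method!r}; choose from {self.METHODS}")
        self.method = method
        self.params = params
        self.profile: Optional[Profile] = None

    def fit(self, target: np.ndarray) -> "StainNormalizer":
        fitters = {
            "reinhard": fit_reinhard,
            "macenko": fit_macenko,
            "ruifrok": fit_ruifrok,
            "vahadane": fit_vahadane,
        }
        self.profile = fitters[self.method](target, **self.params)
        return self

    def transform(self, source: np.ndarray) -> np.ndarray:
        if self.profile is None:
            raise RuntimeError("normalizer must be fitted before transform")
        appliers = {
            "reinhard": apply_reinhard,
            "macenko": apply_macenko,
            "ruifrok": apply_ruifrok,
            "vahadane": apply_vahadane,
        }
        return appliers[self.method](source, self.profile, **self.params)


def get_normalizer(method: str, **params) -> StainNormalizer:
    return StainNormalizer(method, **params)


# ---------------------------------------------------------------------------
# Profile serialisation (YAML, full float precision)


def save_profile(profile: Profile, path: Union[str, Path]) -> None:
    if isinstance(profile, ReinhardProfile):
        doc = {
            "kind": "reinhard",
            "means": [float(v) for v in profile.means],
            "stds": [float(v) for v in profile.stds],
        }
    else:
        doc = {
            "kind": "stain_matrix",
            "stain_matrix": [[float(v) for v in row] for row in profile.stain_matrix],
            "max_concentration": [float(v) for v in profile.max_concentration],
            "converged": bool(profile.converged),
        }
    Path(path).write_text(yaml.safe_dump(doc))


def load_profile(path: Union[str, Path]) -> Profile:
    doc = yaml.safe_load(Path(path).read_text())
    if doc["kind"] == "reinhard":
        return ReinhardProfile(means=np.array(doc["means"]), stds=np.array(doc["stds"]))
    if doc["kind"] == "stain_matrix":
        return StainMatrixProfile(
            stain_matrix=np.array(doc["stain_matrix"]),
            max_concentration=np.array(doc["max_concentration"]),
            converged=doc.get("converged", True),
        )
    raise ValueError(f"unknown profile kind {doc.get('kind')!r} in {path}")


# ---------------------------------------------------------------------------
# Throughput (informational only; hardware-dependent)


def benchmark_throughput(
    normalise: Callable[[np.ndarray], np.ndarray],
    images: Sequence[np.ndarray],
    n_runs: int = 3,
) -> float:
    """Mean images/second over ``n_runs`` timed passes over ``images``."""
    if len(images) < 1:
        raise ValueError("need at least one image")
    rates = []
    for _ in range(n_runs):
        start = time.perf_counter()
        for img in images:
            normalise(img)
        elapsed = time.perf_counter() - start
        rates.append(len(images) / max(elapsed, 1e-12))
    return float(np.mean(rates))
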