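"""Shared fixtures: small synthetic cohorts and Beer-Lambert test images."""

from __future__ import annotations

import numpy as np
import pytest

from hawkshead import synthcohort
from hawkshead.records import TileRecord
from hawkshead.stainnorm import od_to_rgb


@pytest.fixture(scope="session")
def small_cohort():
    """Two classes x 4 patients x 6 tiles, default morphologies, jittered."""
    return synthcohort.generate_cohort(4, 6, seed=11)


@pytest.fixture(scope="session")
def rendered_tiles(small_cohort):
    """One rendered tile per patient of the small cohort."""
    return [small_cohort.render_tile(p, 0) for p in small_cohort.patients]


#: A well-conditioned synthetic stain pair for parameter-recovery tests.
#: Near-pure pixels of either stain keep all three OD channels above the
#: Macenko/Vahadane foreground threshold (the canonical eosin vector's tiny
#: red OD would otherwise exclude its pure pixels from the fit).
BALANCED_PAIR = np.array(
    [
        [0.65, 0.25],
        [0.70, 0.85],
        [0.29, 0.45],
    ]
)
BALANCED_PAIR = BALANCED_PAIR / np.linalg.norm(BALANCED_PAIR, axis=0, keepdims=True)


def beer_lambert_image(
    stain_matrix: np.ndarray,
    shape: tuple[int, int] = (64, 64),
    seed: int = 0,
    max_conc: tuple[float, float] = (1.2, 0.8),
    pure_fraction: float = 0.08,
) -> np.ndarray:
    """RGB image whose OD lies exactly in the span of two stain vectors.

    Most pixels mix both stains; a ``pure_fraction`` share carries one
    stain only (emulating stain-pure tissue regions, the identifiability
    condition stain-separation methods rely on).
    """
    rng = np.random.default_rng(seed)
    h, w = shape
    c_h = rng.uniform(0.0, max_conc[0], size=h * w)
    c_e = rng.uniform(0.0, max_conc[1], size=h * w)
    n_pure = int(pure_fraction * h * w)
    pure_idx = rng.choice(h * w, size=2 * n_pure, replace=False)
    c_e[pure_idx[:n_pure]] = 0.0  # hematoxylin-only pixels
    c_h[pure_idx[:n_pure]] = rng.uniform(0.5 * max_conc[0], max_conc[0], size=n_pure)
    c_h[pure_idx[n_pure:]] = 0.0  # eosin-only pixels
    c_e[pure_idx[n_pure:]] = rng.uniform(0.5 * max_conc[1], max_conc[1], size=n_pure)
    od = np.stack([c_h, c_e]).T @ stain_matrix.T
    return od_to_rgb(od.reshape(h, w, 3))


@pytest.fixture
def bl_image():
    """Beer-Lambert image rendered from the canonical H&E vectors."""
    return beer_lambert_image(synthcohort.RUIFROK_HE, seed=5)


@pytest.fixture
def balanced_image():
    """Beer-Lambert image from the well-conditioned pair: pure pixels of
    both stains survive the foreground OD threshold, so stain separation is
    identifiable."""
    return beer_lambert_image(BALANCED_PAIR, seed=5, max_conc=(1.5, 1.2))


def flat_tiles(n: int, value: int = 200, label: int = 0, size: int = 512) -> list[TileRecord]:
    """Constant-colour tiles, for plumbing tests that ignore content."""
    return [
        TileRecord(
            pixels=np.full((size, size, 3), value, dtype=np.uint8),
            slide_id=f"s{label}",
            patient_id=f"p{label}",
            origin=(512 * i, 0),
            label=label,
        )
        for i in range(n)
    ]
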