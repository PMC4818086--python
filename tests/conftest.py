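"""Shared fixtures: small phantoms and canonical rasterized shapes."""

from __future__ import annotations

import logging

import numpy as np
import pytest

from sama3d.core import ImageStack, LabelVolume
from sama3d.phantom import make_condition_spec, generate_stack, rasterize_ellipsoid

logging.getLogger("sama3d").setLevel(logging.ERROR)

#: scaled-down phantom geometry for fast tests
SMALL = dict(grid_shape=(40, 128, 128), n_structures=8)


@pytest.fixture(scope="session")
def small_c1():
    """One scaled-down reference stack + truth (8 prolate hollow ellipsoids)."""
    return generate_stack(make_condition_spec("C1", **SMALL), seed=5)


@pytest.fixture(scope="session")
def sphere_label() -> LabelVolume:
    """Rasterized solid sphere of radius 10 in a 41^3 grid, label 1."""
    mask = rasterize_ellipsoid((20, 20, 20), (10, 10, 10), None, (41, 41, 41))
    return LabelVolume(mask.astype(np.int32), (1.0, 1.0, 1.0))


@pytest.fixture()
def flat_stack() -> ImageStack:
    return ImageStack(np.full((8, 32, 32), 50.0), (1, 1, 1))


def hollow_ellipsoid_stack(
    semi_axes=(12, 8, 6), fraction=0.5, shape=(33, 33, 33),
    fg=200.0, bg=20.0,
) -> tuple[ImageStack, np.ndarray, np.ndarray]:
    """Clean synthetic stack of one hollow ellipsoid: (stack, shell, cavity)."""
    center = tuple(s // 2 for s in shape)
    outer = rasterize_ellipsoid(center, semi_axes, None, shape)
    cavity = rasterize_ellipsoid(center, tuple(a * fraction for a in semi_axes), None, shape)
    img = np.full(shape, bg, dtype=np.float32)
    img[outer] = fg
    img[cavity] = bg
    return ImageStack(img, (1, 1, 1)), outer & ~cavity, cavity
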