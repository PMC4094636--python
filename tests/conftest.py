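"""Shared fixtures: analytic strip scenes and small synthetic cohorts."""

import numpy as np
import pytest

from rvgeom.synthetic import GroupGenerativeParams, generate_cohort
from rvgeom.types import Point2D, RectangleSeed


def strip_image(
    width: float,
    direction_deg: float = 90.0,
    size: int = 120,
    background: float = 200.0,
    vessel: float = 60.0,
    profile: str = "box",
    center: tuple[float, float] | None = None,
) -> np.ndarray:
    """Analytic render of an infinite dark strip through the image center.

    Box strips use 1-px linear edge coverage so the half-height crossing sits
    exactly at the true half-width; Gaussian strips have FWHM = width.
    """
    cx, cy = center if center is not None else ((size - 1) / 2, (size - 1) / 2)
    a = np.radians(direction_deg)
    nx, ny = -np.sin(a), np.cos(a)
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    dist = np.abs((xx - cx) * nx + (yy - cy) * ny)
    if profile == "box":
        alpha = np.clip(width / 2 + 0.5 - dist, 0.0, 1.0)
    else:
        sigma = width / (2 * np.sqrt(2 * np.log(2)))
        alpha = np.exp(-0.5 * (dist / sigma) ** 2)
    return background + (vessel - background) * alpha


def strip_seed(
    direction_deg: float = 90.0,
    size: int = 120,
    length: float = 20.0,
    initial_width: float = 6.0,
    center: tuple[float, float] | None = None,
) -> RectangleSeed:
    cx, cy = center if center is not None else ((size - 1) / 2, (size - 1) / 2)
    return RectangleSeed(
        center=Point2D(cx, cy), axis_angle=direction_deg,
        length=length, initial_width=initial_width,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Default-parameter cohort at the reference group sizes (seed 7)."""
    return generate_cohort(seed=7)


@pytest.fixture(scope="session")
def null_params():
    return GroupGenerativeParams.null()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
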