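"""Shared fixtures: phantoms are expensive to segment, so the default sphere
phantom and its segmentation are built once per session and reused."""

import numpy as np
import pytest

import cuticlevol as cv

# Noiseless phantoms carry no speckle, and at phantom scale (tens of px)
# genuine pole-cap contours fall under the full-scan 40 px speckle filter,
# so phantom validation runs with the filter off.
PHANTOM_CFG = cv.SegConfig(min_perimeter=0)


@pytest.fixture(scope="session")
def sphere():
    """Default hollow-sphere phantom: (stack, truth)."""
    spec = cv.PhantomSpec()
    return cv.make_hollow_shell_stack(spec)


@pytest.fixture(scope="session")
def sphere_series(sphere):
    """Segmentation of the default sphere phantom (counts series)."""
    stack, _ = sphere
    return cv.segment_stack(stack, PHANTOM_CFG, pixel_size_um=2.44)


@pytest.fixture(scope="session")
def truth_series(sphere):
    """Ground-truth counts of the default sphere as a SliceSeries."""
    _, truth = sphere
    return cv.SliceSeries(
        cuticle_px=truth.cuticle_counts.astype(float),
        body_px=truth.body_counts.astype(float),
    )


@pytest.fixture(scope="session")
def phantom_cfg():
    return PHANTOM_CFG


def make_trapezoid_series(peak=1000.0, step=50.0, plateau=20):
    """Piecewise-linear count profile: ramp up, plateau, ramp down.

    Locally linear everywhere except the two corners, which is the model
    regime in which spike repair is exact.
    """
    up = np.arange(0.0, peak, step)
    flat = np.full(plateau, peak)
    down = np.arange(peak, 0.0, -step)
    body = np.concatenate([up, flat, down])
    return cv.SliceSeries(cuticle_px=0.25 * body, body_px=body)


@pytest.fixture
def trapezoid_series():
    return make_trapezoid_series()
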