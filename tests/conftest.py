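"""Shared fixtures: desk-scale phantom cases and grid helpers."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from dosepaint import PhantomConfig, generate_phantom
from dosepaint.plan_surrogate import SurrogateBeamModel
from dosepaint.volumes import BinaryMask, ScalarVolume


def small_config(**overrides) -> PhantomConfig:
    """A reduced phantom that keeps every anatomical feature but runs fast."""
    base = PhantomConfig(
        grid_shape=(64, 64, 56),
        brain_semi_axes_mm=(30.0, 34.0, 27.0),
        gtv_radius_mm=7.0,
        gtv_centre_offset_mm=(8.0, 6.0, 2.0),
        seed=7,
    )
    return dataclasses.replace(base, **overrides)


@pytest.fixture(scope="session")
def phantom():
    return generate_phantom(small_config())


@pytest.fixture(scope="session")
def phantom_zero_noise():
    return generate_phantom(small_config(noise_sd=0.0))


@pytest.fixture(scope="session")
def fast_beam():
    return SurrogateBeamModel(max_iterations=60, tolerance=1e-5)


def make_volume(values, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0)) -> ScalarVolume:
    return ScalarVolume(values=np.asarray(values, dtype=float), spacing=spacing, origin=origin)


def make_mask(values, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0), label="m") -> BinaryMask:
    return BinaryMask(values=np.asarray(values), spacing=spacing, origin=origin, label=label)


def sphere_mask(radius_mm, spacing=1.0, n=64, label="sphere") -> BinaryMask:
    ax = (np.arange(n) - (n - 1) / 2.0) * spacing
    xx, yy, zz = np.meshgrid(ax, ax, ax, indexing="ij")
    origin = (float(ax[0]),) * 3
    return BinaryMask(
        values=xx**2 + yy**2 + zz**2 <= radius_mm**2,
        spacing=(spacing,) * 3,
        origin=origin,
        label=label,
    )
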