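"""Preprocessing of co-registered parametric maps (ADC, rCBF).

The chain for raw maps is: resample to 1.2 mm isotropic → normalize to a
reference region in contralateral normal brain → edge-preserving bilateral
smoothing → z-score standardization over brain voxels. The chain is
invariant to a global positive rescaling of the raw input because the
reference normalization divides it out.

Inputs are assumed already rigidly co-registered (phantoms are by
construction); registration itself is out of scope.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volumes import BinaryMask, ScalarVolume, assert_same_grid


@dataclass
class ReferenceRegion:
    """Reference voxels in contralateral normal brain used for normalization."""

    mask: BinaryMask
    min_voxels: int = 100

    def __post_init__(self) -> None:
        if self.mask.voxel_count < self.min_voxels:
            raise ValueError(
                f"reference region has {self.mask.voxel_count} voxels, "
                f"fewer than the required {self.min_voxels}"
            )


def resample_isotropic(
    vol: ScalarVolume | BinaryMask, spacing_mm: float, mode: str = "linear"
) -> ScalarVolume | BinaryMask:
    """Resample to an isotropic grid covering the same physical extent.

    ``mode`` is ``linear`` for scalar maps and ``nearest`` for masks.
    The output grid keeps the input origin (voxel-centre convention) and
    spans the input's physical extent.
    """
    if spacing_mm <= 0:
        raise ValueError("target spacing must be positive")
    if mode not in ("linear", "nearest"):
        raise ValueError(f"unknown interpolation mode {mode!r}")

    in_shape = vol.shape
    in_spacing = vol.spacing
    extent = [(n - 1) * s for n, s in zip(in_shape, in_spacing)]
    out_shape = tuple(int(np.floor(e / spacing_mm)) + 1 for e in extent)

    # output voxel centres expressed in input index coordinates
    idx_axes = [
        np.arange(m) * spacing_mm / s for m, s in zip(out_shape, in_spacing)
    ]
    grid = np.meshgrid(*idx_axes, indexing="ij")
    coords = np.stack([g.ravel() for g in grid])

    values = vol.values.astype(float)
    order = 1 if mode == "linear" else 0
    out = ndimage.map_coordinates(values, coords, order=order, mode="nearest")
    out = out.reshape(out_shape)

    spacing = (spacing_mm,) * 3
    if isinstance(vol, BinaryMask):
        return BinaryMask(values=out > 0.5, spacing=spacing, origin=vol.origin, label=vol.label)
    return ScalarVolume(values=out, spacing=spacing, origin=vol.origin)


def normalize_to_reference(vol: ScalarVolume, ref: ReferenceRegion) -> ScalarVolume:
    """Divide by the mean over the reference region (mean over ref becomes 1)."""
    assert_same_grid([vol, ref.mask])
    mean = float(np.nanmean(vol.values[ref.mask.values]))
    if not np.isfinite(mean) or abs(mean) < 1e-9:
        raise ValueError("degenerate reference region: mean is zero or undefined")
    return vol.with_values(vol.values / mean)


def bilateral_smooth(
    vol: ScalarVolume, spatial_sd_mm: float = 2.0, range_sd: float = 0.5,
    truncate: float = 2.5,
) -> ScalarVolume:
    """Edge-preserving bilateral filter.

    Each output voxel is a normalized weighted mean of its neighbours with
    weights Gaussian both in physical distance (``spatial_sd_mm``) and in
    intensity difference (``range_sd``, in the map's current units). NaN
    voxels are ignored as neighbours and left NaN in the output. The kernel
    is truncated at ``truncate`` spatial standard deviations.

    Implemented by vectorized array shifts over the truncated window.
    """
    if spatial_sd_mm <= 0 or range_sd <= 0:
        raise ValueError("spatial_sd_mm and range_sd must be positive")

    values = vol.values.astype(float)
    nan_mask = ~np.isfinite(values)
    centre = np.where(nan_mask, 0.0, values)

    radii = [max(1, int(np.ceil(truncate * spatial_sd_mm / s))) for s in vol.spacing]
    num = np.zeros_like(centre)
    den = np.zeros_like(centre)
    inv2_spatial = 1.0 / (2.0 * spatial_sd_mm**2)
    inv2_range = 1.0 / (2.0 * range_sd**2)

    offsets = itertools.product(*(range(-r, r + 1) for r in radii))
    for off in offsets:
        dist2 = sum((o * s) ** 2 for o, s in zip(off, vol.spacing))
        if dist2 > (truncate * spatial_sd_mm) ** 2:
            continue
        w_spatial = np.exp(-dist2 * inv2_spatial)
        shifted = np.roll(centre, off, axis=(0, 1, 2))
        valid = ~np.roll(nan_mask, off, axis=(0, 1, 2))
        # suppress wrap-around from np.roll at the array edges
        for ax, o in enumerate(off):
            if o > 0:
                sl = [slice(None)] * 3
                sl[ax] = slice(0, o)
                valid[tuple(sl)] = False
            elif o < 0:
                sl = [slice(None)] * 3
                sl[ax] = slice(o, None)
                valid[tuple(sl)] = False
        w = w_spatial * np.exp(-((shifted - centre) ** 2) * inv2_range) * valid
        num += w * shifted
        den += w

    out = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    out[nan_mask] = np.nan
    return vol.with_values(out)


def standardize(vol: ScalarVolume, mask: BinaryMask) -> ScalarVolume:
    """Z-score over the mask (population sd); voxels outside the mask → NaN."""
    assert_same_grid([vol, mask])
    if mask.voxel_count < 2:
        raise ValueError("standardization mask must contain at least 2 voxels")
    sample = vol.values[mask.values]
    if np.any(~np.isfinite(sample)):
        raise ValueError("NaN inside the standardization mask; restrict the mask first")
    mean = float(sample.mean())
    sd = float(sample.std())  # population (÷N) standard deviation
    if sd <= 0:
        raise ValueError("degenerate input: zero variance over the standardization mask")
    out = np.full(vol.shape, np.nan)
    out[mask.values] = (vol.values[mask.values] - mean) / sd
    return vol.with_values(out)


def restrict_to_fov(vol: ScalarVolume, fov: BinaryMask) -> ScalarVolume:
    """NaN out every voxel outside the acquisition field of view."""
    assert_same_grid([vol, fov])
    if fov.voxel_count == 0:
        raise ValueError("FOV mask is empty")
    out = np.where(fov.values, vol.values, np.nan)
    return vol.with_values(out)
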