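"""Synthetic phantom cases for the dose-painting pipeline.

Each phantom emulates a co-registered, 1.2 mm isotropic multiparametric MRI
study of a post-operative glioblastoma patient: a brain ellipsoid inside a
skull shell, two ellipsoidal lateral ventricles labelled CSF, a spherical
GTV (resection cavity plus enhancing rim), simple geometric organs at risk,
and an axial field-of-view slab mimicking the limited coverage of the
perfusion acquisition.

The ground-truth infiltration field decays exponentially with Euclidean
distance from the GTV surface, modulated by a smooth random perturbation so
the resulting dose-painting prescriptions are spatially non-trivial:

    p_true(x) = clamp(exp(−d(x)/λ) · (1 + η(x)), 0, 1)

with λ = 10 mm and η a Gaussian-filtered white-noise field (kernel sd 6 mm,
amplitude 0.15). Standardized ADC and rCBF maps are constructed by
*inverting* the infiltration model: the noiseless linear predictor
L = link⁻¹(p_true) is split between the two maps so that
1.80·ADC = m·(L − 1.64) and 1.43·rCBF = (1 − m)·(L − 1.64) for mixing
fraction m, then independent Gaussian voxel noise is added. With zero noise
the infiltration module therefore recovers p_true exactly, giving an
end-to-end ground truth for every downstream stage.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .infiltration import InfiltrationModelParams, inverse_link
from .structures import MarginConfig, build_structure_set
from .volumes import BinaryMask, ScalarVolume, StructureSet


@dataclass
class PhantomConfig:
    """Geometry, noise and seeding for one phantom case. Distances in mm."""

    grid_shape: tuple[int, int, int] = (96, 96, 96)
    spacing_mm: tuple[float, float, float] = (1.2, 1.2, 1.2)
    brain_semi_axes_mm: tuple[float, float, float] = (45.0, 52.0, 42.0)
    gtv_radius_mm: float = 10.0
    gtv_centre_offset_mm: tuple[float, float, float] = (16.0, 10.0, 4.0)
    infiltration_decay_mm: float = 10.0
    noise_sd: float = 0.1
    mixing_fraction: float = 0.5
    perturbation_sd_mm: float = 6.0
    perturbation_amplitude: float = 0.15
    fov_half_extent_mm: float = 30.0
    margins: MarginConfig = field(default_factory=MarginConfig)
    model: InfiltrationModelParams = field(default_factory=InfiltrationModelParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0.0 <= self.mixing_fraction <= 1.0:
            raise ValueError("mixing_fraction must lie in [0, 1]")
        if self.gtv_radius_mm <= 0:
            raise ValueError("gtv_radius_mm must be positive")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomConfig":
        d = dict(d)
        if isinstance(d.get("margins"), dict):
            d["margins"] = MarginConfig(**d["margins"])
        if isinstance(d.get("model"), dict):
            d["model"] = InfiltrationModelParams(**d["model"])
        for key in ("grid_shape", "spacing_mm", "brain_semi_axes_mm", "gtv_centre_offset_mm"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class PhantomCase:
    """A complete synthetic case: maps, structures, FOV and ground truth."""

    adc: ScalarVolume
    rcbf: ScalarVolume
    structures: StructureSet
    p_true: ScalarVolume
    fov: BinaryMask
    seed: int
    config: PhantomConfig


def _coordinate_grids(config: PhantomConfig):
    """Physical coordinates (mm) of voxel centres, origin at the grid centre."""
    shape = config.grid_shape
    spacing = config.spacing_mm
    axes = [
        (np.arange(n) - (n - 1) / 2.0) * s for n, s in zip(shape, spacing)
    ]
    return np.meshgrid(*axes, indexing="ij")


def _ellipsoid(xx, yy, zz, centre, semi_axes) -> np.ndarray:
    return (
        ((xx - centre[0]) / semi_axes[0]) ** 2
        + ((yy - centre[1]) / semi_axes[1]) ** 2
        + ((zz - centre[2]) / semi_axes[2]) ** 2
    ) <= 1.0


def _sphere(xx, yy, zz, centre, radius) -> np.ndarray:
    return ((xx - centre[0]) ** 2 + (yy - centre[1]) ** 2 + (zz - centre[2]) ** 2) <= radius**2


def _cylinder_z(xx, yy, zz, centre_xy, radius, z_range) -> np.ndarray:
    return (
        ((xx - centre_xy[0]) ** 2 + (yy - centre_xy[1]) ** 2 <= radius**2)
        & (zz >= z_range[0])
        & (zz <= z_range[1])
    )


def _cylinder_y(xx, yy, zz, centre_xz, radius, y_range) -> np.ndarray:
    return (
        ((xx - centre_xz[0]) ** 2 + (zz - centre_xz[1]) ** 2 <= radius**2)
        & (yy >= y_range[0])
        & (yy <= y_range[1])
    )


def generate_phantom(config: PhantomConfig | None = None) -> PhantomCase:
    """Generate one phantom case; bit-identical for identical config + seed."""
    config = config or PhantomConfig()
    rng = np.random.default_rng(config.seed)
    xx, yy, zz = _coordinate_grids(config)
    a = config.brain_semi_axes_mm

    brain_arr = _ellipsoid(xx, yy, zz, (0, 0, 0), a)
    gtv_arr = _sphere(xx, yy, zz, config.gtv_centre_offset_mm, config.gtv_radius_mm)
    if np.any(gtv_arr & ~brain_arr):
        raise ValueError("GTV does not fit inside the brain ellipsoid; adjust the config")
    if not gtv_arr.any():
        raise ValueError("GTV is empty on this grid; increase gtv_radius_mm")

    # lateral ventricles, scaled to the brain and kept clear of the GTV later
    vent_semi = (0.14 * a[0], 0.30 * a[1], 0.18 * a[2])
    csf_arr = _ellipsoid(xx, yy, zz, (-0.28 * a[0], -0.10 * a[1], 0.08 * a[2]), vent_semi)
    csf_arr |= _ellipsoid(xx, yy, zz, (0.28 * a[0], -0.10 * a[1], 0.08 * a[2]), vent_semi)
    csf_arr &= brain_arr
    csf_arr &= ~gtv_arr

    spacing = config.spacing_mm
    origin = tuple(-(n - 1) / 2.0 * s for n, s in zip(config.grid_shape, spacing))

    def mask(arr, label):
        return BinaryMask(values=arr, spacing=spacing, origin=origin, label=label)

    oars = _place_oars(xx, yy, zz, a, gtv_arr)
    structures = build_structure_set(
        gtv=mask(gtv_arr, "GTV"),
        brain=mask(brain_arr, "brain"),
        csf=mask(csf_arr, "CSF"),
        oars={name: mask(arr, name) for name, arr in oars.items()},
        margins=config.margins,
    )

    # ground-truth infiltration: exponential decay from the GTV surface
    dist_mm = ndimage.distance_transform_edt(~gtv_arr, sampling=spacing)
    pert = rng.standard_normal(config.grid_shape)
    sigma_vox = [config.perturbation_sd_mm / s for s in spacing]
    pert = ndimage.gaussian_filter(pert, sigma=sigma_vox)
    sd = pert.std()
    if sd > 0:
        pert = pert / sd * config.perturbation_amplitude
    p_true_arr = np.clip(
        np.exp(-dist_mm / config.infiltration_decay_mm) * (1.0 + pert), 0.0, 1.0
    )
    p_true_arr[gtv_arr] = 1.0
    p_true_arr[csf_arr] = 0.0

    # invert the infiltration model to obtain standardized ADC/rCBF maps
    model = config.model
    predictor = inverse_link(p_true_arr, model.link)
    m = config.mixing_fraction
    adc_arr = m * (predictor - model.intercept) / model.coef_adc
    rcbf_arr = (1.0 - m) * (predictor - model.intercept) / model.coef_rcbf
    if config.noise_sd > 0:
        adc_arr = adc_arr + rng.normal(0.0, config.noise_sd, size=adc_arr.shape)
        rcbf_arr = rcbf_arr + rng.normal(0.0, config.noise_sd, size=rcbf_arr.shape)

    gz = config.gtv_centre_offset_mm[2]
    half = config.gtv_radius_mm + config.fov_half_extent_mm
    fov_arr = (zz >= gz - half) & (zz <= gz + half)

    def vol(arr):
        return ScalarVolume(values=arr, spacing=spacing, origin=origin)

    return PhantomCase(
        adc=vol(adc_arr),
        rcbf=vol(rcbf_arr),
        structures=structures,
        p_true=vol(p_true_arr),
        fov=mask(fov_arr, "FOV"),
        seed=config.seed,
        config=config,
    )


def _place_oars(xx, yy, zz, a, gtv_arr) -> dict[str, np.ndarray]:
    """Disjoint geometric organs at risk in the inferior/anterior brain.

    Positions are scaled to the brain semi-axes; anything overlapping a
    previously placed structure (or the GTV) is trimmed away so the masks
    are pairwise disjoint by construction.
    """
    oars: dict[str, np.ndarray] = {}
    occupied = gtv_arr.copy()

    def add(name, arr):
        arr = arr & ~occupied
        oars[name] = arr
        occupied[:] |= arr

    add("brainstem", _cylinder_z(xx, yy, zz, (0.0, -0.25 * a[1]), 0.16 * a[0],
                                 (-0.95 * a[2], -0.35 * a[2])))
    chiasm = (
        (np.abs(xx) <= 0.12 * a[0])
        & (np.abs(yy - 0.30 * a[1]) <= 0.08 * a[1])
        & (np.abs(zz + 0.30 * a[2]) <= 0.06 * a[2])
    )
    add("chiasm", chiasm)
    for side, sign in (("L", -1.0), ("R", 1.0)):
        add(
            f"optic_nerve_{side}",
            _cylinder_y(xx, yy, zz, (sign * 0.20 * a[0], -0.30 * a[2]), 0.05 * a[0],
                        (0.40 * a[1], 0.75 * a[1])),
        )
        eye_x = sign * 0.30 * a[0]
        add(f"lens_{side}", _sphere(xx, yy, zz, (eye_x, 1.02 * a[1], -0.30 * a[2]), 0.06 * a[0]))
        add(f"retina_{side}", _sphere(xx, yy, zz, (eye_x, 0.90 * a[1], -0.30 * a[2]), 0.08 * a[0]))
    return oars


def derive_subseed(seed: int, case_index: int) -> int:
    """Deterministic per-case sub-seed, independent of generation order."""
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(int(case_index),))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def generate_cohort(
    n: int,
    base_config: PhantomConfig | None = None,
    seed: int = 0,
) -> list[PhantomCase]:
    """Generate ``n`` phantom cases with jittered GTV size and position.

    Per-case jitter: GTV radius ±20%, centre shifted by up to ±6 mm per
    axis, drawn from the case sub-seed so cohorts are reproducible and
    order-independent.
    """
    if n < 1:
        raise ValueError("cohort size must be at least 1")
    base = base_config or PhantomConfig()
    cases = []
    for k in range(n):
        sub = derive_subseed(seed, k)
        jitter_rng = np.random.default_rng(sub)
        radius = base.gtv_radius_mm * (1.0 + jitter_rng.uniform(-0.2, 0.2))
        offset = tuple(
            c + jitter_rng.uniform(-6.0, 6.0) for c in base.gtv_centre_offset_mm
        )
        cfg = dataclasses.replace(
            base, gtv_radius_mm=radius, gtv_centre_offset_mm=offset, seed=sub
        )
        cases.append(generate_phantom(cfg))
    return cases


def save_case(case: PhantomCase, out_dir: str | Path) -> None:
    """Write one case as NIfTI volumes plus a config JSON."""
    from . import imaging_io

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    imaging_io.write_volume(case.adc, out / "adc.nii.gz")
    imaging_io.write_volume(case.rcbf, out / "rcbf.nii.gz")
    imaging_io.write_volume(case.p_true, out / "p_true.nii.gz")
    imaging_io.write_mask(case.fov, out / "fov.nii.gz")
    for name, m in case.structures.masks.items():
        imaging_io.write_mask(m, out / f"{name}.nii.gz")
    cfg = case.config.to_dict()
    (out / "config.json").write_text(json.dumps(cfg, indent=1, default=list))
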