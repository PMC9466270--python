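"""Surrogate dose-plan optimization.

A clinical dose-painting study runs its prescriptions through a commercial
VMAT treatment planning system. This module replaces that machine model
(arcs, MLC sequencing, depth dose, CT densities) with a transparent
fluence-convolution surrogate that preserves the *structure* of the
planning problem: the deliverable dose is a Gaussian point-spread-function
blur of a non-negative latent intensity field, and the field is found by
projected gradient descent on a weighted sum of one-sided quadratic
penalties —

* squared deviation from the prescription inside the PTV (dose-painting
  mode) or from the uniform 60 Gy base dose (standard mode);
* under-dose penalties against the minimum-dose planning targets
  (GTV 76.8 Gy, CTV 61.2 Gy, PTV 60.6 Gy by default);
* an over-dose penalty against the PTV maximum (77.5 Gy);
* organ-at-risk limit penalties (max-dose, plus a mean-dose limit for the
  whole brain);
* a quadratic dose-falloff penalty outside the PTV beyond 10 mm.

The default 5 mm PSF width mirrors the leaf size of the delivery system
the surrogate stands in for. Step halving on objective increase makes the
objective trace non-increasing by construction; ``converged`` is False
(not an error) if the relative-change tolerance is unmet at the iteration
cap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .prescription import DosePrescription
from .volumes import ScalarVolume, StructureSet, assert_same_grid

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class OptimizerTargets:
    """Minimum/maximum planning-dose targets (Gy) used by the optimizer."""

    gtv_min_gy: float = 76.8
    ctv_min_gy: float = 61.2
    ptv_min_gy: float = 60.6
    ptv_max_gy: float = 77.5

    def __post_init__(self) -> None:
        if not (self.ptv_min_gy <= self.ctv_min_gy <= self.gtv_min_gy <= self.ptv_max_gy):
            raise ValueError("targets must satisfy ptv_min <= ctv_min <= gtv_min <= ptv_max")


def default_oar_limits() -> dict[str, tuple[str, float]]:
    """Per-organ dose limits (metric, Gy) following EORTC-style constraints."""
    return {
        "brain": ("Dmean", 45.0),
        "brainstem": ("Dmax", 54.0),
        "chiasm": ("Dmax", 54.0),
        "optic_nerve_L": ("Dmax", 54.0),
        "optic_nerve_R": ("Dmax", 54.0),
        "lens_L": ("Dmax", 10.0),
        "lens_R": ("Dmax", 10.0),
        "retina_L": ("Dmax", 50.0),
        "retina_R": ("Dmax", 50.0),
    }


@dataclass
class ConstraintSet:
    """OAR dose limits plus penalty weights for the objective."""

    limits: dict[str, tuple[str, float]] = field(default_factory=default_oar_limits)
    weight_fit: float = 1.0
    weight_target: float = 10.0
    weight_oar: float = 100.0
    weight_falloff: float = 0.01
    falloff_margin_mm: float = 10.0

    def __post_init__(self) -> None:
        for name, (metric, limit) in self.limits.items():
            if limit <= 0:
                raise ValueError(f"constraint limit for {name} must be positive")
            if metric not in ("Dmax", "Dmean"):
                raise ValueError(f"unknown constraint metric {metric!r} for {name}")


@dataclass
class SurrogateBeamModel:
    """Deliverability model: isotropic Gaussian penumbra + optimizer settings."""

    psf_fwhm_mm: float = 5.0
    max_iterations: int = 300
    step_size: float = 0.2
    tolerance: float = 1e-6

    def __post_init__(self) -> None:
        if self.psf_fwhm_mm < 0:
            raise ValueError("psf_fwhm_mm must be non-negative")


@dataclass
class DosePlan:
    """Deliverable dose (Gy, finite and non-negative everywhere).

    ``latent`` is the non-negative intensity field whose PSF blur is the
    dose; it is kept so smoothness can be audited against the convolution.
    """

    dose: ScalarVolume
    converged: bool
    objective_trace: list[float]
    mode: str = "dose_painting"
    latent: np.ndarray | None = None


def _crop_box(arrays: list[np.ndarray], pad_vox: tuple[int, int, int]) -> tuple[slice, ...]:
    union = np.zeros_like(arrays[0], dtype=bool)
    for a in arrays:
        union |= a
    slices = []
    for ax, pad in enumerate(pad_vox):
        proj = union.any(axis=tuple(i for i in range(3) if i != ax))
        idx = np.where(proj)[0]
        lo = max(0, idx[0] - pad)
        hi = min(union.shape[ax], idx[-1] + 1 + pad)
        slices.append(slice(lo, hi))
    return tuple(slices)


class _Objective:
    """Penalty objective and its gradient with respect to the dose field."""

    def __init__(self, rx_target, regions, constraints, oar_masks, falloff_region):
        self.rx = rx_target  # (mask, target-dose array on mask)
        self.regions = regions  # list of (mask, bound, side) one-sided terms
        self.constraints = constraints
        self.oar_masks = oar_masks  # name -> (mask, metric, limit)
        self.falloff_region = falloff_region

    def value_and_grad(self, dose):
        c = self.constraints
        grad = np.zeros_like(dose)
        rx_mask, rx_vals = self.rx
        diff = dose[rx_mask] - rx_vals
        obj = c.weight_fit * float(np.sum(diff**2))
        grad[rx_mask] += c.weight_fit * 2.0 * diff

        for mask, bound, side in self.regions:
            d = dose[mask]
            viol = np.maximum(0.0, bound - d) if side == "min" else np.maximum(0.0, d - bound)
            obj += c.weight_target * float(np.sum(viol**2))
            sign = -1.0 if side == "min" else 1.0
            grad[mask] += c.weight_target * 2.0 * sign * viol

        for _name, (mask, metric, limit) in self.oar_masks.items():
            d = dose[mask]
            if metric == "Dmax":
                viol = np.maximum(0.0, d - limit)
                obj += c.weight_oar * float(np.sum(viol**2))
                grad[mask] += c.weight_oar * 2.0 * viol
            else:  # Dmean: penalty scaled by region size so it competes with sums
                n = d.size
                excess = max(0.0, float(d.mean()) - limit)
                obj += c.weight_oar * n * excess**2
                if excess > 0:
                    grad[mask] += c.weight_oar * 2.0 * excess

        d = dose[self.falloff_region]
        obj += c.weight_falloff * float(np.sum(d**2))
        grad[self.falloff_region] += c.weight_falloff * 2.0 * d
        return obj, grad

    def value(self, dose):
        obj, _ = self.value_and_grad(dose)
        return obj


def optimize_plan(
    rx: DosePrescription,
    structures: StructureSet,
    targets: OptimizerTargets | None = None,
    constraints: ConstraintSet | None = None,
    beam: SurrogateBeamModel | None = None,
    mode: str = "dose_painting",
) -> DosePlan:
    """Fit a deliverable dose to the prescription by projected gradient descent.

    In ``standard`` mode the fit target is the uniform base dose and the
    GTV/CTV boost minima are replaced by the PTV minimum (a uniform plan
    has no boost targets); the PTV maximum is kept.
    """
    targets = targets or OptimizerTargets()
    constraints = constraints or ConstraintSet()
    beam = beam or SurrogateBeamModel()
    if mode not in ("dose_painting", "standard"):
        raise ValueError(f"unknown mode {mode!r}")
    assert_same_grid([rx.dose, structures.grid_reference()])

    ptv = structures["PTV"].values
    if not ptv.any():
        raise ValueError("PTV is empty")
    gtv = structures["GTV"].values
    ctv = structures["CTV"].values
    spacing = rx.dose.spacing

    rx_full = np.where(np.isfinite(rx.dose.values), rx.dose.values, 0.0)
    if mode == "standard":
        rx_full = np.where(ptv, rx.params.d_min_gy, 0.0)

    # work on a crop box around everything that enters the objective
    oar_arrays = [structures[n].values for n in structures.oar_names]
    pad_mm = 3.0 * beam.psf_fwhm_mm * FWHM_TO_SIGMA + constraints.falloff_margin_mm + 6.0
    pad_vox = tuple(int(np.ceil(pad_mm / s)) for s in spacing)
    box = _crop_box([structures["brain"].values, ptv] + oar_arrays, pad_vox)

    ptv_c, gtv_c, ctv_c = ptv[box], gtv[box], ctv[box]
    rx_c = rx_full[box]

    if mode == "dose_painting":
        region_terms = [
            (gtv_c, targets.gtv_min_gy, "min"),
            (ctv_c, targets.ctv_min_gy, "min"),
            (ptv_c, targets.ptv_min_gy, "min"),
            (ptv_c, targets.ptv_max_gy, "max"),
        ]
    else:
        region_terms = [
            (ptv_c, targets.ptv_min_gy, "min"),
            (ptv_c, targets.ptv_max_gy, "max"),
        ]

    oar_masks = {}
    for name, (metric, limit) in constraints.limits.items():
        if name in structures:
            m = structures[name].values[box]
            if name != "brain":
                m = m & ~ptv_c  # target coverage outranks an overlapping OAR
            if m.any():
                oar_masks[name] = (m, metric, limit)

    dist_to_ptv = ndimage.distance_transform_edt(~ptv_c, sampling=spacing)
    falloff_region = (~ptv_c) & (dist_to_ptv > constraints.falloff_margin_mm)

    objective = _Objective((ptv_c, rx_c[ptv_c]), region_terms, constraints,
                           oar_masks, falloff_region)

    sigma_vox = [beam.psf_fwhm_mm * FWHM_TO_SIGMA / s for s in spacing]

    def blur(x):
        if beam.psf_fwhm_mm == 0:
            return x
        return ndimage.gaussian_filter(x, sigma=sigma_vox, mode="constant")

    latent = rx_c.copy()  # initialized to the prescription, zero outside PTV
    dose = blur(latent)
    obj, grad_dose = objective.value_and_grad(dose)
    trace = [obj]
    step = beam.step_size
    converged = False

    for _ in range(beam.max_iterations):
        grad_latent = blur(grad_dose)  # Gaussian PSF is self-adjoint
        accepted = False
        for _half in range(40):
            cand = np.maximum(latent - step * grad_latent, 0.0)
            cand_dose = blur(cand)
            cand_obj, cand_grad = objective.value_and_grad(cand_dose)
            if cand_obj <= obj:
                accepted = True
                break
            step *= 0.5
        if not accepted:
            converged = True  # no descent direction at any step: stationary
            break
        rel_change = (obj - cand_obj) / max(obj, 1e-12)
        latent, dose, obj, grad_dose = cand, cand_dose, cand_obj, cand_grad
        trace.append(obj)
        step *= 1.25
        if rel_change < beam.tolerance:
            converged = True
            break

    full = np.zeros(rx.dose.shape)
    full[box] = dose
    full_latent = np.zeros(rx.dose.shape)
    full_latent[box] = latent
    plan_vol = ScalarVolume(values=full, spacing=spacing, origin=rx.dose.origin)
    return DosePlan(dose=plan_vol, converged=converged, objective_trace=trace, mode=mode,
                    latent=full_latent)


def check_constraints(
    plan: DosePlan, structures: StructureSet, constraints: ConstraintSet | None = None
) -> pd.DataFrame:
    """Achieved Dmax/Dmean per constrained organ versus its limit.

    One row per constrained structure present in the set, with columns
    (structure, metric, achieved_gy, limit_gy, passed).
    """
    constraints = constraints or ConstraintSet()
    rows = []
    for name, (metric, limit) in constraints.limits.items():
        if name not in structures:
            continue
        d = plan.dose.values[structures[name].values]
        achieved = float(d.max()) if metric == "Dmax" else float(d.mean())
        rows.append(
            {"structure": name, "metric": metric, "achieved_gy": achieved,
             "limit_gy": limit, "passed": achieved < limit}
        )
    return pd.DataFrame(rows, columns=["structure", "metric", "achieved_gy", "limit_gy", "passed"])
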