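"""Voxel-wise tumour-probability mapping from standardized ADC and rCBF.

A biologically validated linear model of glioma infiltration combines the
two standardized maps into a per-voxel probability of tumour presence:

    L_i = 1.64 + 1.80 * ADC_i + 1.43 * rCBF_i

The coefficients come from a logistic-regression fit reported in prior
work and are treated as fixed constants. Because the printed combination
is unbounded while its output is used as a probability, two link functions
are offered: the logistic sigmoid of L (default, matching the logistic
provenance of the coefficients) and a literal clamp of L to [0, 1].

Overrides: every GTV voxel is assigned probability 1 (residual tumour by
definition); every CSF voxel probability 0 (the model was not validated
there). The map is masked to the CTV: NaN outside.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .volumes import BinaryMask, ScalarVolume, StructureSet, assert_same_grid

logger = logging.getLogger(__name__)

LINKS = ("logistic", "clamped-linear")


@dataclass
class InfiltrationModelParams:
    """Fixed coefficients of the infiltration model plus the link choice."""

    intercept: float = 1.64
    coef_adc: float = 1.80
    coef_rcbf: float = 1.43
    link: str = "logistic"

    def __post_init__(self) -> None:
        if not all(np.isfinite([self.intercept, self.coef_adc, self.coef_rcbf])):
            raise ValueError("model coefficients must be finite")
        if self.link not in LINKS:
            raise ValueError(f"link must be one of {LINKS}, got {self.link!r}")


@dataclass
class TumourProbabilityMap:
    """Per-voxel tumour probability in [0,1] within the CTV, NaN outside."""

    values: ScalarVolume
    params: InfiltrationModelParams
    overrides: dict = field(default_factory=dict)


def linear_predictor(adc, rcbf, params: InfiltrationModelParams | None = None):
    """Evaluate intercept + coef_adc*ADC + coef_rcbf*rCBF (elementwise)."""
    params = params or InfiltrationModelParams()
    adc = np.asarray(adc, dtype=float)
    rcbf = np.asarray(rcbf, dtype=float)
    if not (np.all(np.isfinite(adc)) and np.all(np.isfinite(rcbf))):
        raise ValueError("linear predictor requires finite standardized inputs")
    out = params.intercept + params.coef_adc * adc + params.coef_rcbf * rcbf
    return float(out) if out.ndim == 0 else out


def apply_link(predictor: np.ndarray, link: str) -> np.ndarray:
    """Map a linear predictor to [0, 1] via the chosen link."""
    if link == "logistic":
        return 1.0 / (1.0 + np.exp(-predictor))
    if link == "clamped-linear":
        return np.clip(predictor, 0.0, 1.0)
    raise ValueError(f"unknown link {link!r}")


def inverse_link(probability: np.ndarray, link: str, eps: float = 1e-7) -> np.ndarray:
    """Inverse of :func:`apply_link`; probabilities are clipped to (eps, 1-eps)
    for the logistic link so the predictor stays finite."""
    p = np.asarray(probability, dtype=float)
    if link == "logistic":
        p = np.clip(p, eps, 1.0 - eps)
        return np.log(p / (1.0 - p))
    if link == "clamped-linear":
        return p
    raise ValueError(f"unknown link {link!r}")


def tumour_probability_map(
    adc: ScalarVolume,
    rcbf: ScalarVolume,
    structures: StructureSet,
    params: InfiltrationModelParams | None = None,
    fov: BinaryMask | None = None,
) -> TumourProbabilityMap:
    """Build the tumour-probability map on the CTV with GTV/CSF overrides.

    Voxels in the CTV but outside the acquisition field of view carry no
    model output; unless covered by an override they receive probability 0,
    which downstream yields the safe 60 Gy base dose (a warning is logged).
    """
    params = params or InfiltrationModelParams()
    vols = [adc, rcbf, structures.grid_reference()]
    if fov is not None:
        vols.append(fov)
    assert_same_grid(vols)

    ctv = structures["CTV"].values
    gtv = structures["GTV"].values
    csf = structures["CSF"].values
    if not ctv.any():
        raise ValueError("CTV is empty")

    in_fov = fov.values if fov is not None else np.ones_like(ctv, dtype=bool)
    model_region = ctv & in_fov
    if np.any(~np.isfinite(adc.values[model_region])) or np.any(
        ~np.isfinite(rcbf.values[model_region])
    ):
        raise ValueError("NaN in ADC/rCBF inside CTV∩FOV; mask inputs first")

    prob = np.full(adc.shape, np.nan)
    pred = (
        params.intercept
        + params.coef_adc * adc.values[model_region]
        + params.coef_rcbf * rcbf.values[model_region]
    )
    prob[model_region] = apply_link(pred, params.link)

    n_outside_fov = int(np.sum(ctv & ~in_fov & ~gtv & ~(csf & ctv)))
    prob[ctv & ~in_fov] = 0.0
    if n_outside_fov:
        msg = (
            f"{n_outside_fov} CTV voxels outside the FOV assigned probability 0 "
            "(base 60 Gy dose)"
        )
        logger.warning(msg)
        warnings.warn(msg, stacklevel=2)

    # override precedence: GTV→1 first, then CSF→0; GTV∩CSF is empty by
    # structure-set invariant so the order is immaterial but recorded
    prob[gtv] = 1.0
    prob[csf & ctv] = 0.0
    prob[~ctv] = np.nan

    overrides = {
        "gtv_to_one": int(gtv.sum()),
        "csf_to_zero": int((csf & ctv).sum()),
        "outside_fov_to_zero": n_outside_fov,
        "order": ["GTV->1", "CSF->0"],
        "link": params.link,
    }
    return TumourProbabilityMap(values=adc.with_values(prob), params=params, overrides=overrides)
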