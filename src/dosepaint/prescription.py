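"""Dose-painting prescriptions: probability → per-voxel dose and its inverse.

The prescription is a linear map of tumour probability onto total physical
dose, D_i = Dmin + (Dmax − Dmin)·p_i, with Dmin = 60 Gy (standard-of-care
adjuvant dose) and Dmax = 80 Gy (maximum tolerated dose in dose-escalation
trials). The PTV ring outside the CTV receives the uniform base dose.
Fractionation (30 daily fractions) is carried as metadata only: all doses
here are total physical dose.

The inverse prescription Dinv_i = Dmax − D_i exists to drive commercial
optimizers via a pretreated mock plan; the surrogate optimizer in this
package does not need the trick, but the map is provided for fidelity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .infiltration import TumourProbabilityMap
from .volumes import ScalarVolume, StructureSet, assert_same_grid


@dataclass
class PrescriptionParams:
    d_min_gy: float = 60.0
    d_max_gy: float = 80.0
    fractions: int = 30  # metadata only

    def __post_init__(self) -> None:
        if not (0 < self.d_min_gy <= self.d_max_gy):
            raise ValueError("require 0 < d_min_gy <= d_max_gy")


@dataclass
class DosePrescription:
    """Per-voxel prescribed dose (Gy) on the PTV, NaN outside."""

    dose: ScalarVolume
    params: PrescriptionParams
    mode: str = "dose_painting"


def dose_prescription(
    p: TumourProbabilityMap,
    structures: StructureSet,
    params: PrescriptionParams | None = None,
) -> DosePrescription:
    """Linear dose mapping: Dmin + (Dmax − Dmin)·p on the CTV, Dmin on PTV∖CTV."""
    params = params or PrescriptionParams()
    assert_same_grid([p.values, structures.grid_reference()])
    ctv = structures["CTV"].values
    ptv = structures["PTV"].values

    prob = p.values.values
    in_ctv = prob[ctv]
    if np.any(~np.isfinite(in_ctv)) or np.any((in_ctv < 0) | (in_ctv > 1)):
        raise ValueError("tumour probability must lie in [0, 1] on the CTV")

    dose = np.full(prob.shape, np.nan)
    dose[ptv] = params.d_min_gy
    dose[ctv] = params.d_min_gy + (params.d_max_gy - params.d_min_gy) * prob[ctv]
    return DosePrescription(dose=p.values.with_values(dose), params=params, mode="dose_painting")


def inverse_prescription(rx: DosePrescription) -> ScalarVolume:
    """Dinv = Dmax − prescription on the PTV; NaN outside. Involutive."""
    dose = rx.dose.values
    inv = np.where(np.isfinite(dose), rx.params.d_max_gy - dose, np.nan)
    return rx.dose.with_values(inv)


def standard_prescription(
    structures: StructureSet, params: PrescriptionParams | None = None
) -> DosePrescription:
    """Uniform base-dose (60 Gy) prescription over the PTV."""
    params = params or PrescriptionParams()
    ptv = structures["PTV"].values
    if not ptv.any():
        raise ValueError("PTV is empty")
    dose = np.full(ptv.shape, np.nan)
    dose[ptv] = params.d_min_gy
    ref = structures.grid_reference()
    vol = ScalarVolume(values=dose, spacing=ref.spacing, origin=ref.origin)
    return DosePrescription(dose=vol, params=params, mode="standard")
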