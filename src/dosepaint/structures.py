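"""Target-volume construction: metric margin expansion with barrier clipping.

The clinical target volume (CTV) is grown from the gross tumour volume (GTV)
by a 1.5 cm isotropic margin clipped to anatomical boundaries (here the brain
mask), and the planning target volume (PTV) adds a further 0.3 cm set-up
margin that is allowed to extend beyond the brain surface.

Expansion is Euclidean in physical mm (anisotropy-aware distance transform,
voxel-centre convention); a barrier is applied as a post-hoc clip rather
than geodesically, matching common treatment-planning-system behaviour.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import ndimage

from .volumes import BinaryMask, StructureSet, assert_same_grid


@dataclass
class MarginConfig:
    """Margins in mm for GTV→CTV and CTV→PTV expansion."""

    ctv_margin_mm: float = 15.0
    ptv_margin_mm: float = 3.0

    def __post_init__(self) -> None:
        if self.ctv_margin_mm < 0 or self.ptv_margin_mm < 0:
            raise ValueError("margins must be non-negative")


def expand_margin(
    seed_mask: BinaryMask,
    margin_mm: float,
    barrier: BinaryMask | None = None,
) -> BinaryMask:
    """Expand a mask by a Euclidean margin in physical mm.

    Output voxels are those whose distance to the seed mask is at most
    ``margin_mm``, minus any barrier voxels, always unioned with the seed
    itself (so seed ⊆ output even where the barrier overlaps the seed).
    """
    if margin_mm < 0:
        raise ValueError("margin_mm must be non-negative")
    if seed_mask.voxel_count == 0:
        raise ValueError("cannot expand an empty seed mask")
    if barrier is not None:
        assert_same_grid([seed_mask, barrier])

    seed = seed_mask.values
    if margin_mm == 0:
        out = seed.copy()
    else:
        # distance from each background voxel to the nearest seed voxel, in mm
        dist = ndimage.distance_transform_edt(~seed, sampling=seed_mask.spacing)
        out = dist <= margin_mm
    if barrier is not None:
        out &= ~barrier.values
    out |= seed
    return seed_mask.with_values(out)


def build_structure_set(
    gtv: BinaryMask,
    brain: BinaryMask,
    csf: BinaryMask,
    oars: Mapping[str, BinaryMask] | None = None,
    margins: MarginConfig | None = None,
) -> StructureSet:
    """Derive CTV and PTV from the GTV and assemble a structure set.

    CTV = GTV expanded by the CTV margin, clipped to the brain (the brain
    boundary acting as the default anatomical barrier). PTV = CTV expanded
    by the set-up margin, not clipped (set-up uncertainty is physical, not
    anatomical). CSF is made disjoint from the GTV so probability overrides
    are unambiguous.
    """
    margins = margins or MarginConfig()
    assert_same_grid([gtv, brain, csf])
    if np.any(gtv.values & ~brain.values):
        raise ValueError("GTV must be contained in the brain mask")

    outside_brain = brain.with_values(~brain.values, label="outside_brain")
    ctv = expand_margin(gtv, margins.ctv_margin_mm, barrier=outside_brain)
    ctv = ctv.with_values(ctv.values, label="CTV")
    ptv = expand_margin(ctv, margins.ptv_margin_mm)
    ptv = ptv.with_values(ptv.values, label="PTV")

    masks = {
        "GTV": gtv.with_values(gtv.values, label="GTV"),
        "CTV": ctv,
        "PTV": ptv,
        "brain": brain.with_values(brain.values, label="brain"),
        "CSF": csf.with_values(csf.values & ~gtv.values, label="CSF"),
    }
    for name, mask in (oars or {}).items():
        masks[name] = mask.with_values(mask.values, label=name)
    return StructureSet.from_masks(masks)
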