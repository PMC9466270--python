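"""Core in-memory containers: scalar volumes, binary masks, structure sets.

All volumes live on a regular 3-D grid with a fixed internal axis order
(x, y, z). Voxel indices are 0-based and physical coordinates follow the
voxel-centre convention: ``coord = origin + index * spacing`` (mm).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np

AXIS_ORDER = "xyz"

#: required structure names for a complete structure set
REQUIRED_STRUCTURES = ("GTV", "CTV", "PTV", "brain", "CSF")

#: recognised organ-at-risk names
OAR_NAMES = (
    "brainstem",
    "chiasm",
    "optic_nerve_L",
    "optic_nerve_R",
    "lens_L",
    "lens_R",
    "retina_L",
    "retina_R",
)


class GridMismatchError(ValueError):
    """Raised when volumes that must share a grid do not."""


@dataclass
class ScalarVolume:
    """A 3-D scalar field (ADC, rCBF, probability, dose ...) with grid metadata.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Voxel values. NaN is permitted only outside the field of view and
        must be masked before arithmetic.
    spacing : tuple of float
        Per-axis voxel size in mm; strictly positive.
    origin : tuple of float
        Physical coordinate (mm) of the centre of voxel (0, 0, 0).
    """

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_order: str = AXIS_ORDER

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3-D array, got ndim={self.values.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or len(self.origin) != 3:
            raise ValueError("spacing and origin must have length 3")
        if not all(np.isfinite(s) and s > 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def with_values(self, values: np.ndarray) -> "ScalarVolume":
        """Same grid, new values."""
        return replace(self, values=np.asarray(values))

    def copy(self) -> "ScalarVolume":
        return replace(self, values=self.values.copy())


@dataclass
class BinaryMask:
    """A {0,1} field on the same grid as its companion volumes."""

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    label: str = ""
    axis_order: str = AXIS_ORDER

    def __post_init__(self) -> None:
        vals = np.asarray(self.values)
        if vals.ndim != 3:
            raise ValueError(f"expected a 3-D array, got ndim={vals.ndim}")
        # any nonzero encoding collapses to boolean
        self.values = vals.astype(bool) if vals.dtype != bool else vals
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if not all(np.isfinite(s) and s > 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_count(self) -> int:
        return int(self.values.sum())

    @property
    def volume_mm3(self) -> float:
        return self.voxel_count * float(np.prod(self.spacing))

    def equivalent_sphere_radius_mm(self) -> float:
        """Radius of the sphere with the same volume as this mask."""
        return float((3.0 * self.volume_mm3 / (4.0 * np.pi)) ** (1.0 / 3.0))

    def with_values(self, values: np.ndarray, label: str | None = None) -> "BinaryMask":
        return replace(
            self, values=np.asarray(values), label=self.label if label is None else label
        )

    def copy(self) -> "BinaryMask":
        return replace(self, values=self.values.copy())


GridLike = ScalarVolume | BinaryMask


def assert_same_grid(
    volumes: Iterable[GridLike],
    spacing_tol_mm: float = 1e-4,
    origin_tol_mm: float = 1e-3,
) -> None:
    """Check that all volumes share shape, spacing and origin.

    Raises
    ------
    GridMismatchError
        Naming the first offending pair. Spacing tolerance 1e-4 mm,
        origin tolerance 1e-3 mm.
    """
    vols = list(volumes)
    if not vols:
        raise ValueError("empty collection: nothing to compare")
    ref = vols[0]
    for i, v in enumerate(vols[1:], start=1):
        if v.shape != ref.shape:
            raise GridMismatchError(
                f"shape mismatch between item 0 {ref.shape} and item {i} {v.shape}"
            )
        if not np.allclose(v.spacing, ref.spacing, atol=spacing_tol_mm, rtol=0):
            raise GridMismatchError(
                f"spacing mismatch between item 0 {ref.spacing} and item {i} {v.spacing}"
            )
        if not np.allclose(v.origin, ref.origin, atol=origin_tol_mm, rtol=0):
            raise GridMismatchError(
                f"origin mismatch between item 0 {ref.origin} and item {i} {v.origin}"
            )


@dataclass
class StructureSet:
    """Named binary masks on a shared grid.

    Required names: GTV, CTV, PTV, brain, CSF. OARs (brainstem, chiasm,
    optic_nerve_L/R, lens_L/R, retina_L/R) are optional. Construction
    enforces GTV ⊆ CTV ⊆ PTV nesting and CSF ∩ GTV = ∅.
    """

    masks: dict[str, BinaryMask] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.masks:
            assert_same_grid(list(self.masks.values()))
        self._validate()

    def _validate(self) -> None:
        m = self.masks
        missing = [name for name in REQUIRED_STRUCTURES if name not in m]
        if missing:
            raise ValueError(f"structure set missing required masks: {missing}")
        gtv, ctv, ptv = m["GTV"].values, m["CTV"].values, m["PTV"].values
        if np.any(gtv & ~ctv):
            raise ValueError("nesting violated: GTV not contained in CTV")
        if np.any(ctv & ~ptv):
            raise ValueError("nesting violated: CTV not contained in PTV")
        if np.any(m["CSF"].values & gtv):
            raise ValueError("CSF overlaps GTV; resolve overrides before construction")

    def __getitem__(self, name: str) -> BinaryMask:
        return self.masks[name]

    def __contains__(self, name: str) -> bool:
        return name in self.masks

    @property
    def oar_names(self) -> list[str]:
        return [n for n in OAR_NAMES if n in self.masks]

    def grid_reference(self) -> BinaryMask:
        return next(iter(self.masks.values()))

    @classmethod
    def from_masks(cls, masks: Mapping[str, BinaryMask]) -> "StructureSet":
        return cls(masks=dict(masks))
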