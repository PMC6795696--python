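"""NIfTI volume and mask I/O with voxel-grid alignment checks.

All downstream stages assume that every volume and mask of a study lives on
one voxel grid; no resampling or registration is performed. Grid equality is
therefore a hard precondition, verified by :func:`check_alignment`.

Voxel indexing is 0-based ``(x, y, z)`` with ``z`` the axial slice index; the
slice-wise Markov-random-field smoothing relies on this convention.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "Quantity",
    "VoxelGrid",
    "ParameterVolume",
    "MaskVolume",
    "AlignmentReport",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "check_alignment",
]

#: Tolerance (mm) below which two voxel spacings count as equal.
SPACING_TOL_MM = 1e-4


class Quantity:
    """Tags identifying what a :class:`ParameterVolume` stores."""

    ADC = "ADC mm^2/s"          # apparent diffusion coefficient, native units
    FF = "FF %"                 # Dixon fat fraction, percent
    EF = "EF %"                 # fractional enhancement, percent
    SIGNAL = "signal a.u."      # raw scanner signal, arbitrary units
    NORMALIZED = "normalized"   # unitless, rescaled to [0, 1]

    ALL = (ADC, FF, EF, SIGNAL, NORMALIZED)


@dataclass(frozen=True)
class VoxelGrid:
    """Shape, spacing and orientation of a 3-D voxel lattice."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]  # mm per voxel along (x, y, z)
    affine: tuple = None  # 4x4 voxel->world map, row-major nested tuple

    def __post_init__(self):
        if len(self.shape) != 3 or any(int(s) < 1 for s in self.shape):
            raise ValueError(f"grid shape must be a positive triple, got {self.shape}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"voxel spacing must be positive, got {self.spacing}")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        if self.affine is None:
            aff = np.diag([*self.spacing, 1.0])
            object.__setattr__(self, "affine", tuple(map(tuple, aff)))
        else:
            object.__setattr__(self, "affine", tuple(map(tuple, np.asarray(self.affine))))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def affine_array(self) -> np.ndarray:
        return np.asarray(self.affine, dtype=float)

    def matches(self, other: "VoxelGrid", tol: float = SPACING_TOL_MM) -> bool:
        return self.shape == other.shape and all(
            abs(a - b) <= tol for a, b in zip(self.spacing, other.spacing)
        )


@dataclass
class ParameterVolume:
    """A scalar field on a voxel grid with a quantity tag and validity mask.

    ``valid`` marks voxels that carry a usable value; NaN or otherwise
    rejected voxels are masked out rather than imputed.
    """

    grid: VoxelGrid
    values: np.ndarray
    quantity: str
    valid: np.ndarray = None
    name: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        if self.quantity not in Quantity.ALL:
            raise ValueError(f"unknown quantity tag {self.quantity!r}")
        if self.valid is None:
            self.valid = np.isfinite(self.values)
        else:
            self.valid = np.asarray(self.valid, dtype=bool) & np.isfinite(self.values)

    def copy_with(self, **kw) -> "ParameterVolume":
        return dataclasses.replace(self, **kw)


@dataclass
class MaskVolume:
    """Boolean membership volume (whole-tumor VOI or a training ROI)."""

    grid: VoxelGrid
    membership: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.membership = np.asarray(self.membership, dtype=bool)
        if self.membership.shape != self.grid.shape:
            raise ValueError(
                f"mask shape {self.membership.shape} != grid shape {self.grid.shape}"
            )

    @property
    def size(self) -> int:
        return int(self.membership.sum())


@dataclass
class AlignmentReport:
    ok: bool
    mismatches: list = field(default_factory=list)

    def __bool__(self) -> bool:
        return self.ok


def _grid_from_nifti(img) -> VoxelGrid:
    zooms = img.header.get_zooms()[:3]
    return VoxelGrid(shape=tuple(img.shape[:3]), spacing=tuple(float(z) for z in zooms),
                     affine=tuple(map(tuple, np.asarray(img.affine))))


def read_volume(path, expected_quantity: str) -> ParameterVolume:
    """Read a 3-D NIfTI volume and tag it with its physical quantity.

    Fails loudly on non-3-D images or all-NaN payloads rather than silently
    reinterpreting units or shapes.
    """
    path = Path(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    data = np.squeeze(data)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D volume, got shape {data.shape}")
    if not np.isfinite(data).any():
        raise ValueError(f"{path}: volume contains no finite voxel values")
    return ParameterVolume(
        grid=_grid_from_nifti(img),
        values=data.astype(np.float64),
        quantity=expected_quantity,
        name=path.name,
    )


def write_volume(volume: ParameterVolume, path) -> Path:
    """Write a volume as NIfTI-1; invalid voxels are stored as NaN.

    Payload is float32, which round-trips bit-exact for float32-representable
    values.
    """
    path = Path(path)
    data = np.where(volume.valid, volume.values, np.nan).astype(np.float32)
    img = nib.Nifti1Image(data, volume.grid.affine_array)
    img.header.set_zooms(volume.grid.spacing)
    nib.save(img, str(path))
    return path


def read_mask(path, label: str = "") -> MaskVolume:
    """Read a 0/1-valued NIfTI mask."""
    path = Path(path)
    img = nib.load(str(path))
    data = np.squeeze(np.asanyarray(img.dataobj))
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D mask, got shape {data.shape}")
    return MaskVolume(grid=_grid_from_nifti(img), membership=data > 0.5,
                      label=label or path.name)


def write_mask(mask: MaskVolume, path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(mask.membership.astype(np.uint8), mask.grid.affine_array)
    img.header.set_zooms(mask.grid.spacing)
    nib.save(img, str(path))
    return path


def check_alignment(volumes=(), masks=(), tol: float = SPACING_TOL_MM) -> AlignmentReport:
    """Verify that all volumes and masks of a study share one voxel grid.

    Symmetric in argument order; mismatches are reported, not raised, so a
    caller can surface every problem at once.
    """
    items = [(getattr(v, "name", "") or f"volume[{i}]", v.grid)
             for i, v in enumerate(volumes)]
    items += [(m.label or f"mask[{i}]", m.grid) for i, m in enumerate(masks)]
    if len(items) < 2:
        raise ValueError("check_alignment needs at least two inputs")
    ref_name, ref = items[0]
    mismatches = []
    for name, grid in items[1:]:
        if grid.shape != ref.shape:
            mismatches.append(f"{name}: shape {grid.shape} != {ref_name} shape {ref.shape}")
        if any(abs(a - b) > tol for a, b in zip(grid.spacing, ref.spacing)):
            mismatches.append(
                f"{name}: spacing {grid.spacing} != {ref_name} spacing {ref.spacing}"
            )
    return AlignmentReport(ok=not mismatches, mismatches=mismatches)
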