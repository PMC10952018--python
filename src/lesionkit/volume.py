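"""Voxel-grid containers for SUV volumes and segmentation masks.

An :class:`SUVVolume` is a 3D scalar field of standardized uptake values
(SUV, dimensionless) on a regular, possibly anisotropic grid. Voxel centers
sit at ``origin + index * spacing`` (0-based indices, world millimetres).
Binary and labeled masks carry the same geometry so mesh coordinates remain
well-defined downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np

__all__ = ["SUVVolume", "BinaryMask", "LabeledMask", "load_nifti", "save_nifti"]


def _as_spacing(spacing) -> np.ndarray:
    s = np.asarray(spacing, dtype=float)
    if s.shape == ():
        s = np.full(3, float(s))
    if s.shape != (3,):
        raise ValueError(f"spacing must be a scalar or length-3, got shape {s.shape}")
    if not np.all(s > 0):
        raise ValueError(f"spacing must be positive, got {s}")
    return s


def _as_origin(origin) -> np.ndarray:
    o = np.asarray(origin, dtype=float)
    if o.shape != (3,):
        raise ValueError(f"origin must be length-3, got shape {o.shape}")
    return o


@dataclass
class _Grid:
    """Shared geometry: values on a grid with spacing (mm) and origin (mm)."""

    values: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 3 or self.values.size == 0:
            raise ValueError("values must be a non-empty 3D array")
        self.spacing = _as_spacing(self.spacing)
        self.origin = _as_origin(self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def voxel_volume(self) -> float:
        """Volume of one voxel cell in mm^3."""
        return float(np.prod(self.spacing))

    def world_coords(self, indices: np.ndarray) -> np.ndarray:
        """World coordinates (mm) of voxel centers for an (n, 3) index array."""
        return np.asarray(indices, dtype=float) * self.spacing + self.origin

    def same_geometry(self, other: "_Grid") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )


@dataclass
class SUVVolume(_Grid):
    """3D SUV grid. Values must be finite and non-negative."""

    def __post_init__(self):
        super().__post_init__()
        self.values = self.values.astype(float, copy=False)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("SUV values must be finite")
        if np.any(self.values < 0):
            raise ValueError("SUV values must be >= 0")

    @property
    def suvmax(self) -> float:
        return float(self.values.max())

    def translated(self, offset) -> "SUVVolume":
        """Same voxel data with the origin shifted by ``offset`` mm."""
        return replace(self, origin=self.origin + np.asarray(offset, dtype=float))


@dataclass
class BinaryMask(_Grid):
    """Boolean foreground mask sharing the source volume's geometry."""

    def __post_init__(self):
        super().__post_init__()
        self.values = self.values.astype(bool, copy=False)


@dataclass
class LabeledMask(_Grid):
    """Integer label grid: 0 = background, 1..K = lesion components."""

    def __post_init__(self):
        super().__post_init__()
        if not np.issubdtype(self.values.dtype, np.integer):
            self.values = self.values.astype(np.int32)
        if self.values.min() < 0:
            raise ValueError("labels must be non-negative")

    @property
    def n_labels(self) -> int:
        return int(self.values.max())

    @property
    def labels(self) -> list[int]:
        return [int(k) for k in np.unique(self.values) if k > 0]


def _affine(spacing: np.ndarray, origin: np.ndarray) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(spacing)
    aff[:3, 3] = origin
    return aff


def save_nifti(grid: _Grid, path) -> None:
    """Write a volume or mask as NIfTI with spacing/origin in the affine."""
    data = grid.values
    if data.dtype == bool:
        data = data.astype(np.uint8)
    img = nib.Nifti1Image(np.asarray(data), _affine(grid.spacing, grid.origin))
    nib.save(img, str(path))


def load_nifti(path, kind: str = "suv"):
    """Load a NIfTI file as an SUVVolume ('suv'), BinaryMask ('mask') or
    LabeledMask ('labels'). Only diagonal affines (no rotation) are supported."""
    img = nib.load(str(path))
    aff = np.asarray(img.affine)
    rot = aff[:3, :3]
    if not np.allclose(rot, np.diag(np.diag(rot)), atol=1e-6):
        raise ValueError("only axis-aligned (diagonal-affine) NIfTI volumes are supported")
    spacing = np.abs(np.diag(rot))
    origin = aff[:3, 3]
    data = np.asanyarray(img.dataobj)
    cls = {"suv": SUVVolume, "mask": BinaryMask, "labels": LabeledMask}[kind]
    if kind == "mask":
        data = data.astype(bool)
    elif kind == "labels":
        data = np.rint(data).astype(np.int32)
    return cls(values=data, spacing=spacing, origin=origin)
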