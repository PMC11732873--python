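"""Volume and mask data model with NIfTI I/O and strict geometry checking.

The package works on co-registered 3D CT (Hounsfield units) and PET
(body-weight SUV) volumes plus binary masks. All volumes carry voxel
spacing and origin in millimetres; axial slices are indexed along the
*third* array axis (``data[:, :, k]`` is one axial slice), and every
per-slice computation in the package iterates that axis.

Coordinates are voxel-center based: voxel ``(i, j, k)`` sits at
``origin + (i*dx, j*dy, k*dz)`` in world millimetres (0-based indices).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "AXIAL_AXIS",
    "GeometryError",
    "ImageVolume",
    "BinaryMask",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "assert_same_geometry",
]

#: Array axis along which axial slices are stacked.
AXIAL_AXIS = 2

#: Tolerance (mm) for spacing/origin equality between companion volumes.
GEOMETRY_ATOL_MM = 1e-6

VALID_UNITS = ("HU", "SUV", "none")


class GeometryError(ValueError):
    """Raised when two volumes that must share a grid do not."""


@dataclass
class ImageVolume:
    """A 3D scalar image on a regular anisotropic grid.

    Parameters
    ----------
    data
        3D array; axial slices along axis 2.
    spacing
        Voxel spacing ``(dx, dy, dz)`` in mm, all strictly positive.
    origin
        World coordinate (mm) of the center of voxel ``(0, 0, 0)``.
    unit
        Intensity unit tag: ``"HU"``, ``"SUV"`` or ``"none"``.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    unit: str = "none"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(
                f"expected a 3D volume, got {self.data.ndim} dimensions"
            )
        if min(self.data.shape) < 1:
            raise ValueError(f"degenerate volume shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")
        if len(self.origin) != 3:
            raise ValueError(f"origin must have 3 components, got {self.origin}")
        if self.unit not in VALID_UNITS:
            raise ValueError(f"unit must be one of {VALID_UNITS}, got {self.unit!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_slices(self) -> int:
        """Number of axial slices."""
        return self.data.shape[AXIAL_AXIS]

    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in millilitres (1 mL = 1000 mm^3)."""
        dx, dy, dz = self.spacing
        return dx * dy * dz / 1000.0

    def voxel_centers_axis(self, axis: int) -> np.ndarray:
        """World coordinates (mm) of voxel centers along one axis."""
        n = self.data.shape[axis]
        return self.origin[axis] + np.arange(n) * self.spacing[axis]


@dataclass
class BinaryMask:
    """A boolean mask sharing the grid of a companion :class:`ImageVolume`."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(
                f"expected a 3D mask, got {self.data.ndim} dimensions"
            )
        if self.data.dtype != bool:
            vals = np.unique(self.data)
            if not np.isin(vals, (0, 1)).all():
                raise ValueError("mask values must be 0/1 or boolean")
            self.data = self.data.astype(bool)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def count(self) -> int:
        return int(self.data.sum())

    def is_empty(self) -> bool:
        return not self.data.any()

    def voxel_centers_axis(self, axis: int) -> np.ndarray:
        n = self.data.shape[axis]
        return self.origin[axis] + np.arange(n) * self.spacing[axis]


def _affine(spacing, origin) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0])
    aff[:3, 3] = origin
    return aff


def read_volume(path: str | Path, unit: str = "none") -> ImageVolume:
    """Read a NIfTI-1 volume (.nii / .nii.gz).

    Spacing and origin are taken from the header affine; ``unit`` is a
    caller-supplied hint since NIfTI does not carry HU/SUV semantics.
    """
    path = Path(path)
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
    except Exception as exc:  # nibabel raises many exception types
        raise IOError(f"cannot read NIfTI volume {path}: {exc}") from exc
    if data.ndim != 3:
        raise ValueError(
            f"{path}: expected a 3D volume, file has {data.ndim} dimensions"
        )
    aff = img.affine
    spacing = tuple(float(abs(aff[i, i])) for i in range(3))
    origin = tuple(float(aff[i, 3]) for i in range(3))
    return ImageVolume(data=data, spacing=spacing, origin=origin, unit=unit)


def write_volume(vol: ImageVolume, path: str | Path) -> None:
    """Write a volume as NIfTI-1; round-trips exactly through read_volume."""
    path = Path(path)
    if not path.parent.is_dir():
        raise IOError(f"parent directory does not exist: {path.parent}")
    img = nib.Nifti1Image(np.asarray(vol.data), _affine(vol.spacing, vol.origin))
    nib.save(img, str(path))


def read_mask(path: str | Path) -> BinaryMask:
    """Read a 0/1 NIfTI volume as a boolean mask."""
    vol = read_volume(path)
    return BinaryMask(data=vol.data, spacing=vol.spacing, origin=vol.origin)


def write_mask(mask: BinaryMask, path: str | Path) -> None:
    """Write a mask as a 0/1 uint8 NIfTI volume."""
    vol = ImageVolume(
        data=mask.data.astype(np.uint8),
        spacing=mask.spacing,
        origin=mask.origin,
        unit="none",
    )
    write_volume(vol, path)


def assert_same_geometry(a, b) -> None:
    """Check two volumes/masks share shape, spacing and origin.

    Raises :class:`GeometryError` naming the differing field; spacing and
    origin must agree within ``GEOMETRY_ATOL_MM``.
    """
    if a.shape != b.shape:
        raise GeometryError(f"shape mismatch: {a.shape} vs {b.shape}")
    if not np.allclose(a.spacing, b.spacing, atol=GEOMETRY_ATOL_MM, rtol=0):
        raise GeometryError(f"spacing mismatch: {a.spacing} vs {b.spacing}")
    if not np.allclose(a.origin, b.origin, atol=GEOMETRY_ATOL_MM, rtol=0):
        raise GeometryError(f"origin mismatch: {a.origin} vs {b.origin}")
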