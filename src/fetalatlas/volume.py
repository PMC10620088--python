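"""Core image containers and NIfTI-1 I/O.

Axis convention throughout the package: axis 0 runs left→right, axis 1
posterior→anterior, axis 2 inferior→superior.  Spacing is stored per axis in
millimetres; after standardisation it is isotropic (0.6 mm by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["Volume3D", "LabelMap", "read_volume", "write_volume",
           "read_labelmap", "write_labelmap", "DEFAULT_LABELS"]

#: label dictionary used by the phantom generator and volumetry
DEFAULT_LABELS = {0: "background", 1: "brain", 2: "ChP", 3: "CoP", 4: "CB"}


@dataclass
class Volume3D:
    """A 3D scalar intensity grid with voxel-spacing metadata.

    Parameters
    ----------
    values : ndarray, shape (X, Y, Z)
        Scalar intensities; finite.
    spacing_mm : tuple of 3 floats
        Voxel edge length per axis, millimetres.
    origin_mm : tuple of 3 floats
        World coordinate of voxel (0, 0, 0).
    """

    values: np.ndarray
    spacing_mm: tuple[float, float, float] = (0.6, 0.6, 0.6)
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D grid, got shape {self.values.shape}")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be positive, got {self.spacing_mm}")
        self.origin_mm = tuple(float(o) for o in self.origin_mm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def is_isotropic(self) -> bool:
        s = self.spacing_mm
        return abs(s[0] - s[1]) < 1e-9 and abs(s[0] - s[2]) < 1e-9

    def with_values(self, values: np.ndarray) -> "Volume3D":
        """Copy of this volume with new intensities on the same grid."""
        return replace(self, values=np.asarray(values))

    def copy(self) -> "Volume3D":
        return replace(self, values=self.values.copy())


@dataclass
class LabelMap:
    """An integer label volume sharing the Volume3D grid contract."""

    values: np.ndarray
    spacing_mm: tuple[float, float, float] = (0.6, 0.6, 0.6)
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    labels: dict[int, str] = field(default_factory=lambda: dict(DEFAULT_LABELS))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if not np.issubdtype(self.values.dtype, np.integer):
            self.values = np.rint(self.values).astype(np.int16)
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        self.origin_mm = tuple(float(o) for o in self.origin_mm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def mask(self, label_id: int | None = None) -> np.ndarray:
        """Boolean mask of one label, or of all foreground if ``label_id`` is None."""
        if label_id is None:
            return self.values > 0
        return self.values == label_id

    def with_values(self, values: np.ndarray) -> "LabelMap":
        return replace(self, values=np.asarray(values))


def _affine(spacing: tuple[float, ...], origin: tuple[float, ...]) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0])
    aff[:3, 3] = origin
    return aff


def write_volume(vol: Volume3D | LabelMap, path: str | Path) -> Path:
    """Write a volume or label map as NIfTI-1 (.nii or .nii.gz)."""
    path = Path(path)
    data = vol.values
    if isinstance(vol, LabelMap):
        data = data.astype(np.int16)
    else:
        data = data.astype(np.float32)
    img = nib.Nifti1Image(data, _affine(vol.spacing_mm, vol.origin_mm))
    img.header.set_zooms(vol.spacing_mm)
    nib.save(img, str(path))
    return path


def read_volume(path: str | Path) -> Volume3D:
    """Read a NIfTI-1 scalar volume, preserving spacing and origin."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D image, got shape {data.shape}")
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(o) for o in img.affine[:3, 3])
    return Volume3D(np.ascontiguousarray(data, dtype=np.float64), zooms, origin)


def write_labelmap(lab: LabelMap, path: str | Path) -> Path:
    return write_volume(lab, path)


def read_labelmap(path: str | Path,
                  labels: dict[int, str] | None = None) -> LabelMap:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(o) for o in img.affine[:3, 3])
    return LabelMap(np.ascontiguousarray(np.rint(data).astype(np.int16)),
                    zooms, origin, labels or dict(DEFAULT_LABELS))
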