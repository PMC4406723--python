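"""Voxel-grid containers shared across the pipeline.

Two container types cover every gridded quantity in the package: a
:class:`ScalarImage` for real-valued contrasts and a :class:`LabelVolume`
for integer tissue maps.  Both carry physical spacing and origin in
millimetres and use the voxel-centre convention: the centre of voxel
``(i, j, k)`` sits at ``origin + spacing * (i, j, k)`` in world (mm)
coordinates.  NIfTI round-tripping uses a diagonal affine built from
spacing and origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["ScalarImage", "LabelVolume", "voxel_centers"]


def _as_triple(x, dtype=float) -> np.ndarray:
    arr = np.asarray(x, dtype=dtype).reshape(-1)
    if arr.size == 1:
        arr = np.repeat(arr, 3)
    if arr.size != 3:
        raise ValueError(f"expected 3 components, got {arr.size}")
    return arr


@dataclass
class ScalarImage:
    """A 3-D real image with physical spacing/origin in mm.

    ``valid`` optionally marks voxels that carry data (e.g. after
    resampling, out-of-field voxels are invalid and excluded from
    similarity measures).  ``None`` means all voxels are valid.
    """

    values: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    valid: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("ScalarImage values must be 3-D")
        self.spacing = _as_triple(self.spacing)
        self.origin = _as_triple(self.origin)
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("image values must be finite")
        if self.valid is not None:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != self.values.shape:
                raise ValueError("valid mask shape mismatch")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def valid_mask(self) -> np.ndarray:
        if self.valid is None:
            return np.ones(self.shape, dtype=bool)
        return self.valid

    def copy(self) -> "ScalarImage":
        return ScalarImage(
            self.values.copy(),
            self.spacing.copy(),
            self.origin.copy(),
            None if self.valid is None else self.valid.copy(),
        )

    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.spacing)
        aff[:3, 3] = self.origin
        return aff

    def to_nifti(self, path: str | Path) -> None:
        img = nib.Nifti1Image(self.values.astype(np.float32), self.affine())
        nib.save(img, str(path))

    @classmethod
    def from_nifti(cls, path: str | Path) -> "ScalarImage":
        img = nib.load(str(path))
        aff = img.affine
        spacing = np.abs(np.diag(aff)[:3])
        origin = aff[:3, 3]
        return cls(np.asarray(img.dataobj, dtype=float), spacing, origin)


@dataclass
class LabelVolume:
    """A 3-D integer tissue-label grid; 0 is background air."""

    labels: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integer-typed")
        if self.labels.ndim != 3:
            raise ValueError("LabelVolume labels must be 3-D")
        self.spacing = _as_triple(self.spacing)
        self.origin = _as_triple(self.origin)
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def mask(self, label: int) -> np.ndarray:
        return self.labels == label

    def present_labels(self) -> np.ndarray:
        return np.unique(self.labels)

    def copy(self) -> "LabelVolume":
        return LabelVolume(self.labels.copy(), self.spacing.copy(), self.origin.copy())

    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.spacing)
        aff[:3, 3] = self.origin
        return aff

    def to_nifti(self, path: str | Path) -> None:
        dtype = np.uint8 if self.labels.max(initial=0) < 256 else np.uint16
        img = nib.Nifti1Image(self.labels.astype(dtype), self.affine())
        nib.save(img, str(path))

    @classmethod
    def from_nifti(cls, path: str | Path) -> "LabelVolume":
        img = nib.load(str(path))
        aff = img.affine
        spacing = np.abs(np.diag(aff)[:3])
        origin = aff[:3, 3]
        return cls(np.asarray(img.dataobj).astype(np.int32), spacing, origin)


def voxel_centers(shape, spacing, origin) -> np.ndarray:
    """World (mm) coordinates of every voxel centre, shape ``(*shape, 3)``."""
    spacing = _as_triple(spacing)
    origin = _as_triple(origin)
    idx = np.indices(shape, dtype=float)
    return np.stack(
        [origin[a] + spacing[a] * idx[a] for a in range(3)], axis=-1
    )
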