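"""In-memory containers for multi-channel eye volumes and label maps.

Conventions used throughout the package:

* arrays are indexed ``[x, y, z]`` (0-based voxel indices),
* world coordinates are millimetres, ``world = origin + index * spacing``,
* NIfTI I/O goes through nibabel with a diagonal affine, which makes the
  array axis order coincide with the world axis order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

#: canonical tissue codes of the eye label map
LABEL_BACKGROUND = 0
LABEL_SCLERA = 1  # sclera + cornea shell
LABEL_VH = 2  # vitreous humor
LABEL_LENS = 3
LABEL_TUMOR = 4

LABEL_NAMES = {
    LABEL_BACKGROUND: "background",
    LABEL_SCLERA: "sclera",
    LABEL_VH: "vh",
    LABEL_LENS: "lens",
    LABEL_TUMOR: "tumor",
}

CHANNEL_NAMES = ("T1", "T2")


def _affine(spacing: np.ndarray, origin: np.ndarray) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(spacing)
    aff[:3, 3] = origin
    return aff


@dataclass
class MultiChannelVolume:
    """Two co-registered scalar 3D grids ("T1" and "T2") sharing one geometry."""

    channels: dict[str, np.ndarray]
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        shapes = {c: a.shape for c, a in self.channels.items()}
        if len(set(shapes.values())) > 1:
            raise ValueError(f"channel grids differ: {shapes}")
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be positive on every axis")

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.channels.values())).shape

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        return self.origin + np.asarray(idx, dtype=float) * self.spacing

    def world_to_index(self, world: np.ndarray) -> np.ndarray:
        return (np.asarray(world, dtype=float) - self.origin) / self.spacing

    def copy(self) -> "MultiChannelVolume":
        return MultiChannelVolume(
            {c: a.copy() for c, a in self.channels.items()},
            self.spacing.copy(),
            self.origin.copy(),
        )

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        aff = _affine(self.spacing, self.origin)
        for name, arr in self.channels.items():
            img = nib.Nifti1Image(np.asarray(arr, dtype=np.float32), aff)
            nib.save(img, directory / f"{name.lower()}.nii.gz")

    @classmethod
    def load(cls, directory: str | Path, names: tuple[str, ...] = CHANNEL_NAMES) -> "MultiChannelVolume":
        directory = Path(directory)
        channels = {}
        spacing = origin = None
        for name in names:
            img = nib.load(directory / f"{name.lower()}.nii.gz")
            channels[name] = np.asarray(img.dataobj, dtype=np.float64)
            aff = img.affine
            spacing = np.diag(aff)[:3].copy()
            origin = aff[:3, 3].copy()
        return cls(channels, spacing, origin)


@dataclass
class EyeLabelMap:
    """Integer tissue-code grid sharing the geometry of its source volume."""

    data: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def mask(self, code: int) -> np.ndarray:
        return self.data == code

    def copy(self) -> "EyeLabelMap":
        return EyeLabelMap(self.data.copy(), self.spacing.copy(), self.origin.copy())

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        img = nib.Nifti1Image(np.asarray(self.data, dtype=np.int16), _affine(self.spacing, self.origin))
        nib.save(img, path)

    @classmethod
    def load(cls, path: str | Path) -> "EyeLabelMap":
        img = nib.load(path)
        data = np.asarray(img.dataobj).astype(np.int16)
        aff = img.affine
        return cls(data, np.diag(aff)[:3].copy(), aff[:3, 3].copy())


def save_mask_nifti(mask: np.ndarray, spacing: np.ndarray, origin: np.ndarray, path: str | Path) -> None:
    """Write a boolean/probability plane as NIfTI with the package affine."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arr = np.asarray(mask)
    dtype = np.uint8 if arr.dtype == bool else np.float32
    nib.save(nib.Nifti1Image(arr.astype(dtype), _affine(np.asarray(spacing, float), np.asarray(origin, float))), path)
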