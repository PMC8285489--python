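"""Core containers shared across the segmentation pipeline.

Conventions
-----------
Volumes are 3D arrays indexed ``(x, y, z)`` where the anatomical reading is

* axis 0 (``x``): left–right — the mirroring axis for augmentation,
* axis 1 (``y``): anterior–posterior,
* axis 2 (``z``): superior–inferior.

The three orthogonal 2D views used by the multi-view classifier are

* ``axial``:    in-plane axes (0, 1), sliced along axis 2,
* ``coronal``:  in-plane axes (0, 2), sliced along axis 1,
* ``sagittal``: in-plane axes (1, 2), sliced along axis 0.

``voxel_spacing`` is millimetres per voxel along each axis.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property
from pathlib import Path

import nibabel as nib
import numpy as np

#: segmentation class codes, in label-map order
CLASS_NAMES = (
    "background",
    "sclera",
    "vitreous",
    "lens",
    "retinal_detachment",
    "tumor",
)
N_CLASSES = len(CLASS_NAMES)
CLASS_INDEX = {name: i for i, name in enumerate(CLASS_NAMES)}

#: canonical channel (sequence) order wherever sequences are stacked
SEQUENCE_ORDER = ("fiesta", "t2", "t1c")

#: 2D view name -> (in-plane axes, slice axis)
VIEW_AXES = {
    "axial": ((0, 1), 2),
    "coronal": ((0, 2), 1),
    "sagittal": ((1, 2), 0),
}
VIEWS_2D = tuple(VIEW_AXES)


def _affine(spacing: tuple[float, float, float]) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0])
    return aff


@dataclass
class SequenceStack:
    """A subject's co-registered MR sequences on one voxel grid.

    Parameters
    ----------
    volumes
        Mapping from sequence name (e.g. ``"fiesta"``) to a 3D float array.
        All volumes must share shape. Iteration order of channels follows
        :data:`SEQUENCE_ORDER` for known names, then insertion order.
    voxel_spacing
        Millimetres per voxel along each axis.
    """

    volumes: dict[str, np.ndarray]
    voxel_spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        shapes = {v.shape for v in self.volumes.values()}
        if len(shapes) != 1:
            raise ValueError(f"sequence volumes disagree on shape: {shapes}")
        self.voxel_spacing = tuple(float(s) for s in self.voxel_spacing)

    @property
    def sequences(self) -> tuple[str, ...]:
        known = [s for s in SEQUENCE_ORDER if s in self.volumes]
        extra = [s for s in self.volumes if s not in SEQUENCE_ORDER]
        return tuple(known + extra)

    @property
    def ch(self) -> int:
        return len(self.volumes)

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.volumes.values())).shape

    def subset(self, sequences: tuple[str, ...]) -> "SequenceStack":
        """Restrict to the given sequences (order per SEQUENCE_ORDER)."""
        missing = [s for s in sequences if s not in self.volumes]
        if missing:
            raise KeyError(f"stack lacks sequences {missing}")
        return SequenceStack(
            {s: self.volumes[s] for s in sequences}, self.voxel_spacing
        )

    def as_array(self, dtype=np.float32) -> np.ndarray:
        """Channel-first ``(ch, X, Y, Z)`` array in canonical sequence order."""
        return np.stack(
            [self.volumes[s].astype(dtype, copy=False) for s in self.sequences]
        )

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name, vol in self.volumes.items():
            nib.save(
                nib.Nifti1Image(np.asarray(vol, dtype=np.float32), _affine(self.voxel_spacing)),
                directory / f"{name}.nii.gz",
            )

    @classmethod
    def load(cls, paths: dict[str, str | Path]) -> "SequenceStack":
        volumes, spacing = {}, None
        for name, p in paths.items():
            img = nib.load(str(p))
            volumes[name] = np.asarray(img.dataobj, dtype=np.float32)
            spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(volumes, spacing)


@dataclass
class LabelMap:
    """Integer 6-class segmentation sharing the stack's grid."""

    data: np.ndarray
    voxel_spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.min() < 0 or self.data.max() >= N_CLASSES:
            raise ValueError("label values must lie in {0..5}")
        self.voxel_spacing = tuple(float(s) for s in self.voxel_spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_spacing))

    def mask(self, cls: int | str) -> np.ndarray:
        if isinstance(cls, str):
            cls = CLASS_INDEX[cls]
        return self.data == cls

    def class_counts(self) -> np.ndarray:
        return np.bincount(self.data.ravel(), minlength=N_CLASSES)

    def save(self, path: str | Path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        nib.save(
            nib.Nifti1Image(self.data.astype(np.uint8), _affine(self.voxel_spacing)),
            str(path),
        )

    @classmethod
    def load(cls, path: str | Path) -> "LabelMap":
        img = nib.load(str(path))
        return cls(
            np.asarray(img.dataobj).astype(np.uint8),
            tuple(float(z) for z in img.header.get_zooms()[:3]),
        )


@dataclass
class SphereROI:
    """A detected eye sphere and its derived dilated masks.

    The two dilation radii are fixed by the preprocessing protocol: 25 mm for
    the registration/sampling region of interest and 5 mm for the intensity
    normalization support. Masks are Euclidean balls of radius
    ``radius_mm + dilation`` around the detected centre, clipped to the grid.
    """

    center: tuple[int, int, int]
    radius_mm: float
    grid_shape: tuple[int, int, int]
    voxel_spacing: tuple[float, float, float]
    votes: float = 0.0

    REGISTRATION_DILATION_MM = 25.0
    NORMALIZATION_DILATION_MM = 5.0

    @cached_property
    def _distance_mm(self) -> np.ndarray:
        grids = np.ogrid[tuple(slice(0, n) for n in self.grid_shape)]
        d2 = sum(
            ((g - c) * s) ** 2
            for g, c, s in zip(grids, self.center, self.voxel_spacing)
        )
        return np.sqrt(d2)

    def distance_mm(self) -> np.ndarray:
        """Distance (mm) of every voxel centre from the sphere centre."""
        return self._distance_mm

    def mask(self, dilation_mm: float) -> np.ndarray:
        return self._distance_mm <= self.radius_mm + dilation_mm

    @cached_property
    def registration_mask(self) -> np.ndarray:
        return self.mask(self.REGISTRATION_DILATION_MM)

    @cached_property
    def normalization_mask(self) -> np.ndarray:
        return self.mask(self.NORMALIZATION_DILATION_MM)
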