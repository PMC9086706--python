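"""Labeled voxel volumes: grid metadata, invariants, NIfTI round-trip.

Label convention: 0 background, 1 wall, 2 chamber, 3 excluded-wall
(pulmonary-vein ostia / mitral annulus caps).  The chamber must be
non-empty, 6-connected and fully enclosed by wall+excluded-wall: no
chamber voxel may share a face with background.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage

BACKGROUND, WALL, CHAMBER, EXCLUDED = 0, 1, 2, 3
VALID_LABELS = frozenset({BACKGROUND, WALL, CHAMBER, EXCLUDED})

# 6-connectivity (face adjacency) defines all neighbourhood notions here
STRUCT6 = ndimage.generate_binary_structure(3, 1)


class VolumeError(ValueError):
    pass


@dataclass(frozen=True)
class GridSpec:
    """Isotropic voxel lattice: counts per axis, edge length, world origin.

    origin_mm is the world coordinate of the centre of voxel (0,0,0).
    """

    shape: tuple[int, int, int]
    spacing_mm: float
    origin_mm: tuple[float, float, float] = field(default=(0.0, 0.0, 0.0))

    def __post_init__(self):
        if len(self.shape) != 3 or any(int(s) != s or s < 32 for s in self.shape):
            raise VolumeError(f"grid shape must be 3 integers >= 32, got {self.shape}")
        if not (np.isfinite(self.spacing_mm) and self.spacing_mm > 0):
            raise VolumeError(f"spacing must be positive, got {self.spacing_mm}")

    @classmethod
    def centered(cls, shape, spacing_mm: float) -> "GridSpec":
        shape = tuple(int(s) for s in np.broadcast_to(shape, (3,)))
        origin = tuple(-(s - 1) / 2.0 * spacing_mm for s in shape)
        return cls(shape=shape, spacing_mm=spacing_mm, origin_mm=origin)

    def axis_coords(self, axis: int) -> np.ndarray:
        return self.origin_mm[axis] + np.arange(self.shape[axis]) * self.spacing_mm

    def world(self, idx: np.ndarray) -> np.ndarray:
        """World coordinates (mm) of voxel centres for integer indices (N,3)."""
        idx = np.atleast_2d(np.asarray(idx))
        return np.asarray(self.origin_mm) + idx * self.spacing_mm

    @property
    def voxel_volume_ml(self) -> float:
        return self.spacing_mm**3 / 1000.0

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag([self.spacing_mm] * 3 + [1.0])
        aff[:3, 3] = self.origin_mm
        return aff


@dataclass(frozen=True)
class LabeledVolume:
    labels: np.ndarray
    grid: GridSpec

    def __post_init__(self):
        if self.labels.shape != tuple(self.grid.shape):
            raise VolumeError(
                f"label array shape {self.labels.shape} != grid shape {self.grid.shape}"
            )

    def count(self, label: int) -> int:
        return int((self.labels == label).sum())

    def validate(self) -> None:
        """Check label values and the chamber-closure/connectivity invariants."""
        present = np.unique(self.labels)
        bad = sorted(set(int(v) for v in present) - VALID_LABELS)
        if bad:
            raise VolumeError(f"unknown labels present: {bad} (allowed: 0,1,2,3)")
        chamber = self.labels == CHAMBER
        if not chamber.any():
            raise VolumeError("chamber (label 2) is empty")
        _, n_comp = ndimage.label(chamber, structure=STRUCT6)
        if n_comp != 1:
            raise VolumeError(f"chamber is not 6-connected: {n_comp} components")
        # closure: no chamber voxel may have a background 6-neighbour
        near_chamber = ndimage.binary_dilation(chamber, structure=STRUCT6)
        leak = near_chamber & (self.labels == BACKGROUND)
        if leak.any():
            where = np.argwhere(leak)[0]
            raise VolumeError(
                "chamber closure violated: background voxel at "
                f"{tuple(int(i) for i in where)} is 6-adjacent to the chamber"
            )

    def save(self, path) -> None:
        img = nib.Nifti1Image(self.labels.astype(np.uint8), self.grid.affine)
        img.header.set_zooms((self.grid.spacing_mm,) * 3)
        nib.save(img, str(path))


def load_labeled_volume(path, validate: bool = True) -> LabeledVolume:
    """Read a labeled NIfTI volume and enforce the container invariants.

    Violations are reported, never silently repaired.  Anisotropic
    spacing beyond 1% relative tolerance is rejected: the thickness
    engine assumes an isotropic lattice.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if not np.issubdtype(data.dtype, np.integer):
        rounded = np.rint(data)
        if not np.allclose(data, rounded, atol=1e-6):
            raise VolumeError(f"{path}: label data must be integer-valued")
        data = rounded
    data = data.astype(np.uint8)
    zooms = np.asarray(img.header.get_zooms()[:3], dtype=float)
    if np.any(zooms <= 0):
        raise VolumeError(f"{path}: non-positive voxel spacing {zooms}")
    if (zooms.max() - zooms.min()) / zooms.mean() > 0.01:
        raise VolumeError(
            f"{path}: anisotropic spacing {tuple(zooms)} exceeds 1% tolerance; "
            "isotropic volumes are required"
        )
    origin = tuple(float(v) for v in img.affine[:3, 3])
    grid = GridSpec(shape=tuple(int(s) for s in data.shape), spacing_mm=float(zooms.mean()),
                    origin_mm=origin)
    vol = LabeledVolume(labels=data, grid=grid)
    if validate:
        vol.validate()
    return vol
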