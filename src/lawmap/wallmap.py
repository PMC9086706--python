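"""Voxel wall-mapping: boundaries, shortest-distance thickness, indices.

The five-step workflow on a labeled volume: (1) the delineated LA
arrives as labels, (2) the inner boundary is the chamber-adjacent wall
shell, (3) the outer boundary is the wall-adjacent background shell,
(4) wall mass/volume is voxel integration, (5) the thickness map is
exported as a point cloud and a triangulated surface.

Thickness at an inner-shell wall voxel p is decomposed as

    t(p) = d_ch(p) + d_bg(p) - h

where d_ch/d_bg are exact Euclidean distances from the centre of p to
the nearest chamber/background voxel centre and h is the voxel edge.
This decomposition returns exactly k*h for a k-voxel slab (no half-voxel
bias).  Samples 6-adjacent to excluded-wall voxels (PV ostia, annulus)
are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull

from .volume import (
    BACKGROUND,
    CHAMBER,
    EXCLUDED,
    STRUCT6,
    WALL,
    GridSpec,
    LabeledVolume,
    VolumeError,
    load_labeled_volume,  # re-exported: reading is part of this module's surface
)

__all__ = [
    "load_labeled_volume",
    "Boundaries",
    "ThicknessMap",
    "WallIndices",
    "extract_boundaries",
    "compute_thickness_map",
    "compute_indices",
    "export_projection_map",
]


class WallMapError(ValueError):
    pass


@dataclass(frozen=True)
class Boundaries:
    """Voxel index sets (N,3) with matching world coordinates (mm)."""

    inner_shell_idx: np.ndarray
    inner_shell_mm: np.ndarray
    outer_boundary_idx: np.ndarray
    outer_boundary_mm: np.ndarray
    chamber_face_idx: np.ndarray
    chamber_face_mm: np.ndarray


@dataclass(frozen=True)
class ThicknessMap:
    """Per-inner-shell-sample wall thickness."""

    voxel_indices: np.ndarray  # (N,3) int
    positions_mm: np.ndarray  # (N,3)
    thickness_mm: np.ndarray  # (N,)
    excluded_count: int
    spacing_mm: float

    def __len__(self) -> int:
        return len(self.thickness_mm)


@dataclass(frozen=True)
class WallIndices:
    lav_ml: float
    lavi_ml_m2: float
    lawv_ml: float
    lawt_mm: float
    lawt_sd_mm: float
    n_samples: int
    excluded_count: int

    def to_dict(self) -> dict:
        return {
            "lav_ml": self.lav_ml,
            "lavi_ml_m2": self.lavi_ml_m2,
            "lawv_ml": self.lawv_ml,
            "lawt_mm": self.lawt_mm,
            "lawt_sd_mm": self.lawt_sd_mm,
            "n_samples": self.n_samples,
            "excluded_count": self.excluded_count,
        }


def _dilate(mask: np.ndarray) -> np.ndarray:
    return ndimage.binary_dilation(mask, structure=STRUCT6)


def extract_boundaries(vol: LabeledVolume) -> Boundaries:
    """Inner shell (wall voxels facing chamber), outer boundary (background
    voxels facing wall) and chamber face (chamber voxels facing wall)."""
    lab = vol.labels
    wall = lab == WALL
    if not wall.any():
        raise WallMapError("wall (label 1) is empty")
    chamber = lab == CHAMBER
    background = lab == BACKGROUND
    inner = wall & _dilate(chamber)
    outer = background & _dilate(wall)
    cface = chamber & _dilate(wall)
    g = vol.grid
    ii, oo, cc = (np.argwhere(m) for m in (inner, outer, cface))
    return Boundaries(
        inner_shell_idx=ii,
        inner_shell_mm=g.world(ii),
        outer_boundary_idx=oo,
        outer_boundary_mm=g.world(oo),
        chamber_face_idx=cc,
        chamber_face_mm=g.world(cc),
    )


def _crop_slices(lab: np.ndarray) -> tuple[slice, slice, slice]:
    """Bounding box of non-background voxels padded by one layer.

    Distances computed on this crop equal full-lattice distances for
    every interior voxel: any background voxel outside the crop clamps
    coordinate-wise onto the all-background pad shell without increasing
    its distance to the query voxel.
    """
    nz = np.argwhere(lab != BACKGROUND)
    if len(nz) == 0:
        raise WallMapError("volume contains no labeled voxels")
    lo = np.maximum(nz.min(axis=0) - 1, 0)
    hi = np.minimum(nz.max(axis=0) + 2, lab.shape)
    return tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))


def compute_thickness_map(vol: LabeledVolume) -> ThicknessMap:
    """Shortest-distance wall thickness at every eligible inner-shell voxel.

    Both distance fields are exact Euclidean distance transforms; samples
    adjacent to excluded-wall voxels are skipped and counted.
    """
    lab = vol.labels
    h = vol.grid.spacing_mm
    sl = _crop_slices(lab)
    sub = lab[sl]
    wall = sub == WALL
    if not wall.any():
        raise WallMapError("wall (label 1) is empty")
    chamber = sub == CHAMBER
    inner = wall & _dilate(chamber)
    if not inner.any():
        raise WallMapError("no wall voxel is 6-adjacent to the chamber")
    near_excluded = _dilate(sub == EXCLUDED)
    eligible = inner & ~near_excluded
    excluded_count = int(inner.sum() - eligible.sum())
    if not eligible.any():
        raise WallMapError(
            "no eligible thickness samples: every inner-shell voxel is adjacent "
            "to excluded wall"
        )
    d_ch = ndimage.distance_transform_edt(sub != CHAMBER, sampling=h)
    d_bg = ndimage.distance_transform_edt(sub != BACKGROUND, sampling=h)
    idx_sub = np.argwhere(eligible)
    thickness = d_ch[tuple(idx_sub.T)] + d_bg[tuple(idx_sub.T)] - h
    offset = np.array([s.start for s in sl])
    idx = idx_sub + offset
    return ThicknessMap(
        voxel_indices=idx,
        positions_mm=vol.grid.world(idx),
        thickness_mm=thickness,
        excluded_count=excluded_count,
        spacing_mm=h,
    )


def compute_indices(
    vol: LabeledVolume, bsa_m2: float, tmap: ThicknessMap | None = None
) -> WallIndices:
    """The four MDCT wall indices plus BSA-indexed chamber volume.

    LAV integrates chamber voxels; LAWV integrates wall voxels (excluded
    wall is not counted); LAWT / LAWT(SD) are the mean and population SD
    of the thickness samples.
    """
    if not (np.isfinite(bsa_m2) and bsa_m2 > 0):
        raise WallMapError(f"BSA must be positive, got {bsa_m2}")
    if tmap is None:
        tmap = compute_thickness_map(vol)
    vox_ml = vol.grid.voxel_volume_ml
    lav = vol.count(CHAMBER) * vox_ml
    lawv = vol.count(WALL) * vox_ml
    t = tmap.thickness_mm
    return WallIndices(
        lav_ml=lav,
        lavi_ml_m2=lav / bsa_m2,
        lawv_ml=lawv,
        lawt_mm=float(t.mean()),
        lawt_sd_mm=float(t.std(ddof=0)),
        n_samples=len(t),
        excluded_count=tmap.excluded_count,
    )


def export_projection_map(tmap: ThicknessMap, out_prefix) -> dict:
    """Write the 3D projection map: CSV point cloud + PLY surface.

    The CSV has one record per thickness sample (x_mm, y_mm, z_mm,
    thickness_mm).  The PLY carries every sample as a vertex with a
    per-vertex `thickness` scalar, triangulated by the convex hull of
    the sample cloud (phantom chambers are convex).
    """
    if len(tmap) == 0:
        raise WallMapError("empty thickness map: nothing to export")
    import pandas as pd

    out_prefix = str(out_prefix)
    csv_path = out_prefix + ".csv"
    ply_path = out_prefix + ".ply"
    df = pd.DataFrame(
        {
            "x_mm": tmap.positions_mm[:, 0],
            "y_mm": tmap.positions_mm[:, 1],
            "z_mm": tmap.positions_mm[:, 2],
            "thickness_mm": tmap.thickness_mm,
        }
    )
    df.to_csv(csv_path, index=False)

    hull = ConvexHull(tmap.positions_mm)
    faces = hull.simplices
    with open(ply_path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {len(tmap)}\n")
        fh.write("property float x\nproperty float y\nproperty float z\n")
        fh.write("property float thickness\n")
        fh.write(f"element face {len(faces)}\n")
        fh.write("property list uchar int vertex_indices\nend_header\n")
        for p, t in zip(tmap.positions_mm, tmap.thickness_mm):
            fh.write(f"{p[0]:.4f} {p[1]:.4f} {p[2]:.4f} {t:.4f}\n")
        for f in faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")
    return {"csv": csv_path, "ply": ply_path, "n_records": len(tmap)}
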