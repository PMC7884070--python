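"""Spherical regions of interest on a voxel grid.

ROIs are spheres specified by an MNI-millimeter center and radius; a
``VoxelMask`` is the set of voxels whose centers fall inside the sphere.
The six default ROIs are theory-of-mind network peaks (bilateral
temporoparietal junction and superior temporal sulcus, medial prefrontal
cortex, precuneus) with a 10 mm radius.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RoiSpec:
    name: str
    center_mm: tuple[float, float, float]
    radius_mm: float = 10.0

    def __post_init__(self):
        if self.radius_mm <= 0:
            raise ValueError("radius_mm must be positive")


#: Theory-of-mind network peaks (meta-analytic), 10-mm spheres.
DEFAULT_ROIS: tuple[RoiSpec, ...] = (
    RoiSpec("L_TPJ", (-52.0, -56.0, 24.0)),
    RoiSpec("R_TPJ", (55.0, -53.0, 24.0)),
    RoiSpec("L_STS", (-59.0, -26.0, -9.0)),
    RoiSpec("R_STS", (59.0, -18.0, -17.0)),
    RoiSpec("MPFC", (1.0, 58.0, 19.0)),
    RoiSpec("precuneus", (-3.0, -56.0, 37.0)),
)


@dataclass(frozen=True)
class GridSpec:
    """Voxel grid: array shape plus the 4x4 voxel-to-millimeter affine."""

    shape: tuple[int, int, int]
    affine: np.ndarray

    def __post_init__(self):
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        object.__setattr__(self, "affine", affine)

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def voxel_centers_mm(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        hom = np.c_[ijk, np.ones(len(ijk))]
        return (self.affine @ hom.T).T[:, :3]


def mni_grid(voxel_mm: float = 2.5) -> GridSpec:
    """Standard-space grid at the given isotropic resolution.

    Covers roughly x in [-90, 90], y in [-126, 90], z in [-72, 108] mm.
    """
    affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    affine[:3, 3] = (-90.0, -126.0, -72.0)
    shape = tuple(
        int(np.floor(extent / voxel_mm)) + 1 for extent in (180.0, 216.0, 180.0)
    )
    return GridSpec(shape=shape, affine=affine)


@dataclass
class VoxelMask:
    """Set of voxel indices with grid metadata.

    ``indices`` is an (n, 3) integer array in canonical (lexicographic by
    i, j, k) order; construction sorts and de-duplicates.
    """

    indices: np.ndarray
    grid: GridSpec

    def __post_init__(self):
        idx = np.atleast_2d(np.asarray(self.indices, dtype=int))
        if idx.size == 0:
            idx = idx.reshape(0, 3)
        if idx.shape[1] != 3:
            raise ValueError("indices must be (n, 3)")
        shape = self.grid.shape
        if idx.size and ((idx < 0).any() or (idx >= np.array(shape)).any()):
            raise ValueError("voxel index outside grid")
        # canonical lexicographic order, unique rows
        idx = np.unique(idx, axis=0)
        self.indices = idx

    @property
    def n_voxels(self) -> int:
        return len(self.indices)

    def flat(self) -> np.ndarray:
        """Raveled (C-order) linear indices into the grid."""
        return np.ravel_multi_index(self.indices.T, self.grid.shape)

    def as_volume(self) -> np.ndarray:
        vol = np.zeros(self.grid.shape, dtype=np.uint8)
        vol[tuple(self.indices.T)] = 1
        return vol


def mm_to_voxel(
    affine: np.ndarray,
    mm: tuple[float, float, float],
    shape: tuple[int, int, int] | None = None,
) -> tuple[int, int, int]:
    """Nearest voxel to a millimeter coordinate.

    Rounds half-integers away from zero.  If ``shape`` is given, coordinates
    outside the grid raise ``ValueError``.
    """
    affine = np.asarray(affine, dtype=float)
    v = np.linalg.solve(affine, np.r_[np.asarray(mm, dtype=float), 1.0])[:3]
    ijk = (np.sign(v) * np.floor(np.abs(v) + 0.5)).astype(int)
    if shape is not None and (
        (ijk < 0).any() or (ijk >= np.array(shape)).any()
    ):
        raise ValueError(f"{tuple(mm)} mm maps to voxel {tuple(ijk)}, outside grid {shape}")
    return tuple(int(c) for c in ijk)


def sphere_voxels(
    center_mm: tuple[float, float, float], radius_mm: float, grid: GridSpec
) -> VoxelMask:
    """All voxels whose centers lie within ``radius_mm`` of ``center_mm``.

    Candidates are drawn from the voxel-space image of the sphere's
    bounding box, then filtered by Euclidean distance in millimeters.
    """
    if radius_mm <= 0:
        raise ValueError("radius_mm must be positive")
    center = np.asarray(center_mm, dtype=float)
    inv = np.linalg.inv(grid.affine)
    # bounding box corners in mm -> voxel space
    corners = center + radius_mm * np.array(
        [[sx, sy, sz] for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)]
    )
    vcorners = (inv @ np.c_[corners, np.ones(8)].T).T[:, :3]
    lo = np.maximum(np.floor(vcorners.min(axis=0)).astype(int), 0)
    hi = np.minimum(np.ceil(vcorners.max(axis=0)).astype(int), np.array(grid.shape) - 1)
    if (lo > hi).any():
        raise ValueError("sphere does not intersect the grid")
    ii, jj, kk = np.meshgrid(
        *(np.arange(l, h + 1) for l, h in zip(lo, hi)), indexing="ij"
    )
    cand = np.c_[ii.ravel(), jj.ravel(), kk.ravel()]
    centers = grid.voxel_centers_mm(cand)
    inside = np.linalg.norm(centers - center, axis=1) <= radius_mm
    if not inside.any():
        raise ValueError("sphere contains no voxel centers")
    return VoxelMask(indices=cand[inside], grid=grid)


def roi_masks(
    rois: tuple[RoiSpec, ...], grid: GridSpec, report_overlap: bool = True
) -> dict[str, VoxelMask]:
    """Build one mask per ROI; overlapping pairs are allowed but logged."""
    masks = {r.name: sphere_voxels(r.center_mm, r.radius_mm, grid) for r in rois}
    if report_overlap:
        for (na, ma), (nb, mb) in combinations(masks.items(), 2):
            shared = np.intersect1d(ma.flat(), mb.flat())
            if shared.size:
                logger.warning("ROIs %s and %s share %d voxels", na, nb, shared.size)
            else:
                logger.debug("ROIs %s and %s are disjoint", na, nb)
    return masks


def union_mask(masks) -> VoxelMask:
    masks = list(masks)
    if not masks:
        raise ValueError("no masks given")
    idx = np.vstack([m.indices for m in masks])
    return VoxelMask(indices=idx, grid=masks[0].grid)
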