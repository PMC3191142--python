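"""Sphere ROIs, thresholded-map intersection, template fit and extraction.

Geometry lives in world (mm) coordinates: voxel (i, j, k) has its center at
``origin_mm + voxel_size_mm * (i, j, k)`` on a regular grid, matching MNI
space when volumes come from NIfTI files (in which case the affine supplies
the mapping).  ROIs are spheres around peak coordinates (10 mm radius for
region extraction, 5 mm for the component-selection template).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class VoxelGrid:
    """Regular voxel grid: dimensions, voxel size (mm) and world origin."""

    dims: tuple[int, int, int]
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "dims", tuple(int(d) for d in self.dims))
        object.__setattr__(self, "voxel_size_mm", tuple(float(v) for v in self.voxel_size_mm))
        object.__setattr__(self, "origin_mm", tuple(float(v) for v in self.origin_mm))
        if any(d <= 0 for d in self.dims):
            raise ValueError("grid dims must be positive")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel sizes must be positive")

    def voxel_centers_mm(self) -> np.ndarray:
        """World coordinates of all voxel centers, shape (*dims, 3)."""
        axes = [
            self.origin_mm[a] + self.voxel_size_mm[a] * np.arange(self.dims[a])
            for a in range(3)
        ]
        gi, gj, gk = np.meshgrid(*axes, indexing="ij")
        return np.stack([gi, gj, gk], axis=-1)


@dataclass(frozen=True)
class VoxelMask:
    """Set of voxel indices on a grid."""

    grid: VoxelGrid
    voxels: frozenset[tuple[int, int, int]]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "voxels", frozenset(tuple(int(c) for c in v) for v in self.voxels)
        )
        nx, ny, nz = self.grid.dims
        for i, j, k in self.voxels:
            if not (0 <= i < nx and 0 <= j < ny and 0 <= k < nz):
                raise ValueError(f"voxel {(i, j, k)} outside grid {self.grid.dims}")

    def __len__(self) -> int:
        return len(self.voxels)

    def indices(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Index arrays suitable for fancy-indexing a volume."""
        if not self.voxels:
            empty = np.array([], dtype=int)
            return empty, empty.copy(), empty.copy()
        arr = np.array(sorted(self.voxels), dtype=int)
        return arr[:, 0], arr[:, 1], arr[:, 2]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "dims": list(self.grid.dims),
            "voxel_size_mm": list(self.grid.voxel_size_mm),
            "origin_mm": list(self.grid.origin_mm),
            "voxels": sorted(list(v) for v in self.voxels),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "VoxelMask":
        d = json.loads(Path(path).read_text())
        grid = VoxelGrid(tuple(d["dims"]), tuple(d["voxel_size_mm"]), tuple(d["origin_mm"]))
        return cls(grid, frozenset(tuple(v) for v in d["voxels"]))


def sphere_mask(
    grid: VoxelGrid, center_mm: Sequence[float], radius_mm: float
) -> VoxelMask:
    """Voxels whose center lies within ``radius_mm`` of ``center_mm``.

    Distances are Euclidean between voxel centers in world coordinates;
    the boundary is inclusive.  An off-grid center may yield an empty mask.
    """
    if radius_mm < 0:
        raise ValueError("radius must be >= 0")
    centers = grid.voxel_centers_mm()
    d2 = np.sum((centers - np.asarray(center_mm, dtype=float)) ** 2, axis=-1)
    sel = np.argwhere(d2 <= radius_mm**2)
    return VoxelMask(grid, frozenset(map(tuple, sel.tolist())))


def intersect_with_threshold(
    mask: VoxelMask, stat_map: np.ndarray, threshold: float
) -> VoxelMask:
    """Voxels of ``mask`` whose statistic is strictly above ``threshold``.

    This reproduces ROI definition as the intersection of a peak-centered
    sphere with the supra-threshold group statistical map.
    """
    stat_map = np.asarray(stat_map, dtype=float)
    if stat_map.shape != mask.grid.dims:
        raise ValueError(
            f"stat map shape {stat_map.shape} != grid dims {mask.grid.dims}"
        )
    kept = frozenset(v for v in mask.voxels if stat_map[v] > threshold)
    return VoxelMask(mask.grid, kept)


def template_fit_score(
    component_map: np.ndarray, template_spheres: Sequence[VoxelMask]
) -> float:
    """Goodness-of-fit of a component map to a set of template spheres.

    Mean intensity over the union of sphere voxels minus mean intensity
    over all voxels outside every sphere.  Invariant under adding a
    constant to the map; scales linearly with the map.
    """
    component_map = np.asarray(component_map, dtype=float)
    if not template_spheres:
        raise ValueError("need at least one template sphere")
    grid = template_spheres[0].grid
    if component_map.shape != grid.dims:
        raise ValueError("component map shape does not match template grid")
    inside = np.zeros(grid.dims, dtype=bool)
    for sph in template_spheres:
        if sph.grid != grid:
            raise ValueError("template spheres live on different grids")
        inside[sph.indices()] = True
    n_in = int(inside.sum())
    n_out = inside.size - n_in
    if n_in == 0 or n_out == 0:
        raise ValueError("template must leave voxels both inside and outside")
    return float(component_map[inside].mean() - component_map[~inside].mean())


def select_best_component(
    component_maps: Sequence[np.ndarray], template_spheres: Sequence[VoxelMask]
) -> tuple[int, float]:
    """Index and score of the component with the best template fit.

    Ties are broken by the lowest component index (logged).
    """
    if not len(component_maps):
        raise ValueError("no component maps given")
    scores = [template_fit_score(m, template_spheres) for m in component_maps]
    best = int(np.argmax(scores))  # argmax takes the first maximum
    if scores.count(max(scores)) > 1:
        logger.info("template fit tie: keeping lowest component index %d", best)
    return best, scores[best]


def extract_roi_timeseries(volumes: np.ndarray, mask: VoxelMask) -> np.ndarray:
    """Average time course over the mask voxels.

    ``volumes`` is 4-D with time last, shape (*grid.dims, T); the result
    is the unweighted mean over mask voxels per time point.
    """
    volumes = np.asarray(volumes, dtype=float)
    if volumes.ndim != 4 or volumes.shape[:3] != mask.grid.dims:
        raise ValueError(
            f"volumes shape {volumes.shape} incompatible with grid {mask.grid.dims}"
        )
    if len(mask) == 0:
        raise ValueError("cannot extract a time series from an empty mask")
    return volumes[mask.indices()].mean(axis=0)


# ---------------------------------------------------------------------------
# optional NIfTI I/O

def load_nifti_volume(path: str | Path) -> tuple[np.ndarray, VoxelGrid]:
    """Read a 3-D or 4-D NIfTI file; the grid comes from the affine.

    Only axis-aligned affines map onto :class:`VoxelGrid`; an oblique
    affine is rejected.
    """
    import nibabel as nib

    img = nib.load(str(path))
    affine = img.affine
    rot = affine[:3, :3]
    if np.count_nonzero(rot - np.diag(np.diag(rot))):
        raise ValueError("oblique affine: grid must be axis-aligned")
    data = np.asarray(img.get_fdata(), dtype=float)
    grid = VoxelGrid(
        dims=tuple(data.shape[:3]),
        voxel_size_mm=tuple(np.abs(np.diag(rot))),
        origin_mm=tuple(affine[:3, 3]),
    )
    return data, grid


def save_nifti_mask(mask: VoxelMask, path: str | Path) -> None:
    """Write a mask as a binary NIfTI volume on its grid."""
    import nibabel as nib

    vol = np.zeros(mask.grid.dims, dtype=np.uint8)
    vol[mask.indices()] = 1
    affine = np.diag(list(mask.grid.voxel_size_mm) + [1.0])
    affine[:3, 3] = mask.grid.origin_mm
    nib.save(nib.Nifti1Image(vol, affine), str(path))
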