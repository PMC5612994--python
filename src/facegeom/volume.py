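"""Volumetric data model: grids, masks, sphere neighborhoods and ROI handling.

Voxel coordinates are 0-based integer index triples ``(i, j, k)``.  World
(mm) coordinates are obtained through the grid affine; distances used for
ROI overlap reassignment are computed in mm so the behaviour is stable
across template resolutions.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "VolumeGrid",
    "BrainMask",
    "ROISpec",
    "sphere_offsets",
    "sphere_neighborhood",
    "build_union_mask",
    "make_spherical_roi",
    "resolve_roi_overlaps",
    "save_volume",
    "load_volume",
    "save_mask",
    "load_mask",
    "write_roi_table",
    "read_roi_table",
]

ROI_SYSTEMS = ("EV", "core-ventral", "core-dorsal", "core-anterior", "extended")


@dataclass(frozen=True)
class VolumeGrid:
    """A 3-D voxel grid with a voxel-to-world affine.

    Parameters
    ----------
    dims:
        Number of voxels along each axis.
    voxel_size:
        Voxel edge lengths in mm.
    affine:
        4x4 voxel-index -> world-mm matrix.  Defaults to a diagonal
        scaling by ``voxel_size``.
    """

    dims: tuple[int, int, int]
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)
    affine: np.ndarray | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        dims = tuple(int(d) for d in self.dims)
        vs = tuple(float(v) for v in self.voxel_size)
        if len(dims) != 3 or any(d < 1 for d in dims):
            raise ValueError(f"dims must be 3 positive integers, got {self.dims}")
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValueError(f"voxel_size must be 3 positive reals, got {self.voxel_size}")
        object.__setattr__(self, "dims", dims)
        object.__setattr__(self, "voxel_size", vs)
        if self.affine is None:
            aff = np.diag((*vs, 1.0))
        else:
            aff = np.asarray(self.affine, dtype=float)
            if aff.shape != (4, 4):
                raise ValueError("affine must be a 4x4 matrix")
            if abs(np.linalg.det(aff[:3, :3])) < 1e-12:
                raise ValueError("affine must be invertible")
        object.__setattr__(self, "affine", aff)

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.dims))

    def to_world(self, ijk: np.ndarray) -> np.ndarray:
        """Map (n, 3) voxel indices to (n, 3) world mm coordinates."""
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def __eq__(self, other) -> bool:  # affine compared by value
        if not isinstance(other, VolumeGrid):
            return NotImplemented
        return (
            self.dims == other.dims
            and self.voxel_size == other.voxel_size
            and np.allclose(self.affine, other.affine)
        )

    def __hash__(self) -> int:
        return hash((self.dims, self.voxel_size))


@dataclass
class BrainMask:
    """Boolean inclusion map over a :class:`VolumeGrid`."""

    grid: VolumeGrid
    included: np.ndarray

    def __post_init__(self) -> None:
        self.included = np.asarray(self.included, dtype=bool)
        if self.included.shape != self.grid.dims:
            raise ValueError(
                f"mask shape {self.included.shape} does not match grid dims {self.grid.dims}"
            )
        if not self.included.any():
            raise ValueError("mask must include at least one voxel")

    @classmethod
    def full(cls, grid: VolumeGrid) -> "BrainMask":
        return cls(grid, np.ones(grid.dims, dtype=bool))

    @property
    def n_voxels(self) -> int:
        return int(self.included.sum())

    def voxel_indices(self) -> np.ndarray:
        """In-mask voxel index triples, shape (n, 3), C order."""
        return np.argwhere(self.included)

    def column_lookup(self) -> np.ndarray:
        """3-D int array mapping voxel index -> in-mask column, -1 outside."""
        lut = np.full(self.grid.dims, -1, dtype=np.int64)
        lut[self.included] = np.arange(self.n_voxels)
        return lut

    def contains(self, ijk) -> bool:
        i, j, k = (int(c) for c in ijk)
        if not (0 <= i < self.grid.dims[0] and 0 <= j < self.grid.dims[1] and 0 <= k < self.grid.dims[2]):
            return False
        return bool(self.included[i, j, k])


@dataclass
class ROISpec:
    """Spherical region of interest resolved to an explicit voxel set."""

    name: str
    center: tuple[int, int, int]
    radius_mm: float
    system: str
    voxels: np.ndarray  # (n, 3) int voxel indices

    def __post_init__(self) -> None:
        self.center = tuple(int(c) for c in self.center)
        if self.radius_mm <= 0:
            raise ValueError("radius_mm must be positive")
        if self.system not in ROI_SYSTEMS:
            raise ValueError(f"unknown system {self.system!r}; expected one of {ROI_SYSTEMS}")
        self.voxels = np.asarray(self.voxels, dtype=np.int64).reshape(-1, 3)
        if len(self.voxels) == 0:
            raise ValueError(f"ROI {self.name!r} has no voxels")

    @property
    def n_voxels(self) -> int:
        return len(self.voxels)

    def voxel_set(self) -> set[tuple[int, int, int]]:
        return {tuple(v) for v in self.voxels.tolist()}


@functools.lru_cache(maxsize=32)
def sphere_offsets(radius_vox: float) -> np.ndarray:
    """Integer lattice offsets with Euclidean norm <= radius_vox (inclusive).

    The (0, 0, 0) offset is always present.  At radius 5 this yields the
    515 lattice points of the standard searchlight sphere.
    """
    if radius_vox < 0:
        raise ValueError("radius_vox must be non-negative")
    r = int(np.floor(radius_vox))
    ax = np.arange(-r, r + 1)
    ii, jj, kk = np.meshgrid(ax, ax, ax, indexing="ij")
    offs = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)
    keep = (offs**2).sum(axis=1) <= radius_vox**2 + 1e-12
    return offs[keep]


def sphere_neighborhood(center, radius_vox: float, mask: BrainMask) -> np.ndarray:
    """All in-mask voxels within ``radius_vox`` (Euclidean, inclusive) of center.

    Returns an (n, 3) int array; always contains the center voxel.
    Raises ``ValueError`` if the center is outside the mask (an invalid
    searchlight seed).
    """
    center = tuple(int(c) for c in center)
    if not mask.contains(center):
        raise ValueError(f"searchlight center {center} is outside the mask")
    pts = sphere_offsets(float(radius_vox)) + np.asarray(center, dtype=np.int64)
    dims = mask.grid.dims
    ok = (
        (pts[:, 0] >= 0) & (pts[:, 0] < dims[0])
        & (pts[:, 1] >= 0) & (pts[:, 1] < dims[1])
        & (pts[:, 2] >= 0) & (pts[:, 2] < dims[2])
    )
    pts = pts[ok]
    inmask = mask.included[pts[:, 0], pts[:, 1], pts[:, 2]]
    return pts[inmask]


def build_union_mask(masks: list[BrainMask], min_count: int) -> BrainMask:
    """Voxels covered by at least ``min_count`` of the input masks."""
    if not masks:
        raise ValueError("empty mask list")
    if min_count < 1:
        raise ValueError("min_count must be a positive integer")
    grid = masks[0].grid
    for m in masks[1:]:
        if m.grid != grid:
            raise ValueError("all masks must share one grid")
    counts = np.sum([m.included for m in masks], axis=0)
    return BrainMask(grid, counts >= min_count)


def make_spherical_roi(
    name: str,
    center,
    radius_mm: float,
    system: str,
    mask: BrainMask,
) -> ROISpec:
    """Resolve a spherical ROI (radius in mm, measured in world space)."""
    center = tuple(int(c) for c in center)
    if not mask.contains(center):
        raise ValueError(f"ROI center {center} must lie inside the mask")
    grid = mask.grid
    r_vox = radius_mm / min(grid.voxel_size)  # candidate bound
    cand = sphere_offsets(float(np.ceil(r_vox))) + np.asarray(center, dtype=np.int64)
    dims = grid.dims
    ok = np.all((cand >= 0) & (cand < np.asarray(dims)), axis=1)
    cand = cand[ok]
    cand = cand[mask.included[cand[:, 0], cand[:, 1], cand[:, 2]]]
    d = np.linalg.norm(grid.to_world(cand) - grid.to_world([center]), axis=1)
    return ROISpec(name, center, radius_mm, system, cand[d <= radius_mm + 1e-9])


def resolve_roi_overlaps(rois: list[ROISpec], grid: VolumeGrid) -> list[ROISpec]:
    """Assign each shared voxel to the ROI with the nearest center (mm).

    Exact distance ties go to the ROI earlier in the input list; ordering
    is therefore part of the configuration.  The union of voxels is
    conserved and the returned ROIs are pairwise disjoint.
    """
    centers = [r.center for r in rois]
    if len(set(centers)) != len(centers):
        raise ValueError("ROI centers must be distinct")
    owner: dict[tuple[int, int, int], list[int]] = {}
    for idx, roi in enumerate(rois):
        for vox in roi.voxel_set():
            owner.setdefault(vox, []).append(idx)
    centers_mm = grid.to_world(np.asarray(centers))
    assigned: dict[int, list[tuple[int, int, int]]] = {i: [] for i in range(len(rois))}
    for vox, idxs in owner.items():
        if len(idxs) == 1:
            assigned[idxs[0]].append(vox)
            continue
        vmm = grid.to_world([vox])[0]
        dists = [float(np.linalg.norm(centers_mm[i] - vmm)) for i in idxs]
        best = idxs[int(np.argmin(dists))]  # argmin takes the first -> earlier ROI on tie
        assigned[best].append(vox)
    out = []
    for idx, roi in enumerate(rois):
        vox = assigned[idx]
        if not vox:
            raise ValueError(f"ROI {roi.name!r} lost all voxels during overlap resolution")
        out.append(replace(roi, voxels=np.asarray(sorted(vox), dtype=np.int64)))
    return out


# ---------------------------------------------------------------------------
# NIfTI and table I/O


def save_volume(data: np.ndarray, grid: VolumeGrid, path) -> None:
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), grid.affine)
    img.header.set_zooms(grid.voxel_size[: data.ndim] + (1.0,) * (data.ndim - 3))
    nib.save(img, str(path))


def load_volume(path) -> tuple[np.ndarray, VolumeGrid]:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    grid = VolumeGrid(data.shape[:3], zooms, np.asarray(img.affine))
    return data, grid


def save_mask(mask: BrainMask, path) -> None:
    save_volume(mask.included.astype(np.float64), mask.grid, path)


def load_mask(path) -> BrainMask:
    data, grid = load_volume(path)
    return BrainMask(grid, data > 0.5)


def write_roi_table(rois: list[ROISpec], path) -> None:
    """Plain-text ROI table: name, center voxel, radius, system."""
    rows = [
        {
            "name": r.name,
            "x": r.center[0],
            "y": r.center[1],
            "z": r.center[2],
            "radius_mm": r.radius_mm,
            "system": r.system,
        }
        for r in rois
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_roi_table(path, mask: BrainMask, resolve_overlaps: bool = True) -> list[ROISpec]:
    df = pd.read_csv(path, sep="\t")
    rois = [
        make_spherical_roi(
            str(row["name"]),
            (row["x"], row["y"], row["z"]),
            float(row["radius_mm"]),
            str(row["system"]),
            mask,
        )
        for _, row in df.iterrows()
    ]
    if resolve_overlaps:
        rois = resolve_roi_overlaps(rois, mask.grid)
    return rois
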