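"""Resting blood volume fraction (V0) calibration from a high-resolution
angiography-like volume.

Large veins are bright in time-of-flight angiography, so a simple intensity
threshold segments them; an isolated supra-threshold voxel (no supra-threshold
neighbor under the configured connectivity) is treated as noise and dropped.
The binary vessel mask is then downsampled onto the coarse functional grid by
exact subvoxel counting: the large-vessel fraction of a functional voxel is
the number of vessel subvoxels in its block over the block size.  Finally the
per-voxel V0 is the two-component mixture

    V0 = lambda * v_blood + (1 - lambda) * v_tissue

where v_tissue is the capillary blood volume fraction of vessel-free tissue
(default 0.02) and v_blood the blood fraction of a pure-vessel subvoxel
(default 1.0).  Registration/reslicing is out of scope: the high-resolution
volume must already be grid-aligned with exact integer per-axis downsampling
factors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "HighResVolume",
    "VesselMask",
    "FunctionalGrid",
    "V0Map",
    "segment_vessels",
    "vessel_fraction",
    "compute_v0_map",
    "calibrate_v0",
    "extract_roi_series",
    "load_volume",
    "save_volume",
]


@dataclass
class HighResVolume:
    """A 3-D scalar intensity grid with physical voxel size (mm)."""

    intensities: np.ndarray
    voxel_size: tuple = (1.0, 1.0, 1.0)
    origin: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 3 or min(self.intensities.shape) < 1:
            raise ValueError("intensities must be a non-empty 3-D array")
        if any(s <= 0 for s in self.voxel_size):
            raise ValueError("voxel_size must be strictly positive")


@dataclass
class VesselMask:
    """Binary vessel mask on the high-resolution lattice."""

    mask: np.ndarray
    threshold: float
    n_removed: int
    connectivity: int = 26

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask)
        if not np.isin(self.mask, (0, 1)).all():
            raise ValueError("mask values must be 0 or 1")
        self.mask = self.mask.astype(np.uint8)


@dataclass
class FunctionalGrid:
    """Shape of the functional (fMRI) grid plus integer downsampling factors."""

    shape: tuple
    factors: tuple
    voxel_size: tuple | None = None

    def __post_init__(self) -> None:
        self.shape = tuple(int(s) for s in self.shape)
        self.factors = tuple(int(f) for f in self.factors)
        if len(self.shape) != 3 or len(self.factors) != 3:
            raise ValueError("shape and factors must be length-3")
        if any(s < 1 for s in self.shape) or any(f < 1 for f in self.factors):
            raise ValueError("shape and factors must be >= 1")

    @property
    def highres_shape(self) -> tuple:
        return tuple(s * f for s, f in zip(self.shape, self.factors))

    @property
    def block_size(self) -> int:
        return int(np.prod(self.factors))


@dataclass
class V0Map:
    """Per-functional-voxel resting blood volume fraction."""

    values: np.ndarray
    v_tissue: float
    v_blood: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        lo, hi = self.values.min(), self.values.max()
        if lo < self.v_tissue - 1e-12 or hi > self.v_blood + 1e-12:
            raise ValueError("V0 values must lie in [v_tissue, v_blood]")


def _neighbor_kernel(connectivity: int) -> np.ndarray:
    if connectivity == 26:
        k = np.ones((3, 3, 3), dtype=np.uint8)
    elif connectivity == 6:
        k = np.zeros((3, 3, 3), dtype=np.uint8)
        k[1, 1, 0] = k[1, 1, 2] = k[1, 0, 1] = k[1, 2, 1] = k[0, 1, 1] = k[2, 1, 1] = 1
    else:
        raise ValueError("connectivity must be 6 or 26")
    k[1, 1, 1] = 0
    return k


def segment_vessels(volume: HighResVolume, threshold: float,
                    connectivity: int = 26) -> VesselMask:
    """Threshold segmentation with isolated-voxel noise rejection.

    A voxel is retained iff its intensity exceeds the threshold AND it has at
    least one supra-threshold neighbor under the connectivity rule (26 =
    face/edge/corner, 6 = face only).  The number of excluded isolated voxels
    is reported on the mask.
    """
    data = volume.intensities
    if threshold < data.min() or threshold > data.max():
        warnings.warn(
            f"threshold {threshold} lies outside the intensity range "
            f"[{data.min()}, {data.max()}]; the mask may be empty or full",
            stacklevel=2)
    above = data > threshold
    neighbors = ndimage.convolve(above.astype(np.uint8),
                                 _neighbor_kernel(connectivity),
                                 mode="constant", cval=0)
    keep = above & (neighbors >= 1)
    removed = int(above.sum() - keep.sum())
    return VesselMask(mask=keep.astype(np.uint8), threshold=float(threshold),
                      n_removed=removed, connectivity=connectivity)


def vessel_fraction(mask: VesselMask, grid: FunctionalGrid) -> np.ndarray:
    """Large-vessel fraction per functional voxel by exact subvoxel counting.

    Functional voxel (i, j, k) owns the half-open subvoxel block
    [i*fx, (i+1)*fx) x [j*fy, (j+1)*fy) x [k*fz, (k+1)*fz).  Counting is
    integer-exact: sum(lambda) * block_size equals the total mask count.
    """
    m = mask.mask
    if m.shape != grid.highres_shape:
        raise ValueError(
            f"mask shape {m.shape} is not functional shape {grid.shape} times "
            f"integer factors {grid.factors}; resample upstream so that every "
            "axis divides exactly")
    nx, ny, nz = grid.shape
    fx, fy, fz = grid.factors
    counts = m.reshape(nx, fx, ny, fy, nz, fz).sum(axis=(1, 3, 5))
    return counts / grid.block_size


def compute_v0_map(lambda_grid: np.ndarray, v_tissue: float = 0.02,
                   v_blood: float = 1.0) -> V0Map:
    """Mixture formula V0 = lambda*v_blood + (1 - lambda)*v_tissue per voxel."""
    lam = np.asarray(lambda_grid, dtype=float)
    if lam.min() < 0 or lam.max() > 1:
        raise ValueError("lambda values must lie in [0, 1]")
    if not 0 < v_tissue < v_blood <= 1.0:
        raise ValueError("require 0 < v_tissue < v_blood <= 1")
    values = lam * v_blood + (1.0 - lam) * v_tissue
    return V0Map(values=values, v_tissue=float(v_tissue), v_blood=float(v_blood))


def calibrate_v0(volume: HighResVolume, threshold: float, grid: FunctionalGrid,
                 v_tissue: float = 0.02, v_blood: float = 1.0,
                 connectivity: int = 26):
    """Full calibration pipeline: segment, count, mix.

    Returns (V0Map, VesselMask, metadata dict).  The metadata echoes every
    configuration value so a run can be reproduced from its sidecar alone.
    """
    mask = segment_vessels(volume, threshold, connectivity)
    lam = vessel_fraction(mask, grid)
    v0 = compute_v0_map(lam, v_tissue, v_blood)
    meta = {
        "threshold": float(threshold),
        "connectivity": connectivity,
        "v_tissue": float(v_tissue),
        "v_blood": float(v_blood),
        "n_removed_isolated": mask.n_removed,
        "functional_shape": list(grid.shape),
        "downsampling_factors": list(grid.factors),
    }
    return v0, mask, meta


def extract_roi_series(bold_4d: np.ndarray, roi_center: tuple):
    """Mean time series over a center voxel and its in-slice edge neighbors.

    The cluster is edge-based, corners excluded: the four (+-1, 0) and
    (0, +-1) neighbors in the same slice, restricted to those inside the
    volume.  Returns (series, member_voxels) where members are audit-friendly
    index triples.
    """
    bold_4d = np.asarray(bold_4d, dtype=float)
    if bold_4d.ndim != 4:
        raise ValueError("bold_4d must be a 4-D (x, y, z, t) array")
    i, j, k = (int(c) for c in roi_center)
    nx, ny, nz, _ = bold_4d.shape
    if not (0 <= i < nx and 0 <= j < ny and 0 <= k < nz):
        raise ValueError(f"roi_center {roi_center} lies outside the volume")
    members = [(i, j, k)]
    for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        ii, jj = i + di, j + dj
        if 0 <= ii < nx and 0 <= jj < ny:
            members.append((ii, jj, k))
    series = np.mean([bold_4d[m] for m in members], axis=0)
    return series, members


def load_volume(path) -> HighResVolume:
    """Read a NIfTI volume into a HighResVolume."""
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return HighResVolume(intensities=data, voxel_size=zooms)


def save_volume(data: np.ndarray, path, voxel_size=(1.0, 1.0, 1.0)) -> None:
    """Write a 3-D array as NIfTI with the given voxel size (mm)."""
    import nibabel as nib

    affine = np.diag(list(voxel_size) + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine), str(path))
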