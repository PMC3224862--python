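"""Shared data containers: sensor time series, voxel grids and volumetric maps.

Conventions
-----------
* All geometry is SI (meters) internally.  Grid spacing is carried in
  millimeters because that is the natural unit for the NIfTI export and for
  volume reporting (cm^3).
* Voxel grids are regular lattices clipped to a sphere; in-mask voxels are
  stored in a flat array ordered by C-order linear index of the bounding box.
  Tie-breaking by "smallest linear index" therefore refers to this ordering.
* NIfTI files are written with a diagonal affine (mm) mapping voxel indices
  to world coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = [
    "as_seed_sequence",
    "SensorTimeSeries",
    "VoxelGrid",
    "FCVolumetricMap",
    "FourDVolume",
    "write_map_nifti",
    "read_map_nifti",
]


def as_seed_sequence(seed) -> np.random.SeedSequence:
    """Coerce an int (or pass through a SeedSequence) for child spawning."""
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


@dataclass
class SensorTimeSeries:
    """M x T multichannel recording with sampling rate ``fs`` (Hz)."""

    data: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def copy(self) -> "SensorTimeSeries":
        return SensorTimeSeries(self.data.copy(), self.fs)


@dataclass
class VoxelGrid:
    """Regular lattice of voxel centers clipped to a sphere.

    Attributes
    ----------
    positions : (N, 3) float array
        In-mask voxel centers in meters, ordered by bounding-box linear index.
    spacing_mm : float
        Lattice spacing in millimeters (uniform in all three axes).
    shape : (3,) int tuple
        Bounding box shape (nx, ny, nz).
    origin : (3,) float array
        World position (meters) of voxel index (0, 0, 0).
    mask : (nx, ny, nz) bool array
        True for in-brain voxels.
    """

    positions: np.ndarray
    spacing_mm: float
    shape: tuple
    origin: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.origin = np.asarray(self.origin, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if int(self.mask.sum()) != len(self.positions):
            raise ValueError("mask voxel count does not match positions")

    @property
    def n_voxels(self) -> int:
        return len(self.positions)

    @property
    def voxel_volume_cm3(self) -> float:
        return (self.spacing_mm / 10.0) ** 3

    def flat_indices(self) -> np.ndarray:
        """Bounding-box linear (C-order) index of each in-mask voxel."""
        return np.flatnonzero(self.mask.ravel(order="C"))

    def to_box(self, values: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Scatter an in-mask value vector into the full bounding box."""
        values = np.asarray(values, dtype=float)
        if values.shape != (self.n_voxels,):
            raise ValueError("values length does not match grid")
        box = np.full(self.shape, fill, dtype=float)
        box[self.mask] = values
        return box

    def from_box(self, box: np.ndarray) -> np.ndarray:
        box = np.asarray(box, dtype=float)
        if box.shape != tuple(self.shape):
            raise ValueError("box shape does not match grid")
        return box[self.mask]

    def nearest_voxel(self, location: np.ndarray) -> int:
        """Index (into ``positions``) of the voxel center nearest ``location``."""
        d = np.linalg.norm(self.positions - np.asarray(location, float), axis=1)
        return int(np.argmin(d))

    def distances_from(self, index: int) -> np.ndarray:
        """Euclidean distance (mm) from voxel ``index`` to every voxel."""
        d = np.linalg.norm(self.positions - self.positions[index], axis=1)
        return d * 1000.0

    def same_geometry(self, other: "VoxelGrid") -> bool:
        return (
            tuple(self.shape) == tuple(other.shape)
            and np.isclose(self.spacing_mm, other.spacing_mm)
            and np.allclose(self.origin, other.origin)
            and np.array_equal(self.mask, other.mask)
        )


@dataclass
class FCVolumetricMap:
    """Per-voxel scalar values on a :class:`VoxelGrid` with provenance."""

    values: np.ndarray
    grid: VoxelGrid
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.n_voxels,):
            raise ValueError("values length does not match grid voxel count")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("map values must be finite")


@dataclass
class FourDVolume:
    """Per-voxel timecourses on a grid: (N_voxels, T) with sampling interval."""

    data: np.ndarray
    grid: VoxelGrid
    tr: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != self.grid.n_voxels:
            raise ValueError("data must be (n_voxels, T)")
        if self.tr <= 0:
            raise ValueError("tr must be positive")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]


def _affine(grid: VoxelGrid) -> np.ndarray:
    aff = np.diag([grid.spacing_mm, grid.spacing_mm, grid.spacing_mm, 1.0])
    aff[:3, 3] = grid.origin * 1000.0
    return aff


def write_map_nifti(path, fc_map: FCVolumetricMap) -> None:
    """Write a volumetric map as NIfTI-1 (mm world coordinates)."""
    box = fc_map.grid.to_box(fc_map.values, fill=np.nan)
    img = nib.Nifti1Image(box.astype(np.float32), _affine(fc_map.grid))
    nib.save(img, str(path))


def read_map_nifti(path, grid: VoxelGrid) -> FCVolumetricMap:
    """Read a map written by :func:`write_map_nifti` back onto ``grid``."""
    img = nib.load(str(path))
    box = np.asarray(img.get_fdata(), dtype=float)
    values = grid.from_box(np.nan_to_num(box, nan=0.0))
    return FCVolumetricMap(values, grid)
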