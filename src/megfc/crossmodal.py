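"""Volumetric-map comparison: smoothing, spatial correlation, overlap, peaks.

Maps live on :class:`~megfc.core.VoxelGrid` lattices.  Smoothing is a
separable Gaussian on the bounding box with mask renormalization so that
values near the mask edge are not pulled toward zero.  By convention,
smoothing before a cross-modal spatial correlation is applied only to the
reference ("hemodynamic") map to account for its intrinsic smoothness.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage, stats

from .core import FCVolumetricMap, FourDVolume, VoxelGrid

__all__ = [
    "gaussian_smooth",
    "spatial_correlation",
    "overlap_volume",
    "seed_correlation_volume",
    "bonferroni_threshold",
    "peak_location",
]

logger = logging.getLogger(__name__)

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def gaussian_smooth(fc_map: FCVolumetricMap, fwhm_mm: float) -> FCVolumetricMap:
    """Separable Gaussian smoothing with the given FWHM; fwhm 0 is identity."""
    if fwhm_mm < 0:
        raise ValueError("fwhm must be nonnegative")
    if fwhm_mm == 0.0:
        return FCVolumetricMap(fc_map.values.copy(), fc_map.grid, dict(fc_map.provenance))
    grid = fc_map.grid
    sigma_vox = fwhm_mm * _FWHM_TO_SIGMA / grid.spacing_mm
    box = grid.to_box(fc_map.values, fill=0.0)
    maskf = grid.mask.astype(float)
    sm = ndimage.gaussian_filter(box, sigma_vox, mode="constant")
    norm = ndimage.gaussian_filter(maskf, sigma_vox, mode="constant")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(norm > 0, sm / norm, 0.0)
    return FCVolumetricMap(
        grid.from_box(out), grid, {**fc_map.provenance, "smoothed_fwhm_mm": fwhm_mm}
    )


def spatial_correlation(
    map_a: FCVolumetricMap,
    map_b: FCVolumetricMap,
    exclude_voxel: int | None = None,
    exclude_radius_mm: float = 0.0,
) -> float:
    """Pearson correlation between the two vectorized in-mask maps.

    Whole-brain by default.  ``exclude_voxel``/``exclude_radius_mm`` drop a
    spherical neighborhood (typically the seed's leakage neighborhood, where
    every band shows trivially high values) from the comparison.
    """
    if not map_a.grid.same_geometry(map_b.grid):
        raise ValueError("maps must share a grid")
    sel = np.ones(map_a.grid.n_voxels, dtype=bool)
    if exclude_voxel is not None and exclude_radius_mm > 0.0:
        sel = map_a.grid.distances_from(exclude_voxel) > exclude_radius_mm
        if sel.sum() < 3:
            raise ValueError("exclusion removes nearly all voxels")
    a = map_a.values[sel] - map_a.values[sel].mean()
    b = map_b.values[sel] - map_b.values[sel].mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    if denom == 0.0:
        raise ValueError("zero-variance map")
    return float(np.dot(a, b) / denom)


def overlap_volume(mask_a: np.ndarray, mask_b: np.ndarray, spacing_mm: float):
    """Intersection volume (cm^3) and Jaccard fraction (|A & B| / |A | B|).

    The fraction is reported relative to the union; raw cm^3 is the primary
    number since overlap normalization is convention dependent.
    """
    a = np.asarray(mask_a, dtype=bool).ravel()
    b = np.asarray(mask_b, dtype=bool).ravel()
    if a.shape != b.shape:
        raise ValueError("masks must share a grid")
    inter = int(np.sum(a & b))
    union = int(np.sum(a | b))
    vol = inter * (spacing_mm / 10.0) ** 3
    frac = inter / union if union else 0.0
    return vol, frac


def _neighbor_indices(grid: VoxelGrid, seed_voxel: int) -> np.ndarray:
    """Seed voxel plus its up-to-26 lattice neighbors inside the mask."""
    flat = grid.flat_indices()
    nx, ny, nz = grid.shape
    ix, iy, iz = np.unravel_index(flat[seed_voxel], grid.shape)
    lookup = -np.ones(np.prod(grid.shape), dtype=int)
    lookup[flat] = np.arange(grid.n_voxels)
    members = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                jx, jy, jz = ix + dx, iy + dy, iz + dz
                if 0 <= jx < nx and 0 <= jy < ny and 0 <= jz < nz:
                    j = lookup[np.ravel_multi_index((jx, jy, jz), grid.shape)]
                    if j >= 0:
                        members.append(j)
    if len(members) < 27:
        logger.info(
            "seed neighborhood clipped at mask boundary: %d of 27 voxels", len(members)
        )
    return np.array(sorted(members))


def seed_correlation_volume(data: FourDVolume, seed_voxel: int) -> FCVolumetricMap:
    """Correlation of every voxel with the seed-neighborhood mean timecourse.

    The seed timecourse is the average over the seed voxel and its up-to-26
    in-mask lattice neighbors.  Zero-variance voxels get value 0 (logged).
    """
    if not 0 <= seed_voxel < data.grid.n_voxels:
        raise ValueError("seed voxel outside grid")
    members = _neighbor_indices(data.grid, seed_voxel)
    seed_ts = data.data[members].mean(axis=0)
    seed_c = seed_ts - seed_ts.mean()
    s_norm = np.linalg.norm(seed_c)
    if s_norm == 0.0:
        raise ValueError("seed timecourse has zero variance")
    centered = data.data - data.data.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    vals = np.zeros(data.grid.n_voxels)
    ok = norms > 0
    if not ok.all():
        logger.warning("%d zero-variance voxels set to 0", int((~ok).sum()))
    vals[ok] = centered[ok] @ seed_c / (norms[ok] * s_norm)
    return FCVolumetricMap(
        vals, data.grid, {"kind": "seed_correlation", "seed_voxel": seed_voxel}
    )


def bonferroni_threshold(
    fc_map: FCVolumetricMap, n_timepoints: int, n_tests: int, alpha: float = 0.05
) -> np.ndarray:
    """Threshold a correlation map at p < alpha / n_tests (two-sided).

    Correlations are converted to p-values with the t-transform
    t = r sqrt((n-2) / (1-r^2)) with n - 2 degrees of freedom.
    """
    if n_tests <= 0:
        raise ValueError("n_tests must be positive")
    if n_timepoints <= 2:
        raise ValueError("need more than 2 timepoints")
    r = np.clip(fc_map.values, -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt((n_timepoints - 2) / np.maximum(1.0 - r**2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), df=n_timepoints - 2)
    return p < alpha / n_tests


def peak_location(fc_map: FCVolumetricMap, region_mask: np.ndarray | None = None):
    """Voxel index and world position of the map maximum within a region.

    Ties are broken toward the smallest linear voxel index (logged).
    """
    if region_mask is None:
        region_mask = np.ones(fc_map.grid.n_voxels, dtype=bool)
    region_mask = np.asarray(region_mask, dtype=bool).ravel()
    if region_mask.shape != fc_map.values.shape or not region_mask.any():
        raise ValueError("region mask empty or mismatched")
    vals = np.where(region_mask, fc_map.values, -np.inf)
    peak = int(np.argmax(vals))  # argmax returns the first (smallest) index
    if np.sum(vals == vals[peak]) > 1:
        logger.info("peak tie broken toward smallest linear index %d", peak)
    return peak, fc_map.grid.positions[peak]
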