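"""Scalar (LCMV-type) beamformer: covariance, weights, orientation, projection.

The weight vector for a location/orientation with lead field L is

    W = (C + mu*sigma*I)^-1 L / (L^T (C + mu*sigma*I)^-1 L)

which minimizes the projected output variance subject to unit gain W^T L = 1.
``sigma`` is the noise-power floor, estimated as the minimum singular value of
the data covariance; ``mu`` is the unitless regularization scalar (default 4).

The source orientation at each voxel is the tangential angle maximizing the
projected output variance W(delta)^T C W(delta); the stationarity condition
reduces to a degree-4 polynomial on the unit circle which is solved in closed
form (see :func:`optimal_orientation`).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .core import FCVolumetricMap, SensorTimeSeries, VoxelGrid
from .forward import (
    ConductorModel,
    DegenerateGeometryError,
    SensorArray,
    tangential_lead_fields_grid,
)
from .spectral import FrequencyBand, fir_bandpass

__all__ = [
    "CovarianceEstimate",
    "BeamformerConfig",
    "WeightsVector",
    "SourceEstimate",
    "GridWeights",
    "estimate_covariance",
    "noise_floor",
    "compute_weights",
    "optimal_orientation",
    "project",
    "scan_grid",
    "variance_map",
    "pseudo_t_map",
    "weights_correlation_map",
    "lead_field_correlation_map",
    "correlation_vs_distance",
    "volume_above",
]

logger = logging.getLogger(__name__)


class SingularCovarianceError(np.linalg.LinAlgError):
    """Regularized covariance is numerically singular."""


@dataclass
class CovarianceEstimate:
    """Channel covariance over a sample window, mean removed per channel."""

    C: np.ndarray
    window: tuple
    n_samples: int

    def __post_init__(self) -> None:
        self.C = np.asarray(self.C, dtype=float)
        if self.C.ndim != 2 or self.C.shape[0] != self.C.shape[1]:
            raise ValueError("C must be square")
        if not np.allclose(self.C, self.C.T, atol=1e-12 * max(1.0, np.abs(self.C).max())):
            raise ValueError("C must be symmetric")

    @property
    def n_channels(self) -> int:
        return self.C.shape[0]


@dataclass
class BeamformerConfig:
    mu: float = 4.0
    band: Optional[FrequencyBand] = None
    window_policy: str = "all_data"  # or "resting_only"

    def __post_init__(self) -> None:
        if self.mu < 0:
            raise ValueError("mu must be nonnegative")
        if self.window_policy not in ("all_data", "resting_only"):
            raise ValueError("window_policy must be 'all_data' or 'resting_only'")


@dataclass
class WeightsVector:
    values: np.ndarray
    location: np.ndarray
    delta: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        self.location = np.asarray(self.location, dtype=float).reshape(3)


@dataclass
class SourceEstimate:
    """Beamformer-projected voxel timecourse (A·m) with sampling rate."""

    timecourse: np.ndarray
    fs: float
    band: Optional[str] = None

    def __post_init__(self) -> None:
        self.timecourse = np.asarray(self.timecourse, dtype=float).ravel()


@dataclass
class GridWeights:
    """Per-voxel weights and optimized orientations for one band/window."""

    weights: np.ndarray  # (n_voxels, M)
    deltas: np.ndarray  # (n_voxels,)
    grid: VoxelGrid
    covariance: CovarianceEstimate
    sigma: float
    config: BeamformerConfig
    lead_fields: Optional[np.ndarray] = None  # (n_voxels, M) at optimized delta

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.deltas = np.asarray(self.deltas, dtype=float)
        if self.weights.shape[0] != self.grid.n_voxels:
            raise ValueError("one weight vector per grid voxel required")


def estimate_covariance(data: SensorTimeSeries, window=None) -> CovarianceEstimate:
    """Covariance of mean-removed data over ``window`` (sample range).

    ``window`` is a (start, stop) pair of sample indices or None for all
    samples.  A warning is emitted when the window is shorter than the
    channel count (rank-deficient estimate).
    """
    if window is None:
        window = (0, data.n_samples)
    start, stop = int(window[0]), int(window[1])
    seg = data.data[:, start:stop]
    if seg.shape[1] == 0:
        raise ValueError("empty covariance window")
    if seg.shape[1] < data.n_channels:
        warnings.warn(
            "covariance window shorter than channel count; estimate is rank deficient",
            stacklevel=2,
        )
    seg = seg - seg.mean(axis=1, keepdims=True)
    c = seg @ seg.T / seg.shape[1]
    c = 0.5 * (c + c.T)
    return CovarianceEstimate(c, (start, stop), seg.shape[1])


def noise_floor(cov: CovarianceEstimate) -> float:
    """Uncorrelated-noise power estimate: minimum singular value of C."""
    return float(np.linalg.svd(cov.C, compute_uv=False)[-1])


def _regularized_inverse(cov: CovarianceEstimate, mu: float, sigma: float) -> np.ndarray:
    c_reg = cov.C + mu * sigma * np.eye(cov.n_channels)
    cond = np.linalg.cond(c_reg)
    if not np.isfinite(cond) or cond > 1e13:
        raise SingularCovarianceError(
            f"regularized covariance is numerically singular (condition number {cond:.3g})"
        )
    return np.linalg.inv(c_reg)


def compute_weights(
    lead_field_values: np.ndarray,
    cov: CovarianceEstimate,
    cfg: BeamformerConfig,
    sigma: Optional[float] = None,
    location=None,
    delta: float = np.nan,
) -> WeightsVector:
    """Unit-gain minimum-variance weights for one lead field."""
    L = np.asarray(getattr(lead_field_values, "values", lead_field_values), float).ravel()
    if sigma is None:
        sigma = noise_floor(cov)
    c_inv = _regularized_inverse(cov, cfg.mu, sigma)
    ci_l = c_inv @ L
    gain = float(L @ ci_l)
    if gain <= 0:
        raise SingularCovarianceError("lead field annihilated by covariance inverse")
    w = ci_l / gain
    loc = np.zeros(3) if location is None else location
    return WeightsVector(w, loc, delta)


def _orientation_quadratics(L1, L2, c_inv, C):
    """2x2 quadratic forms of projected variance over the tangential plane.

    For unit orientation u, with B = [L1 L2]:
        numerator   u^T A u   where A = B^T Ci C Ci B
        denominator (u^T D u)^2  where D = B^T Ci B
    and the projected variance is num / den.
    """
    B = np.column_stack([L1, L2])
    ci_b = c_inv @ B
    A = ci_b.T @ C @ ci_b
    D = B.T @ ci_b
    return A, D


def _trig_coeffs(Q):
    """u^T Q u = q0 + q1*cos(2d) + q2*sin(2d) for u = (cos d, sin d)."""
    return (
        0.5 * (Q[0, 0] + Q[1, 1]),
        0.5 * (Q[0, 0] - Q[1, 1]),
        0.5 * (Q[0, 1] + Q[1, 0]),
    )


def _stationary_deltas(A, D):
    """Closed-form stationary angles of f(d) = N(d) / D(d)^2.

    N and D are sinusoids in 2d; N' D - 2 N D' = 0 becomes a degree-4
    polynomial in z = exp(2 i d), solved with the companion-matrix root
    finder.  Roots on the unit circle give the candidate angles.
    """
    a0, a1, a2 = _trig_coeffs(A)
    d0, d1, d2 = _trig_coeffs(D)
    # G(phi) = (-a1 s + a2 c)(d0 + d1 c + d2 s) - 2 (a0 + a1 c + a2 s)(-d1 s + d2 c)
    # with phi = 2 delta.  Substitute c = (z + 1/z)/2, s = (z - 1/z)/(2i) for
    # z = exp(i phi); each factor is a Laurent polynomial over z^1, z^0, z^-1.
    p_nprime = np.array([a2 / 2 - a1 / (2j), 0.0, a2 / 2 + a1 / (2j)], dtype=complex)
    p_den = np.array([d1 / 2 + d2 / (2j), d0, d1 / 2 - d2 / (2j)], dtype=complex)
    p_num = np.array([a1 / 2 + a2 / (2j), a0, a1 / 2 - a2 / (2j)], dtype=complex)
    p_dprime = np.array([d2 / 2 - d1 / (2j), 0.0, d2 / 2 + d1 / (2j)], dtype=complex)
    poly = np.convolve(p_nprime, p_den) - 2.0 * np.convolve(p_num, p_dprime)
    # poly holds coefficients over z^2 .. z^-2; np.roots wants descending powers
    peak = np.abs(poly).max()
    if peak == 0.0 or not np.isfinite(peak):
        return np.array([0.0])
    roots = np.roots(poly / peak)
    roots = roots[np.abs(np.abs(roots) - 1.0) < 1e-6]
    phis = np.angle(roots)
    return np.unique(np.mod(phis / 2.0, np.pi))


def _best_delta(A: np.ndarray, D: np.ndarray) -> float:
    """Variance-maximizing tangential angle given the 2x2 quadratic forms.

    Evaluates the closed-form stationary angles and returns the maximizer,
    breaking (numerical) ties toward the smallest delta.
    """
    candidates = _stationary_deltas(A, D)
    if candidates.size == 0:
        candidates = np.linspace(0.0, np.pi, 721, endpoint=False)
    vals = np.full(candidates.shape, -np.inf)
    for i, d in enumerate(candidates):
        u = np.array([np.cos(d), np.sin(d)])
        den = float(u @ D @ u)
        if den > 0:
            vals[i] = float(u @ A @ u) / den**2
    best = vals.max()
    if not np.isfinite(best):
        raise DegenerateGeometryError("projected variance undefined for all angles")
    tied = candidates[vals >= best - abs(best) * 1e-9]
    return float(np.min(tied) % np.pi)


def optimal_orientation(
    location,
    cov: CovarianceEstimate,
    cfg: BeamformerConfig,
    basis_lead_fields,
    sigma: Optional[float] = None,
):
    """Tangential angle delta in [0, pi) maximizing projected output variance.

    ``basis_lead_fields`` is the (L1, L2) pair for the voxel's tangential
    basis.  Ties are broken toward smaller delta.  When the covariance has no
    source structure (C proportional to I) the maximizer is the minimum-norm
    lead-field direction, a known degenerate case: it is returned with a
    warning.
    """
    L1, L2 = (np.asarray(v, dtype=float).ravel() for v in basis_lead_fields)
    if np.linalg.norm(L1) < 1e-300 and np.linalg.norm(L2) < 1e-300:
        raise DegenerateGeometryError("both tangential lead fields are zero")
    if sigma is None:
        sigma = noise_floor(cov)
    c_inv = _regularized_inverse(cov, cfg.mu, sigma)
    A, D = _orientation_quadratics(L1, L2, c_inv, cov.C)

    eigvals = np.linalg.eigvalsh(cov.C)
    if eigvals[-1] - eigvals[0] <= 1e-10 * max(eigvals[-1], 1e-300):
        warnings.warn(
            "covariance has no source structure (C ~ c*I): orientation defaults "
            "to the minimum-norm lead-field direction",
            stacklevel=2,
        )

    return _best_delta(A, D)


def project(weights: WeightsVector, data: SensorTimeSeries, band=None) -> SourceEstimate:
    """Inner product of the weights with every data sample (Eq. of unit gain)."""
    if len(weights.values) != data.n_channels:
        raise ValueError(
            f"weights have {len(weights.values)} channels, data has {data.n_channels}"
        )
    return SourceEstimate(weights.values @ data.data, data.fs, band)


def scan_grid(
    grid: VoxelGrid,
    data: SensorTimeSeries,
    cfg: BeamformerConfig,
    array: SensorArray,
    conductor: ConductorModel,
    cov_window=None,
    basis_fields=None,
) -> GridWeights:
    """Weights and optimized orientation at every grid voxel for one band.

    The data are band-filtered (if ``cfg.band`` is set) before covariance
    estimation, so each band gets its own covariance, noise floor and weights.
    ``cov_window`` restricts the covariance estimate to a sample range
    (resting-only vs all-data policies).  ``basis_fields`` may carry the
    precomputed (L1, L2) tangential lead-field pair ((V, M) arrays each) to
    amortize the forward model over repeated scans (lead fields are
    band-independent).
    """
    if cfg.band is not None:
        filtered = SensorTimeSeries(fir_bandpass(data.data, cfg.band, data.fs), data.fs)
    else:
        filtered = data
    cov = estimate_covariance(filtered, cov_window)
    sigma = noise_floor(cov)
    c_inv = _regularized_inverse(cov, cfg.mu, sigma)

    n = grid.n_voxels
    m = data.n_channels
    weights = np.empty((n, m))
    deltas = np.empty(n)
    lead_fields = np.empty((n, m))
    if basis_fields is None:
        basis_fields = tangential_lead_fields_grid(array, conductor, grid.positions)
    all_l1, all_l2 = basis_fields
    for i in range(n):
        L1, L2 = all_l1[i], all_l2[i]
        A, D = _orientation_quadratics(L1, L2, c_inv, cov.C)
        best_d = _best_delta(A, D)
        deltas[i] = best_d
        L = np.cos(best_d) * L1 + np.sin(best_d) * L2
        ci_l = c_inv @ L
        weights[i] = ci_l / (L @ ci_l)
        lead_fields[i] = L
    return GridWeights(weights, deltas, grid, cov, sigma, cfg, lead_fields)


def variance_map(
    gw: GridWeights,
    cov: Optional[CovarianceEstimate] = None,
    normalize: bool = True,
) -> FCVolumetricMap:
    """Projected band variance per voxel.

    With ``normalize=True`` the variance is divided by the projected noise
    power sigma * W.W (a pseudo-Z).  The raw projected variance is depth
    biased: voxels with weak lead fields amplify sensor noise, so raw maps
    peak deep regardless of the sources; use raw only for diagnostics.
    """
    C = (cov or gw.covariance).C
    vals = np.einsum("vm,mn,vn->v", gw.weights, C, gw.weights)
    if normalize:
        vals = vals / (gw.sigma * np.einsum("vm,vm->v", gw.weights, gw.weights))
    return FCVolumetricMap(vals, gw.grid, {"kind": "variance", "normalized": normalize})


def pseudo_t_map(
    grid: VoxelGrid,
    data: SensorTimeSeries,
    active_window,
    control_window,
    cfg: BeamformerConfig,
    array: SensorArray,
    conductor: ConductorModel,
) -> FCVolumetricMap:
    """Noise-normalized active-vs-control projected-power contrast.

    Per voxel: (P_active - P_control) / (sigma * W.W), with weights computed
    from the covariance of both windows combined.  The normalization makes
    the map invariant to global data gain; only peak locations are
    interpreted, not magnitudes.
    """
    a0, a1 = int(active_window[0]), int(active_window[1])
    c0, c1 = int(control_window[0]), int(control_window[1])
    if a1 <= a0 or c1 <= c0:
        raise ValueError("active and control windows must be non-empty")
    if cfg.band is not None:
        filtered = SensorTimeSeries(fir_bandpass(data.data, cfg.band, data.fs), data.fs)
    else:
        filtered = data
    both = SensorTimeSeries(
        np.concatenate([filtered.data[:, a0:a1], filtered.data[:, c0:c1]], axis=1),
        data.fs,
    )
    cov_both = estimate_covariance(both)
    sigma = noise_floor(cov_both)
    c_inv = _regularized_inverse(cov_both, cfg.mu, sigma)
    cov_a = estimate_covariance(filtered, (a0, a1))
    cov_c = estimate_covariance(filtered, (c0, c1))

    vals = np.empty(grid.n_voxels)
    all_l1, all_l2 = tangential_lead_fields_grid(array, conductor, grid.positions)
    for i in range(grid.n_voxels):
        L1, L2 = all_l1[i], all_l2[i]
        A, D = _orientation_quadratics(L1, L2, c_inv, cov_both.C)
        d = _best_delta(A, D)
        L = np.cos(d) * L1 + np.sin(d) * L2
        ci_l = c_inv @ L
        w = ci_l / (L @ ci_l)
        p_a = float(w @ cov_a.C @ w)
        p_c = float(w @ cov_c.C @ w)
        vals[i] = (p_a - p_c) / (sigma * float(w @ w))
    return FCVolumetricMap(vals, grid, {"kind": "pseudo_t"})


def _abs_corr_rows(rows: np.ndarray, seed_row: np.ndarray) -> np.ndarray:
    seed = seed_row - seed_row.mean()
    s_norm = np.linalg.norm(seed)
    centered = rows - rows.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    vals = np.zeros(len(rows))
    ok = (norms > 0) & (s_norm > 0)
    if not ok.all():
        logger.warning(
            "%d zero-variance vectors in correlation map set to 0", int((~ok).sum())
        )
    if s_norm > 0:
        vals[ok] = np.abs(centered[ok] @ seed) / (norms[ok] * s_norm)
    return np.minimum(vals, 1.0)


def weights_correlation_map(seed_voxel: int, gw: GridWeights) -> FCVolumetricMap:
    """Absolute Pearson correlation between seed and every voxel's weights."""
    vals = _abs_corr_rows(gw.weights, gw.weights[seed_voxel])
    return FCVolumetricMap(vals, gw.grid, {"kind": "weights_correlation", "seed": seed_voxel})


def lead_field_correlation_map(seed_voxel: int, gw: GridWeights) -> FCVolumetricMap:
    """Absolute Pearson correlation between lead fields at optimized deltas."""
    if gw.lead_fields is None:
        raise ValueError("GridWeights carries no lead fields")
    vals = _abs_corr_rows(gw.lead_fields, gw.lead_fields[seed_voxel])
    return FCVolumetricMap(
        vals, gw.grid, {"kind": "lead_field_correlation", "seed": seed_voxel}
    )


def correlation_vs_distance(fc_map: FCVolumetricMap, seed_voxel: int):
    """(distance_mm, value) table sorted by distance then voxel index."""
    import pandas as pd

    dist = fc_map.grid.distances_from(seed_voxel)
    order = np.lexsort((np.arange(len(dist)), dist))
    return pd.DataFrame(
        {"distance_mm": dist[order], "value": fc_map.values[order]}
    ).reset_index(drop=True)


def volume_above(fc_map: FCVolumetricMap, threshold: float) -> float:
    """Volume (cm^3) of voxels with value strictly above ``threshold``."""
    count = int(np.sum(fc_map.values > threshold))
    return count * fc_map.grid.voxel_volume_cm3
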