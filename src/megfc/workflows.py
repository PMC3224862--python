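"""High-level analysis workflows combining the lower-level modules.

These are the end-to-end procedures exercised by the acceptance suite:
pair-level connectivity with simulation-based correction, and the band-wise
seed-to-all-voxels connectivity maps used for cross-modal comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .beamformer import (
    BeamformerConfig,
    compute_weights,
    estimate_covariance,
    noise_floor,
    optimal_orientation,
    scan_grid,
)
from .core import SensorTimeSeries, VoxelGrid, as_seed_sequence
from .fc_metrics import aec, band_coherence, band_icoh, cae
from .forward import ConductorModel, DipoleSpec, SensorArray, tangential_lead_fields
from .significance import NullEnsemble, simulate_pair_dataset, synth_sensor_noise
from .spectral import FrequencyBand, fir_bandpass, hilbert_envelope

__all__ = ["PairWeights", "pair_weights", "pair_metrics", "pair_null_ensembles",
           "cae_map"]


@dataclass
class PairWeights:
    """Beamformer weights and orientations for a seed/test location pair."""

    w_seed: np.ndarray
    w_test: np.ndarray
    delta_seed: float
    delta_test: float
    sigma: float
    band: FrequencyBand


def pair_weights(
    data: SensorTimeSeries,
    seed_location,
    test_location,
    band: FrequencyBand,
    array: SensorArray,
    conductor: ConductorModel,
    mu: float = 4.0,
    cov_window=None,
) -> PairWeights:
    """Band-specific weights at two locations with optimized orientations."""
    filtered = SensorTimeSeries(fir_bandpass(data.data, band, data.fs), data.fs)
    cov = estimate_covariance(filtered, cov_window)
    sigma = noise_floor(cov)
    cfg = BeamformerConfig(mu=mu, band=band)
    out = []
    for loc in (seed_location, test_location):
        basis = tangential_lead_fields(array, conductor, loc)
        delta = optimal_orientation(loc, cov, cfg, basis, sigma=sigma)
        L = np.cos(delta) * basis[0] + np.sin(delta) * basis[1]
        w = compute_weights(L, cov, cfg, sigma=sigma, location=loc, delta=delta)
        out.append((w.values, delta))
    return PairWeights(out[0][0], out[1][0], out[0][1], out[1][1], sigma, band)


def pair_metrics(
    data: SensorTimeSeries,
    pw: PairWeights,
    delta: float,
    window=None,
    metrics: Sequence[str] = ("aec", "cae", "coh", "icoh"),
) -> dict:
    """FC metrics between the two projected timecourses over ``window``."""
    if window is None:
        window = (0, data.n_samples)
    filtered = fir_bandpass(data.data, pw.band, data.fs)[:, window[0]: window[1]]
    x = pw.w_seed @ filtered
    y = pw.w_test @ filtered
    ex = hilbert_envelope(x, data.fs)
    ey = hilbert_envelope(y, data.fs)
    out = {}
    for m in metrics:
        if m == "aec":
            out[m] = aec(ex, ey, delta).value
        elif m == "cae":
            out[m] = cae(ex, ey, delta).value
        elif m == "coh":
            out[m] = band_coherence(x, y, delta, pw.band, data.fs).value
        elif m == "icoh":
            out[m] = band_icoh(x, y, delta, pw.band, data.fs).value
        else:
            raise ValueError(f"unknown metric {m!r}")
    return out


def pair_null_ensembles(
    seed_spec: DipoleSpec,
    test_spec: DipoleSpec,
    pw: PairWeights,
    delta: float,
    n_iter: int,
    rng_seed,
    array: SensorArray,
    conductor: ConductorModel,
    duration: float,
    fs: float,
    source_variances=(1.0, 1.0),
    noise_kwargs: Optional[dict] = None,
    metrics: Sequence[str] = ("aec", "cae", "coh", "icoh"),
) -> dict:
    """Null distributions of several metrics from shared uncoupled simulations.

    Every iteration simulates one uncoupled dataset, projects it through the
    fixed pair weights, and evaluates all requested metrics, so the metric
    nulls are directly comparable (same datasets).
    """
    noise_kwargs = noise_kwargs or {}
    ss = as_seed_sequence(rng_seed)
    values = {m: np.empty(n_iter) for m in metrics}
    for i, child in enumerate(ss.spawn(n_iter)):
        noise_seq, src_seq = child.spawn(2)
        noise = synth_sensor_noise(array, duration, fs, noise_seq, **noise_kwargs)
        sim = simulate_pair_dataset(
            seed_spec, test_spec, noise, pw.band, src_seq, array, conductor,
            source_variances,
        )
        x = pw.w_seed @ sim.data
        y = pw.w_test @ sim.data
        ex = hilbert_envelope(x, fs)
        ey = hilbert_envelope(y, fs)
        for m in metrics:
            if m == "aec":
                values[m][i] = aec(ex, ey, delta).value
            elif m == "cae":
                values[m][i] = cae(ex, ey, delta).value
            elif m == "coh":
                values[m][i] = band_coherence(x, y, delta, pw.band, fs).value
            elif m == "icoh":
                values[m][i] = band_icoh(x, y, delta, pw.band, fs).value
            else:
                raise ValueError(f"unknown metric {m!r}")
    return {m: NullEnsemble(m.upper(), v, rng_seed) for m, v in values.items()}


def cae_map(
    data: SensorTimeSeries,
    grid: VoxelGrid,
    seed_voxel: int,
    band: FrequencyBand,
    delta: float,
    array: SensorArray,
    conductor: ConductorModel,
    window=None,
    mu: float = 4.0,
    basis_fields=None,
):
    """Seed-to-all-voxels CAE map for one band (weights from full data).

    Returns (FCVolumetricMap, GridWeights).
    """
    from .core import FCVolumetricMap

    cfg = BeamformerConfig(mu=mu, band=band)
    gw = scan_grid(grid, data, cfg, array, conductor, basis_fields=basis_fields)
    filtered = fir_bandpass(data.data, band, data.fs)
    if window is not None:
        filtered = filtered[:, window[0]: window[1]]
    projected = gw.weights @ filtered
    # segment-averaged envelopes for every voxel at once
    from scipy.signal import hilbert as _hilbert

    env = np.abs(_hilbert(projected, axis=1))
    seg_len = int(round(delta * data.fs))
    n_seg = env.shape[1] // seg_len
    avg = env[:, : n_seg * seg_len].reshape(env.shape[0], n_seg, seg_len).mean(axis=2)
    seed = avg[seed_voxel] - avg[seed_voxel].mean()
    s_norm = np.linalg.norm(seed)
    centered = avg - avg.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    vals = np.zeros(grid.n_voxels)
    ok = norms > 0
    vals[ok] = centered[ok] @ seed / (norms[ok] * s_norm)
    return FCVolumetricMap(vals, grid, {"kind": "cae", "band": band.name}), gw
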