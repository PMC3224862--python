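"""Simulation-based null framework for connectivity significance.

Null datasets contain two dipolar sources with *uncorrelated* band-limited
Gaussian timecourses, mixed through the forward model and added to spatially
correlated sensor noise.  Any FC measured on such data is spurious by
construction (leakage, field spread or correlated noise), which is the basis
of every significance decision here:

* per-voxel null FC images with one simulated dataset per test voxel,
* the per-bin weights-correlation correction (bin width 0.05) applied
  identically to real and null maps,
* upper-fifth-percentile thresholding of the corrected null distribution,
* per-subject mean-corrected null pools with confidence limits, and
* exact (enumerative) Wilcoxon signed-rank statistics for small groups.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import stats
from scipy.signal import hilbert as signal_hilbert

from .beamformer import GridWeights
from .core import FCVolumetricMap, SensorTimeSeries, VoxelGrid, as_seed_sequence
from .fc_metrics import aec, band_coherence, band_icoh, cae
from .forward import ConductorModel, DipoleSpec, SensorArray, lead_field
from .spectral import FrequencyBand, fir_bandpass, hilbert_envelope

__all__ = [
    "NullEnsemble",
    "CorrectedFCMap",
    "SignificanceDecision",
    "colored_noise_source",
    "synth_sensor_noise",
    "simulate_pair_dataset",
    "pair_null_ensemble",
    "null_fc_image",
    "binned_correction",
    "percentile_threshold",
    "pair_confidence_limit",
    "exact_wilcoxon_signed_rank",
    "group_significance_map",
    "spectrum_matched_envelope_source",
]

logger = logging.getLogger(__name__)


@dataclass
class NullEnsemble:
    metric: str
    values: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()

    @property
    def n_iterations(self) -> int:
        return len(self.values)


@dataclass
class CorrectedFCMap:
    real: FCVolumetricMap
    null: FCVolumetricMap
    bin_width: float
    bin_means: dict = field(default_factory=dict)


@dataclass
class SignificanceDecision:
    procedure: str
    threshold: Optional[float] = None
    mask: Optional[np.ndarray] = None
    p_values: Optional[np.ndarray] = None
    detail: dict = field(default_factory=dict)


def colored_noise_source(
    band: FrequencyBand,
    target_variance: float,
    duration: float,
    fs: float,
    rng_seed,
) -> np.ndarray:
    """Gaussian noise colored to ``band``, rescaled to the exact variance."""
    rng = np.random.default_rng(rng_seed)
    n = int(round(duration * fs))
    white = rng.standard_normal(n)
    colored = fir_bandpass(white, band, fs)
    colored = colored - colored.mean()
    colored *= np.sqrt(target_variance / colored.var())
    return colored


def synth_sensor_noise(
    array: SensorArray,
    duration: float,
    fs: float,
    rng_seed,
    spatial_rank: int = 8,
    floor_fraction: float = 0.3,
    channel_variance: float = 2.5e-27,
    mixing_seed=None,
) -> SensorTimeSeries:
    """Spatially correlated Gaussian sensor noise (empty-room surrogate).

    A random rank-``spatial_rank`` mixing of latent white sources plus an
    independent white floor; ``floor_fraction`` of the per-channel variance
    comes from the floor, so the channel covariance is always full rank.
    Default channel variance corresponds to a 50 fT RMS noise level.

    ``mixing_seed`` pins the spatial mixing matrix independently of the
    temporal realization.  Null simulations must share the mixing with the
    dataset whose weights they are projected through: adaptive weights null
    the specific noise subspace they were trained on, and a per-iteration
    mixing would bias real-vs-null comparisons.
    """
    m = array.n_channels
    if spatial_rank > m:
        raise ValueError("spatial_rank cannot exceed the channel count")
    rng = np.random.default_rng(rng_seed)
    n = int(round(duration * fs))
    mix_rng = rng if mixing_seed is None else np.random.default_rng(mixing_seed)
    mixing = mix_rng.standard_normal((m, spatial_rank))
    # scale so the low-rank part contributes (1 - floor_fraction) of variance
    row_power = np.sum(mixing**2, axis=1).mean()
    mixing *= np.sqrt((1.0 - floor_fraction) * channel_variance / row_power)
    latent = rng.standard_normal((spatial_rank, n))
    floor = rng.standard_normal((m, n)) * np.sqrt(floor_fraction * channel_variance)
    return SensorTimeSeries(mixing @ latent + floor, fs)


def simulate_pair_dataset(
    seed_spec: DipoleSpec,
    test_spec: DipoleSpec,
    noise: SensorTimeSeries,
    band: FrequencyBand,
    rng_seed,
    array: SensorArray,
    conductor: ConductorModel,
    source_variances=(1.0, 1.0),
    duration: Optional[float] = None,
) -> SensorTimeSeries:
    """Two uncoupled band-limited dipoles through the forward model plus noise.

    ``source_variances`` are moment variances in (A·m)^2.  The two source
    timecourses are drawn from independent RNG streams, so they carry no
    built-in coupling.  ``duration`` defaults to the noise duration and must
    match it when given.
    """
    l_seed = lead_field(array, conductor, seed_spec).values
    l_test = lead_field(array, conductor, test_spec).values
    ss = as_seed_sequence(rng_seed)
    s_seed_seq, s_test_seq = ss.spawn(2)
    dur = noise.duration if duration is None else float(duration)
    s1 = colored_noise_source(band, source_variances[0], dur, noise.fs, s_seed_seq)
    s2 = colored_noise_source(band, source_variances[1], dur, noise.fs, s_test_seq)
    if len(s1) != noise.n_samples:
        raise ValueError("noise duration does not match the simulated sources")
    data = np.outer(l_seed, s1) + np.outer(l_test, s2) + noise.data
    return SensorTimeSeries(data, noise.fs)


def _metric_fn(metric: str) -> Callable:
    name = metric.lower()
    if name == "aec":
        return lambda x, y, delta, band, fs: aec(
            hilbert_envelope(x, fs), hilbert_envelope(y, fs), delta
        ).value
    if name == "cae":
        return lambda x, y, delta, band, fs: cae(
            hilbert_envelope(x, fs), hilbert_envelope(y, fs), delta
        ).value
    if name == "coh":
        return lambda x, y, delta, band, fs: band_coherence(x, y, delta, band, fs).value
    if name == "icoh":
        return lambda x, y, delta, band, fs: band_icoh(x, y, delta, band, fs).value
    raise ValueError(f"unknown metric {metric!r}")


def pair_null_ensemble(
    seed_spec: DipoleSpec,
    test_spec: DipoleSpec,
    w_seed: np.ndarray,
    w_test: np.ndarray,
    metric: str,
    delta: float,
    band: FrequencyBand,
    n_iter: int,
    rng_seed,
    array: SensorArray,
    conductor: ConductorModel,
    duration: float,
    fs: float,
    source_variances=(1.0, 1.0),
    noise_kwargs: Optional[dict] = None,
) -> NullEnsemble:
    """Null FC values for a fixed seed/test pair projected through fixed weights."""
    fn = _metric_fn(metric)
    noise_kwargs = noise_kwargs or {}
    ss = as_seed_sequence(rng_seed)
    values = np.empty(n_iter)
    for i, child in enumerate(ss.spawn(n_iter)):
        noise_seq, src_seq = child.spawn(2)
        noise = synth_sensor_noise(array, duration, fs, noise_seq, **noise_kwargs)
        data = simulate_pair_dataset(
            seed_spec, test_spec, noise, band, src_seq, array, conductor, source_variances
        )
        x = w_seed @ data.data
        y = w_test @ data.data
        values[i] = fn(x, y, delta, band, fs)
    return NullEnsemble(metric.upper(), values, rng_seed)


def null_fc_image(
    grid: VoxelGrid,
    seed_voxel: int,
    gw: GridWeights,
    metric: str,
    delta: float,
    band: FrequencyBand,
    rng_seed,
    array: SensorArray,
    conductor: ConductorModel,
    duration: float,
    fs: float,
    source_variances=(1.0, 1.0),
    n_iter: int = 1,
    noise_kwargs: Optional[dict] = None,
) -> FCVolumetricMap:
    """Null FC image: one simulated uncoupled dataset per test voxel.

    For each voxel, a dataset containing a source at the seed and a source at
    that voxel (orientations taken from the precomputed grid weights) is
    simulated and projected through the *same* weights used for real data;
    the metric between the two projections is the voxel's null value.
    """
    fn = _metric_fn(metric)
    noise_kwargs = noise_kwargs or {}
    w_seed = gw.weights[seed_voxel]
    seed_spec = DipoleSpec(grid.positions[seed_voxel], gw.deltas[seed_voxel])
    ss = as_seed_sequence(rng_seed)
    children = ss.spawn(grid.n_voxels)
    values = np.empty(grid.n_voxels)
    for v in range(grid.n_voxels):
        test_spec = DipoleSpec(grid.positions[v], gw.deltas[v])
        iter_vals = np.empty(n_iter)
        for j, it_seq in enumerate(children[v].spawn(n_iter)):
            noise_seq, src_seq = it_seq.spawn(2)
            noise = synth_sensor_noise(array, duration, fs, noise_seq, **noise_kwargs)
            data = simulate_pair_dataset(
                seed_spec, test_spec, noise, band, src_seq, array, conductor,
                source_variances,
            )
            x = w_seed @ data.data
            y = gw.weights[v] @ data.data
            iter_vals[j] = fn(x, y, delta, band, fs)
        values[v] = iter_vals.mean()
    return FCVolumetricMap(
        values, grid, {"kind": f"null_{metric.lower()}", "seed_voxel": seed_voxel,
                       "rng_seed": rng_seed, "n_iter": n_iter}
    )


def binned_correction(
    fc_map_real: FCVolumetricMap,
    fc_map_null: FCVolumetricMap,
    weights_corr_map: FCVolumetricMap,
    bin_width: float = 0.05,
) -> CorrectedFCMap:
    """Subtract the per-bin null mean (binned by weights correlation) from both maps.

    Voxels are binned by their weights correlation; the mean *null* FC within
    each bin is subtracted from both real and null values voxel by voxel.
    Voxels falling in empty bins use the nearest populated bin (logged).
    """
    for other in (fc_map_null, weights_corr_map):
        if not fc_map_real.grid.same_geometry(other.grid):
            raise ValueError("maps must share a grid")
    wc = np.clip(weights_corr_map.values, 0.0, 1.0)
    n_bins = int(np.ceil(1.0 / bin_width))
    idx = np.minimum((wc / bin_width).astype(int), n_bins - 1)
    bin_means = np.full(n_bins, np.nan)
    for b in range(n_bins):
        sel = idx == b
        if sel.any():
            bin_means[b] = fc_map_null.values[sel].mean()
    populated = np.flatnonzero(np.isfinite(bin_means))
    if populated.size == 0:
        raise ValueError("all weights-correlation bins are empty")
    missing = np.flatnonzero(~np.isfinite(bin_means))
    if missing.size:
        logger.info("binned_correction: %d empty bins fall back to nearest", len(missing))
        for b in missing:
            nearest = populated[np.argmin(np.abs(populated - b))]
            bin_means[b] = bin_means[nearest]
    correction = bin_means[idx]
    real = FCVolumetricMap(
        fc_map_real.values - correction, fc_map_real.grid,
        {**fc_map_real.provenance, "corrected": True},
    )
    null = FCVolumetricMap(
        fc_map_null.values - correction, fc_map_null.grid,
        {**fc_map_null.provenance, "corrected": True},
    )
    means = {b: float(bin_means[b]) for b in range(n_bins)}
    return CorrectedFCMap(real, null, bin_width, means)


def percentile_threshold(
    corrected_real, corrected_null, quantile: float = 0.95
) -> SignificanceDecision:
    """Flag real values above the given quantile of the corrected null values.

    The quantile uses linear interpolation between order statistics (numpy's
    default), stated explicitly because percentile conventions differ.
    """
    if not 0.0 < quantile < 1.0:
        raise ValueError("quantile must lie in (0, 1)")
    real = np.asarray(getattr(corrected_real, "values", corrected_real), float).ravel()
    null = np.asarray(getattr(corrected_null, "values", corrected_null), float).ravel()
    if null.size < 20:
        warnings.warn("null distribution has fewer than 20 values", stacklevel=2)
    thr = float(np.quantile(null, quantile, method="linear"))
    return SignificanceDecision(
        "percentile_single_subject",
        threshold=thr,
        mask=real > thr,
        detail={"quantile": quantile, "n_null": int(null.size)},
    )


def pair_confidence_limit(
    real_values: Sequence[float],
    null_ensembles: Sequence[NullEnsemble],
    level: float = 0.95,
) -> SignificanceDecision:
    """Group-level corrected value vs a concatenated mean-corrected null pool.

    Each subject's real value is corrected by that subject's null mean; the
    corrected values are averaged with a standard error.  Null values are
    mean-corrected per subject and concatenated (e.g. 6 x 100 = 600 points);
    the confidence limit is the ``level`` quantile of that pool.
    """
    if len(real_values) != len(null_ensembles):
        raise ValueError("one null ensemble per subject required")
    if len(real_values) < 2:
        raise ValueError("standard error needs at least 2 subjects")
    corrected = np.array(
        [r - e.values.mean() for r, e in zip(real_values, null_ensembles)]
    )
    pool = np.concatenate([e.values - e.values.mean() for e in null_ensembles])
    limit = float(np.quantile(pool, level, method="linear"))
    mean = float(corrected.mean())
    sem = float(corrected.std(ddof=1) / np.sqrt(len(corrected)))
    return SignificanceDecision(
        "confidence_limit_pair",
        threshold=limit,
        mask=np.array([mean > limit]),
        detail={
            "mean": mean,
            "sem": sem,
            "level": level,
            "n_pool": int(pool.size),
            "corrected_per_subject": corrected,
        },
    )


def _signed_rank_distribution(ranks: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Exact null distribution of W+ = sum of positively signed ranks.

    Equivalent to enumerating all 2^n sign assignments; implemented as a
    dynamic-programming convolution over doubled (integer) midranks.
    """
    doubled = np.round(ranks * 2).astype(int)
    total = doubled.sum()
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in doubled:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    support = np.arange(total + 1) / 2.0
    return support, counts


def exact_wilcoxon_signed_rank(differences) -> float:
    """Exact two-sided signed-rank p by full enumeration of sign assignments.

    Zero differences are dropped (standard convention); ties in |d| receive
    midranks.  Above n = 25 the normal approximation is used with a warning.
    ``p = 2 * min(P(W+ <= w), P(W+ >= w))`` capped at 1.
    """
    d = np.asarray(differences, dtype=float).ravel()
    nonzero = d[d != 0.0]
    if nonzero.size == 0:
        warnings.warn("all differences are zero; p = 1", stacklevel=2)
        return 1.0
    n = nonzero.size
    if n > 25:
        warnings.warn(
            "n > 25: using the normal approximation instead of enumeration",
            stacklevel=2,
        )
        return float(stats.wilcoxon(nonzero, mode="approx").pvalue)
    ranks = stats.rankdata(np.abs(nonzero))
    w_plus = float(ranks[nonzero > 0].sum())
    support, counts = _signed_rank_distribution(ranks)
    total = counts.sum()  # == 2^n
    p_le = counts[support <= w_plus + 1e-9].sum() / total
    p_ge = counts[support >= w_plus - 1e-9].sum() / total
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def group_significance_map(
    real_maps: Sequence[FCVolumetricMap],
    null_maps: Sequence[FCVolumetricMap],
    alpha: float = 0.05,
    bonferroni: bool = False,
) -> SignificanceDecision:
    """Per-voxel exact Wilcoxon signed-rank test of real vs null across subjects.

    No multiple-comparison correction by default; ``bonferroni=True`` divides
    alpha by the voxel count.
    """
    if len(real_maps) != len(null_maps) or len(real_maps) == 0:
        raise ValueError("equal, nonzero subject counts required")
    grid = real_maps[0].grid
    for m in list(real_maps) + list(null_maps):
        if not grid.same_geometry(m.grid):
            raise ValueError("all maps must share a grid")
    real = np.stack([m.values for m in real_maps])  # (S, V)
    null = np.stack([m.values for m in null_maps])
    diffs = real - null
    p = np.empty(grid.n_voxels)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for v in range(grid.n_voxels):
            p[v] = exact_wilcoxon_signed_rank(diffs[:, v])
    thr = alpha / grid.n_voxels if bonferroni else alpha
    return SignificanceDecision(
        "wilcoxon_group",
        threshold=thr,
        mask=p < thr,
        p_values=p,
        detail={"alpha": alpha, "bonferroni": bonferroni},
    )


def spectrum_matched_envelope_source(
    reference_envelope_spectrum: np.ndarray,
    band: FrequencyBand,
    duration: float,
    fs: float,
    rng_seed,
    n_iter: int = 25,
) -> np.ndarray:
    """Band-limited source whose Hilbert-envelope spectrum matches a reference.

    ``reference_envelope_spectrum`` is the one-sided power spectrum of the
    target envelope sampled at ``rfftfreq(n, 1/fs)`` (n = duration * fs).
    Envelope Fourier phases are randomized, so no coupling can be introduced
    between two independent draws.  The modulator amplitudes are iteratively
    re-imposed after positivity clipping and after measuring the envelope of
    the modulated carrier, so that carrier-induced envelope jitter is
    compensated.  Raises on an infeasible (negative-power) reference.
    """
    ref = np.asarray(reference_envelope_spectrum, dtype=float).ravel()
    if np.any(ref < 0):
        raise ValueError("reference envelope spectrum has negative power")
    n = int(round(duration * fs))
    if len(ref) != n // 2 + 1:
        raise ValueError("reference spectrum length must be n//2 + 1")
    rng = np.random.default_rng(rng_seed)
    carrier = colored_noise_source(band, 1.0, duration, fs, rng.integers(2**31))

    target_amp = np.sqrt(ref)
    phases = rng.uniform(0.0, 2.0 * np.pi, len(ref))
    phases[0] = 0.0
    spec = target_amp * np.exp(1j * phases)
    env = np.fft.irfft(spec, n=n)
    amp_adjust = target_amp.copy()
    for _ in range(n_iter):
        env = np.clip(env, 0.0, None)  # positivity of a modulator
        source = carrier * env
        # envelope of the product via the analytic signal
        measured = np.abs(np.fft.rfft(np.abs(signal_hilbert(source))))
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(measured > 0, target_amp / measured, 1.0)
        ratio = np.clip(ratio, 0.25, 4.0)
        amp_adjust = amp_adjust * ratio**0.5
        cur = np.fft.rfft(env)
        cur_amp = np.abs(cur)
        with np.errstate(divide="ignore", invalid="ignore"):
            cur = np.where(cur_amp > 0, cur / cur_amp, 1.0) * amp_adjust
        env = np.fft.irfft(cur, n=n)
    env = np.clip(env, 0.0, None)
    return carrier * env
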