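"""Synthetic inputs: sensor helmets, voxel grids, coupled dipole pairs,
resting + localizer experiments and matched 4-D "hemodynamic" volumes.

Every generator is a pure function of its parameters and RNG seed.

Coupled sources are band-limited carriers multiplied by slow positive
envelope modulators.  With coupling alpha, each source's modulator is
``alpha * shared + (1 - alpha) * private``; the carriers are always
independent, so envelope correlation can be high while phase coherence
remains at the null level (the envelope/phase dissociation).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .core import FourDVolume, SensorTimeSeries, VoxelGrid, as_seed_sequence
from .forward import ConductorModel, DipoleSpec, SensorArray, lead_field
from .significance import colored_noise_source, synth_sensor_noise
from .spectral import FrequencyBand, hilbert_envelope

__all__ = [
    "ExperimentRecipe",
    "GroundTruth",
    "make_sensor_array",
    "make_grid",
    "make_coupled_pair",
    "calibrate_coupling",
    "make_experiment",
    "make_hemodynamic_volume",
    "desk_recipe",
    "paper_recipe",
]


@dataclass
class ExperimentRecipe:
    """Parameters for a synthetic resting + localizer experiment."""

    fs: float = 300.0
    resting_duration: float = 100.0
    n_task_blocks: int = 0
    block_duration: float = 10.0
    band: FrequencyBand = dc_field(
        default_factory=lambda: FrequencyBand("beta_low", 13.0, 20.0)
    )
    coupling: float = 0.0
    source_locations: tuple = ((0.035, 0.0, 0.035), (-0.035, 0.0, 0.035))
    source_deltas: tuple = (0.3, 1.1)
    source_moment_rms: float = 2.0e-8  # A·m, tens of nA·m scale
    task_gain: float = 0.3  # band-power gain during "active" blocks (< 1: loss)
    noise_channel_variance: float = 2.5e-27
    noise_spatial_rank: int = 8
    noise_floor_fraction: float = 0.3
    # fixed spatial mixing of the noise (environment property); null
    # simulations must share it with the experiment they are compared to
    noise_mixing_seed: int = 7777
    modulator_bandwidth: float = 0.5  # Hz, envelope modulator smoothness
    modulation_depth: float = 1.0  # envelope modulation depth in [0, 1]

    def __post_init__(self) -> None:
        if not 0.0 <= self.coupling <= 1.0:
            raise ValueError("coupling must lie in [0, 1]")
        if self.n_task_blocks < 0 or self.block_duration <= 0:
            raise ValueError("invalid task phase settings")

    @property
    def total_duration(self) -> float:
        # each task block is an active period followed by an equal control period
        return self.resting_duration + 2 * self.n_task_blocks * self.block_duration

    def phases(self):
        """Sample ranges: resting, then alternating active/control blocks."""
        fs = self.fs
        r = int(round(self.resting_duration * fs))
        b = int(round(self.block_duration * fs))
        out = {"resting": (0, r), "active": [], "control": []}
        t = r
        for _ in range(self.n_task_blocks):
            out["active"].append((t, t + b))
            t += b
            out["control"].append((t, t + b))
            t += b
        return out


@dataclass
class GroundTruth:
    """Everything the generators know about a synthetic dataset."""

    source_timecourses: np.ndarray  # (2, T) moment timecourses, A·m
    envelopes: np.ndarray  # (2, T) modulator envelopes (mean ~ 1)
    coupling: float
    dipoles: Sequence[DipoleSpec]
    rng_seed: object
    expected_aec: Optional[float] = None
    extras: dict = dc_field(default_factory=dict)


def make_sensor_array(
    n_channels: int = 64, helmet_radius: float = 0.12, coverage: float = 0.45
) -> SensorArray:
    """Quasi-uniform radial magnetometers on a spherical cap (Fibonacci lattice).

    ``coverage`` is the fraction of the full sphere covered by the cap,
    measured from the +z pole downward.  Deterministic in its parameters.
    """
    if n_channels < 8:
        raise ValueError("need at least 8 channels")
    if not 0.0 < coverage <= 1.0:
        raise ValueError("coverage must lie in (0, 1]")
    golden = np.pi * (3.0 - np.sqrt(5.0))
    i = np.arange(n_channels)
    # z spans the cap: from the pole down to 1 - 2 * coverage
    z = 1.0 - (i + 0.5) / n_channels * 2.0 * coverage
    theta = golden * i
    rho = np.sqrt(np.maximum(0.0, 1.0 - z**2))
    units = np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])
    positions = helmet_radius * units
    return SensorArray(positions, units)


def make_grid(
    spacing_mm: float,
    conductor: ConductorModel,
    brain_radius: float = 0.08,
    margin: float = 0.0,
) -> VoxelGrid:
    """Regular lattice clipped to an inner sphere of ``brain_radius`` (m)."""
    if spacing_mm <= 0:
        raise ValueError("spacing must be positive")
    s = spacing_mm / 1000.0
    r_eff = brain_radius - margin
    half = int(np.floor(r_eff / s))
    coords = np.arange(-half, half + 1) * s
    nx = len(coords)
    xs, ys, zs = np.meshgrid(coords, coords, coords, indexing="ij")
    pts = np.column_stack([xs.ravel(), ys.ravel(), zs.ravel()]) + conductor.center
    radii = np.linalg.norm(pts - conductor.center, axis=1)
    # the lattice point at the exact sphere center has no tangential plane
    # (and a silent lead field), so it is excluded from the grid
    inside = (radii < r_eff) & (radii > 1e-9)
    mask = inside.reshape((nx, nx, nx))
    origin = conductor.center - half * s
    return VoxelGrid(pts[inside], spacing_mm, (nx, nx, nx), origin, mask)


def _positive_modulator(rng, n: int, fs: float, bandwidth: float) -> np.ndarray:
    """Slow positive mean-1 modulator: lowpassed Gaussian, rectified, smoothed."""
    sigma = fs / (2.0 * np.pi * bandwidth)
    slow = ndimage.gaussian_filter1d(rng.standard_normal(n), sigma, mode="wrap")
    m = ndimage.gaussian_filter1d(np.abs(slow), sigma / 4.0, mode="wrap")
    return m / m.mean()


def make_coupled_pair(
    band: FrequencyBand,
    alpha: float,
    duration: float,
    fs: float,
    rng_seed,
    variances=(1.0, 1.0),
    modulator_bandwidth: float = 0.5,
    modulation_depth: float = 1.0,
):
    """Two band-limited sources with envelope coupling ``alpha`` in [0, 1].

    alpha = 0 gives independent sources; alpha = 1 gives identical envelope
    modulators on independent carriers (high envelope correlation, null
    phase coherence).  ``modulation_depth`` shrinks the modulators toward
    their mean (1): depth 1 is full modulation, depth 0 a stationary source.
    Moderate depths keep the envelope kurtosis realistic; full-depth shared
    modulation measurably inflates the pooled-|coherence| sampling floor.
    Returns (s1, s2, GroundTruth); sources are rescaled to the exact
    requested variances.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    if not 0.0 <= modulation_depth <= 1.0:
        raise ValueError("modulation_depth must lie in [0, 1]")
    ss = as_seed_sequence(rng_seed)
    kids = ss.spawn(5)
    n = int(round(duration * fs))
    rngs = [np.random.default_rng(k) for k in kids[:3]]
    shared = _positive_modulator(rngs[0], n, fs, modulator_bandwidth)
    priv1 = _positive_modulator(rngs[1], n, fs, modulator_bandwidth)
    priv2 = _positive_modulator(rngs[2], n, fs, modulator_bandwidth)
    env1 = 1.0 + modulation_depth * (alpha * shared + (1.0 - alpha) * priv1 - 1.0)
    env2 = 1.0 + modulation_depth * (alpha * shared + (1.0 - alpha) * priv2 - 1.0)
    c1 = colored_noise_source(band, 1.0, duration, fs, kids[3])
    c2 = colored_noise_source(band, 1.0, duration, fs, kids[4])
    s1 = c1 * env1
    s2 = c2 * env2
    s1 *= np.sqrt(variances[0] / s1.var())
    s2 *= np.sqrt(variances[1] / s2.var())
    gt = GroundTruth(
        source_timecourses=np.vstack([s1, s2]),
        envelopes=np.vstack([env1, env2]),
        coupling=alpha,
        dipoles=(),
        rng_seed=rng_seed,
    )
    return s1, s2, gt


def _settings_key(**kwargs) -> str:
    blob = json.dumps(
        {k: repr(v) for k, v in sorted(kwargs.items())}, sort_keys=True
    ).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def calibrate_coupling(
    band: FrequencyBand,
    delta: float,
    duration: float,
    fs: float,
    alphas: Sequence[float],
    n_rep: int,
    rng_seed,
    modulator_bandwidth: float = 0.5,
    modulation_depth: float = 1.0,
    cache_path=None,
):
    """Monte-Carlo table mapping coupling alpha to expected source-level AEC.

    Returns a dict with ``alpha``, ``mean_aec`` and ``sem_aec`` arrays.  If a
    ``cache_path`` is given the table is stored keyed by a settings hash and
    reruns are bit-identical loads.
    """
    from .fc_metrics import aec as _aec

    if n_rep < 10:
        raise ValueError("n_rep must be at least 10")
    key = _settings_key(
        band=(band.f_lo, band.f_hi), delta=delta, duration=duration, fs=fs,
        alphas=tuple(alphas), n_rep=n_rep, rng_seed=rng_seed,
        bw=modulator_bandwidth, depth=modulation_depth,
    )
    if cache_path is not None:
        try:
            with open(cache_path) as fh:
                cache = json.load(fh)
            if key in cache:
                entry = cache[key]
                return {k: np.array(v) for k, v in entry.items()}
        except (OSError, json.JSONDecodeError):
            cache = {}
    ss = as_seed_sequence(rng_seed)
    means, sems = [], []
    for alpha in alphas:
        vals = []
        for child in ss.spawn(n_rep):
            s1, s2, _ = make_coupled_pair(
                band, alpha, duration, fs, child,
                modulator_bandwidth=modulator_bandwidth,
                modulation_depth=modulation_depth,
            )
            e1 = hilbert_envelope(s1, fs)
            e2 = hilbert_envelope(s2, fs)
            vals.append(_aec(e1, e2, delta).value)
        vals = np.asarray(vals)
        means.append(vals.mean())
        sems.append(vals.std(ddof=1) / np.sqrt(n_rep))
    table = {
        "alpha": np.asarray(list(alphas), dtype=float),
        "mean_aec": np.asarray(means),
        "sem_aec": np.asarray(sems),
    }
    if cache_path is not None:
        try:
            with open(cache_path) as fh:
                cache = json.load(fh)
        except (OSError, json.JSONDecodeError):
            cache = {}
        cache[key] = {k: v.tolist() for k, v in table.items()}
        with open(cache_path, "w") as fh:
            json.dump(cache, fh)
    return table


def make_experiment(
    recipe: ExperimentRecipe, array: SensorArray, conductor: ConductorModel, rng_seed
):
    """Full synthetic experiment: resting coupled pair + localizer task blocks.

    During "active" blocks the band-limited source moments are scaled by
    ``recipe.task_gain`` (a gain < 1 emulates a task-induced band power
    loss).  Spatially correlated sensor noise is added throughout.  Returns
    (SensorTimeSeries, GroundTruth).
    """
    ss = as_seed_sequence(rng_seed)
    pair_seq, noise_seq = ss.spawn(2)
    dur = recipe.total_duration
    v = recipe.source_moment_rms**2
    s1, s2, gt = make_coupled_pair(
        recipe.band, recipe.coupling, dur, recipe.fs, pair_seq,
        variances=(v, v), modulator_bandwidth=recipe.modulator_bandwidth,
        modulation_depth=recipe.modulation_depth,
    )
    gain = np.ones(int(round(dur * recipe.fs)))
    phases = recipe.phases()
    for a0, a1 in phases["active"]:
        gain[a0:a1] = recipe.task_gain
    sources = np.vstack([s1 * gain, s2 * gain])

    dipoles = tuple(
        DipoleSpec(np.asarray(loc), d)
        for loc, d in zip(recipe.source_locations, recipe.source_deltas)
    )
    lf = np.vstack(
        [lead_field(array, conductor, dip).values for dip in dipoles]
    )  # (2, M)
    noise = synth_sensor_noise(
        array, dur, recipe.fs, noise_seq,
        spatial_rank=recipe.noise_spatial_rank,
        floor_fraction=recipe.noise_floor_fraction,
        channel_variance=recipe.noise_channel_variance,
        mixing_seed=recipe.noise_mixing_seed,
    )
    data = SensorTimeSeries(lf.T @ sources + noise.data, recipe.fs)
    gt.dipoles = dipoles
    gt.source_timecourses = sources
    gt.extras = {
        "phases": phases,
        "recipe_gain": recipe.task_gain,
        "noise_kwargs": {
            "spatial_rank": recipe.noise_spatial_rank,
            "floor_fraction": recipe.noise_floor_fraction,
            "channel_variance": recipe.noise_channel_variance,
            "mixing_seed": recipe.noise_mixing_seed,
        },
    }
    return data, gt


def make_hemodynamic_volume(
    grid: VoxelGrid,
    source_locations,
    coupling: float,
    tr: float,
    duration: float,
    rng_seed,
    blob_fwhm_mm: float = 20.0,
    noise_sd: float = 0.5,
    smooth_noise_fwhm_mm: float = 10.0,
    blob_timecourses: Optional[np.ndarray] = None,
) -> FourDVolume:
    """Synthetic 4-D volume: coupled Gaussian blobs plus smooth background noise.

    Each blob's timecourse shares a slow common component scaled by
    ``coupling`` (or, if ``blob_timecourses`` is given, uses those directly,
    e.g. ground-truth envelopes resampled at the TR).
    """
    if tr <= 0:
        raise ValueError("TR must be positive")
    rng = np.random.default_rng(as_seed_sequence(rng_seed))
    n_t = int(round(duration / tr))
    locs = np.atleast_2d(np.asarray(source_locations, dtype=float))
    n_blob = len(locs)
    if blob_timecourses is None:
        shared = ndimage.gaussian_filter1d(
            rng.standard_normal(n_t), max(1.0, 0.05 * n_t), mode="wrap"
        )
        tcs = []
        for _ in range(n_blob):
            priv = ndimage.gaussian_filter1d(
                rng.standard_normal(n_t), max(1.0, 0.05 * n_t), mode="wrap"
            )
            tc = np.sqrt(coupling) * shared + np.sqrt(1.0 - coupling) * priv
            tcs.append(tc / max(tc.std(), 1e-12))
        tcs = np.vstack(tcs)
    else:
        tcs = np.atleast_2d(np.asarray(blob_timecourses, dtype=float))[:, :n_t]
        tcs = (tcs - tcs.mean(axis=1, keepdims=True)) / tcs.std(axis=1, keepdims=True)
        if tcs.shape != (n_blob, n_t):
            raise ValueError("blob_timecourses must be (n_blobs, n_timepoints)")

    sigma_m = blob_fwhm_mm * 1e-3 / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    data = np.zeros((grid.n_voxels, n_t))
    for loc, tc in zip(locs, tcs):
        d = np.linalg.norm(grid.positions - loc, axis=1)
        profile = np.exp(-0.5 * (d / sigma_m) ** 2)
        data += np.outer(profile, tc)

    # spatially smooth background noise, frame by frame on the bounding box
    sigma_vox = smooth_noise_fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / grid.spacing_mm
    for t in range(n_t):
        frame = rng.standard_normal(grid.shape)
        frame = ndimage.gaussian_filter(frame, sigma_vox, mode="constant")
        frame /= max(frame[grid.mask].std(), 1e-12)
        data[:, t] += noise_sd * frame[grid.mask]
    return FourDVolume(data, grid, tr)


def desk_recipe(**overrides) -> ExperimentRecipe:
    """Small default recipe suitable for CI-scale runs."""
    return ExperimentRecipe(**overrides)


def paper_recipe(**overrides) -> ExperimentRecipe:
    """Acquisition-faithful recipe: 275 channels equivalent, 300 s at 600 Hz.

    Use with ``make_sensor_array(275, 0.12)`` and a 5 mm grid; expensive.
    """
    params = dict(fs=600.0, resting_duration=300.0, n_task_blocks=6, block_duration=30.0)
    params.update(overrides)
    return ExperimentRecipe(**params)
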