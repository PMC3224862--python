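"""Connectivity metrics between a seed and a test timecourse.

Four metrics are provided:

* ``aec`` — mean across segments of per-segment Pearson correlation between
  Hilbert envelopes ("averaged envelope correlation").
* ``cae`` — Pearson correlation between the two segment-averaged envelopes
  ("correlation of averaged envelopes").
* ``band_coherence`` / ``band_icoh`` — per-segment magnitude (resp. absolute
  imaginary part) of the band-pooled normalized cross-spectrum, averaged
  across segments.

A single per-bin coherence is trivially unit modulus, so the cross- and
auto-spectra are pooled over all DFT bins inside the band *within* a segment
before normalization, and the resulting per-segment values are averaged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .spectral import EnvelopeSeries, FrequencyBand, segment

__all__ = [
    "FCMetricResult",
    "FCTimecourse",
    "aec",
    "cae",
    "band_coherence",
    "band_icoh",
    "fc_timecourse",
    "metric_timecourse_correlation",
]

logger = logging.getLogger(__name__)


@dataclass
class FCMetricResult:
    metric: str
    value: float
    per_segment: Optional[np.ndarray]
    delta: float
    band: Optional[str] = None
    n_dropped: int = 0
    seed_id: Optional[str] = None
    test_id: Optional[str] = None


@dataclass
class FCTimecourse:
    """Ordered per-segment metric values with segment length ``delta`` (s)."""

    values: np.ndarray
    delta: float
    metric: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()

    @property
    def n(self) -> int:
        return len(self.values)

    def times(self) -> np.ndarray:
        """Segment-center times (s) relative to the analysed window start."""
        return (np.arange(self.n) + 0.5) * self.delta


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    x = x - x.mean()
    y = y - y.mean()
    sx = np.sqrt(np.dot(x, x))
    sy = np.sqrt(np.dot(y, y))
    if sx == 0.0 or sy == 0.0:
        return np.nan
    return float(np.dot(x, y) / (sx * sy))


def _as_values(env, fs):
    if isinstance(env, EnvelopeSeries):
        return env.values, env.fs
    if fs is None:
        raise ValueError("fs required when passing bare arrays")
    return np.asarray(env, dtype=float).ravel(), fs


def aec(env_seed, env_test, delta: float, fs: float | None = None) -> FCMetricResult:
    """Averaged envelope correlation: per-segment Pearson r, mean of segments.

    Segments in which either envelope has zero variance are excluded from the
    mean; the number excluded is reported in ``n_dropped``.
    """
    x, fs_x = _as_values(env_seed, fs)
    y, fs_y = _as_values(env_test, fs)
    if len(x) != len(y) or fs_x != fs_y:
        raise ValueError("envelopes must share length and sampling rate")
    segs_x = segment(x, delta, fs_x)
    segs_y = segment(y, delta, fs_x)
    if segs_x.shape[1] < 3:
        raise ValueError("segments must contain at least 3 samples")
    per = np.array([_pearson(a, b) for a, b in zip(segs_x, segs_y)])
    good = np.isfinite(per)
    n_dropped = int((~good).sum())
    if n_dropped:
        logger.warning("aec: %d zero-variance segments excluded", n_dropped)
    if not good.any():
        raise ValueError("all segments had zero variance")
    return FCMetricResult("AEC", float(per[good].mean()), per, delta, n_dropped=n_dropped)


def cae(env_seed, env_test, delta: float, fs: float | None = None) -> FCMetricResult:
    """Correlation of averaged envelopes: one Pearson r over n segment means."""
    x, fs_x = _as_values(env_seed, fs)
    y, fs_y = _as_values(env_test, fs)
    if len(x) != len(y) or fs_x != fs_y:
        raise ValueError("envelopes must share length and sampling rate")
    ax = segment(x, delta, fs_x).mean(axis=1)
    ay = segment(y, delta, fs_x).mean(axis=1)
    if len(ax) < 3:
        raise ValueError("CAE needs at least 3 segments")
    return FCMetricResult("CAE", _pearson(ax, ay), None, delta)


def _band_bins(seg_len: int, fs: float, band: FrequencyBand) -> np.ndarray:
    freqs = np.fft.rfftfreq(seg_len, d=1.0 / fs)
    sel = (freqs >= band.f_lo) & (freqs <= band.f_hi)
    if not sel.any():
        raise ValueError(
            f"no DFT bin falls inside {band.name} for this segment length; "
            f"use delta >= {1.0 / (band.f_hi - band.f_lo):.3g} s"
        )
    return sel


def _pooled_cross_spectra(ts_seed, ts_test, delta, band, fs):
    x = np.asarray(ts_seed, dtype=float).ravel()
    y = np.asarray(ts_test, dtype=float).ravel()
    if len(x) != len(y):
        raise ValueError("timecourses must have equal length")
    segs_x = segment(x, delta, fs)
    segs_y = segment(y, delta, fs)
    sel = _band_bins(segs_x.shape[1], fs, band)
    fx = np.fft.rfft(segs_x, axis=1)[:, sel]
    fy = np.fft.rfft(segs_y, axis=1)[:, sel]
    # cross- and autospectra from explicit real/imaginary components: the
    # compiler's fused complex multiply leaves a nonzero imaginary residue on
    # x * conj(x), whereas the component form makes Coh(x, x) = 1 and
    # ICoh(x, x) = 0 hold exactly in floating point
    re = np.sum(fx.real * fy.real + fx.imag * fy.imag, axis=1)
    im = np.sum(fx.imag * fy.real - fx.real * fy.imag, axis=1)
    sxy = re + 1j * im
    sxx = np.sum(fx.real * fx.real + fx.imag * fx.imag, axis=1)
    syy = np.sum(fy.real * fy.real + fy.imag * fy.imag, axis=1)
    denom = np.sqrt(sxx * syy)
    if np.any(denom == 0.0):
        raise ValueError("zero in-band power in at least one segment")
    return sxy, denom


def band_coherence(ts_seed, ts_test, delta, band: FrequencyBand, fs) -> FCMetricResult:
    """Band-pooled coherence per segment, averaged across segments."""
    sxy, denom = _pooled_cross_spectra(ts_seed, ts_test, delta, band, fs)
    per = np.abs(sxy) / denom
    return FCMetricResult("Coh", float(per.mean()), per, delta, band=band.name)


def band_icoh(
    ts_seed, ts_test, delta, band: FrequencyBand, fs, signed: bool = False
) -> FCMetricResult:
    """Band-pooled imaginary coherence per segment, averaged across segments.

    By default the absolute value is taken per segment before averaging
    (magnitude of lagged interaction, not directionality); ``signed=True``
    averages the signed imaginary parts instead.
    """
    sxy, denom = _pooled_cross_spectra(ts_seed, ts_test, delta, band, fs)
    per = np.imag(sxy) / denom
    if not signed:
        per = np.abs(per)
    return FCMetricResult("ICoh", float(per.mean()), per, delta, band=band.name)


def fc_timecourse(
    metric: str,
    seed,
    test,
    delta: float,
    fs: float | None = None,
    band: FrequencyBand | None = None,
) -> FCTimecourse:
    """Per-segment metric values in temporal order.

    ``metric`` is one of ``aec``, ``coh``, ``icoh``.  CAE collapses each
    segment to a single number and therefore has no per-segment timecourse.
    """
    name = metric.lower()
    if name == "cae":
        raise ValueError(
            "CAE has no per-segment timecourse: it is a single correlation "
            "across segment-averaged envelopes"
        )
    if name == "aec":
        res = aec(seed, test, delta, fs)
    elif name == "coh":
        res = band_coherence(seed, test, delta, band, fs)
    elif name == "icoh":
        res = band_icoh(seed, test, delta, band, fs)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return FCTimecourse(res.per_segment, delta, res.metric)


def metric_timecourse_correlation(tc1: FCTimecourse, tc2: FCTimecourse) -> float:
    """Pearson correlation between two FC timecourses on the same segmentation."""
    if tc1.n != tc2.n or tc1.delta != tc2.delta:
        raise ValueError("timecourses must share segmentation (n and delta)")
    if tc1.n < 3:
        raise ValueError("need at least 3 segments")
    return _pearson(tc1.values, tc2.values)
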