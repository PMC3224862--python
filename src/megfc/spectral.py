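"""Band filtering, Hilbert envelopes and segmentation.

Filtering is windowed-sinc FIR applied forward-backward (zero phase).  The
filter order is chosen per band so that a tone one octave below the lower
band edge is attenuated by at least 40 dB after the two passes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

__all__ = [
    "FrequencyBand",
    "SegmentScheme",
    "EnvelopeSeries",
    "DEFAULT_BANDS",
    "HIGH_GAMMA_SPLIT",
    "fir_bandpass",
    "hilbert_envelope",
    "segment",
    "averaged_envelope",
]


@dataclass(frozen=True)
class FrequencyBand:
    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not 0.0 < self.f_lo < self.f_hi:
            raise ValueError("band edges must satisfy 0 < f_lo < f_hi")

    def validate_fs(self, fs: float) -> None:
        if self.f_hi >= fs / 2.0:
            raise ValueError(
                f"band {self.name} upper edge {self.f_hi} Hz is at or beyond "
                f"Nyquist ({fs / 2.0} Hz)"
            )


#: The seven canonical analysis bands.
DEFAULT_BANDS = {
    "delta": FrequencyBand("delta", 1.0, 4.0),
    "theta": FrequencyBand("theta", 4.0, 8.0),
    "alpha": FrequencyBand("alpha", 8.0, 13.0),
    "beta_low": FrequencyBand("beta_low", 13.0, 20.0),
    "beta_high": FrequencyBand("beta_high", 20.0, 30.0),
    "gamma_low": FrequencyBand("gamma_low", 30.0, 40.0),
    "gamma_high": FrequencyBand("gamma_high", 40.0, 70.0),
}

#: Optional split of the 40-70 Hz band used for finer frequency profiles.
HIGH_GAMMA_SPLIT = {
    "gamma_high_a": FrequencyBand("gamma_high_a", 40.0, 50.0),
    "gamma_high_b": FrequencyBand("gamma_high_b", 50.0, 70.0),
}

#: Wider band used for the motor localizer contrast.
BETA_WIDE = FrequencyBand("beta", 13.0, 30.0)


@dataclass(frozen=True)
class SegmentScheme:
    """Equal-length segmentation: length ``delta`` seconds, optional edge trim."""

    delta: float
    edge_trim: float = 0.0

    def n_segments(self, n_samples: int, fs: float) -> int:
        usable = n_samples - 2 * int(round(self.edge_trim * fs))
        n = int(usable // int(round(self.delta * fs)))
        if n < 1:
            raise ValueError("segment length exceeds usable duration")
        return n


@dataclass
class EnvelopeSeries:
    """Nonnegative envelope timecourse with its sampling rate."""

    values: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if np.any(self.values < 0):
            raise ValueError("envelope values must be nonnegative")


def _design_fir(band: FrequencyBand, fs: float) -> np.ndarray:
    # transition width: reach full stopband attenuation one octave below f_lo
    trans = min(band.f_lo / 2.0, (band.f_hi - band.f_lo)) if band.f_lo > 0 else 1.0
    trans = min(trans, fs / 2.0 - band.f_hi)
    numtaps = int(np.ceil(3.3 * fs / trans))
    numtaps += 1 - numtaps % 2  # odd length, linear phase type I
    return signal.firwin(
        numtaps, [band.f_lo, band.f_hi], pass_zero=False, fs=fs, window="hamming"
    )


def fir_bandpass(ts: np.ndarray, band: FrequencyBand, fs: float) -> np.ndarray:
    """Zero-phase FIR bandpass.  Accepts 1-D (T,) or 2-D (channels, T) input."""
    band.validate_fs(fs)
    ts = np.asarray(ts, dtype=float)
    taps = _design_fir(band, fs)
    padlen = min(3 * len(taps), ts.shape[-1] - 1)
    return signal.filtfilt(taps, [1.0], ts, axis=-1, padlen=padlen)


def hilbert_envelope(ts: np.ndarray, fs: float) -> EnvelopeSeries:
    """Modulus of the analytic signal of ``ts`` (1-D)."""
    ts = np.asarray(ts, dtype=float).ravel()
    if not np.all(np.isfinite(ts)):
        raise ValueError("input must be finite")
    return EnvelopeSeries(np.abs(signal.hilbert(ts)), fs)


def trim_edges(values: np.ndarray, fs: float, edge_trim: float) -> np.ndarray:
    """Discard ``edge_trim`` seconds at each end (envelope edge artifacts)."""
    k = int(round(edge_trim * fs))
    if k == 0:
        return np.asarray(values)
    if 2 * k >= len(values):
        raise ValueError("edge trim longer than the signal")
    return np.asarray(values)[k:-k]


def segment(ts: np.ndarray, delta: float, fs: float) -> np.ndarray:
    """Split ``ts`` into contiguous segments of ``delta`` s; drop the remainder.

    Returns an (n, seg_len) array.
    """
    ts = np.asarray(ts, dtype=float).ravel()
    seg_len = int(round(delta * fs))
    if seg_len < 1:
        raise ValueError("segment length below one sample")
    n = len(ts) // seg_len
    if n < 1:
        raise ValueError(
            f"segment length {delta} s exceeds signal duration {len(ts) / fs} s"
        )
    return ts[: n * seg_len].reshape(n, seg_len)


def averaged_envelope(env, delta: float, fs: float | None = None) -> np.ndarray:
    """Per-segment mean of an envelope: the n-point 'averaged envelope'."""
    if isinstance(env, EnvelopeSeries):
        values, fs = env.values, env.fs
    else:
        if fs is None:
            raise ValueError("fs required when passing a bare array")
        values = np.asarray(env, dtype=float)
    return segment(values, delta, fs).mean(axis=1)
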