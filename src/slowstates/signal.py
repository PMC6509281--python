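"""Filtering, resampling, synchronization index, Hilbert phase, running
statistics, and Gaussian-kernel firing-rate estimation.

All filters are applied forward-backward (zero phase) so spike and state
transition timing is preserved.  Elliptic designs default to order 4, 0.1 dB
passband ripple and 40 dB stopband attenuation; they are realized as
second-order sections for numerical stability at the very low normalized
cutoffs the delta bands require.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .core import SpikeTrain, TimeSeries

__all__ = [
    "PhaseTrace", "RateTrace",
    "elliptic_filter", "downsample", "synchronization_index",
    "hilbert_phase", "running_rms", "moving_average", "kernel_ifr",
]


@dataclass(frozen=True)
class PhaseTrace:
    """Instantaneous phase per sample, radians wrapped to [-pi, pi)."""

    phase: np.ndarray
    rate: float
    band: tuple[float, float]
    t0: float = 0.0

    def __post_init__(self) -> None:
        phase = np.asarray(self.phase, dtype=float)
        object.__setattr__(self, "phase", phase)
        if np.any(np.abs(phase) > np.pi + 1e-12):
            raise ValueError("phase must be wrapped to [-pi, pi)")

    def __len__(self) -> int:
        return self.phase.size

    def at_times(self, t: np.ndarray) -> np.ndarray:
        """Phase at arbitrary times (nearest-sample lookup)."""
        idx = np.clip(np.round((np.asarray(t) - self.t0) * self.rate).astype(int),
                      0, self.phase.size - 1)
        return self.phase[idx]


@dataclass(frozen=True)
class RateTrace:
    """Instantaneous firing rate (spikes/s) on a uniform grid."""

    values: np.ndarray
    rate: float          # sampling rate of the grid, Hz
    kernel_sd: float     # s
    source: str = ""
    t0: float = 0.0

    def __len__(self) -> int:
        return self.values.size


def _ellip_sos(kind: str, edges, rate: float, order: int = 4,
               ripple_db: float = 0.1, stop_db: float = 40.0) -> np.ndarray:
    nyq = rate / 2.0
    edges = np.atleast_1d(np.asarray(edges, dtype=float))
    if np.any(edges >= nyq):
        raise ValueError(f"filter edge {edges.max()} Hz >= Nyquist {nyq} Hz")
    if kind == "band" and edges[0] <= 0:
        # a band anchored at DC is a low-pass
        kind, edges = "low", edges[1:]
    wn = edges / nyq
    btype = {"low": "lowpass", "high": "highpass", "band": "bandpass"}[kind]
    return sps.ellip(order, ripple_db, stop_db, wn if wn.size > 1 else wn[0],
                     btype=btype, output="sos")


def elliptic_filter(ts: TimeSeries, kind: str, edges, order: int = 4,
                    ripple_db: float = 0.1, stop_db: float = 40.0) -> TimeSeries:
    """Zero-phase elliptic filter (``kind`` in {"low", "high", "band"}).

    Length is preserved; edges at or above Nyquist raise.
    """
    sos = _ellip_sos(kind, edges, ts.rate, order, ripple_db, stop_db)
    out = sps.sosfiltfilt(sos, ts.samples)
    return ts.with_samples(out)


def downsample(ts: TimeSeries, target_rate: float) -> TimeSeries:
    """Anti-alias filter then decimate to ``target_rate`` (must divide rate)."""
    ratio = ts.rate / target_rate
    q = int(round(ratio))
    if abs(ratio - q) > 1e-9 or q < 1:
        raise ValueError(f"target rate {target_rate} does not divide {ts.rate}")
    if q == 1:
        return ts
    filtered = elliptic_filter(ts, "low", 0.45 * target_rate)
    return ts.with_samples(filtered.samples[::q], rate=target_rate)


def synchronization_index(ts: TimeSeries, trial_len: float = 5.0,
                          low_band=(0.1, 4.0), high_band=(4.0, 100.0),
                          ) -> np.ndarray:
    """Low-/high-band power ratio per consecutive trial.

    Welch PSD (2-s Hann segments, 50% overlap) within each ``trial_len``
    window; the index is band power in ``low_band`` over ``high_band``.
    Values > 4 mark synchronized (slow-oscillation) epochs.  A trailing
    partial trial is skipped with a warning.
    """
    n_trial = int(round(trial_len * ts.rate))
    n_full = ts.samples.size // n_trial
    if n_full == 0:
        warnings.warn("trace shorter than one trial; no index computed")
        return np.empty(0)
    if ts.samples.size % n_trial:
        warnings.warn("trailing partial trial skipped")
    nperseg = min(int(round(2.0 * ts.rate)), n_trial)
    out = np.empty(n_full)
    for i in range(n_full):
        seg = ts.samples[i * n_trial:(i + 1) * n_trial]
        f, pxx = sps.welch(seg, fs=ts.rate, window="hann", nperseg=nperseg,
                           noverlap=nperseg // 2)
        low = _band_power(f, pxx, low_band)
        high = _band_power(f, pxx, high_band)
        out[i] = low / high if high > 0 else np.inf
    return out


def _band_power(f: np.ndarray, pxx: np.ndarray, band) -> float:
    """Integrate a PSD over a band, interpolating at the band edges."""
    lo, hi = band
    inside = (f > lo) & (f < hi)
    fb = np.concatenate(([lo], f[inside], [hi]))
    pb = np.concatenate(([np.interp(lo, f, pxx)], pxx[inside],
                         [np.interp(hi, f, pxx)]))
    return float(np.trapezoid(pb, fb))


def hilbert_phase(ts: TimeSeries, band=(0.1, 4.0)) -> PhaseTrace:
    """Instantaneous phase as the angle of the analytic (Hilbert) signal
    of the band-filtered trace.

    Phase is 0 at positive peaks of the filtered signal.  The trace should
    be at least ~10 s long; shorter traces are dominated by edge effects.
    """
    if not np.any(ts.samples):
        raise ValueError("all-zero trace has no phase")
    filtered = elliptic_filter(ts, "band", band)
    analytic = sps.hilbert(filtered.samples)
    phase = np.angle(analytic)
    phase = np.where(phase >= np.pi, phase - 2 * np.pi, phase)
    return PhaseTrace(phase, ts.rate, (float(np.atleast_1d(band)[0]),
                                       float(np.atleast_1d(band)[-1])), ts.t0)


def _truncated_window_mean(x: np.ndarray, frame_samples: int) -> np.ndarray:
    """Centered sliding mean; edge windows are truncated to what exists."""
    w = int(frame_samples)
    half = w // 2
    c = np.concatenate(([0.0], np.cumsum(x)))
    n = x.size
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, n)
    return (c[hi] - c[lo]) / (hi - lo)


def running_rms(ts: TimeSeries, frame: float = 0.005) -> TimeSeries:
    """Centered sliding root-mean-square in a ``frame``-second window."""
    w = int(round(frame * ts.rate))
    if w < 2:
        raise ValueError("frame must span at least 2 samples")
    ms = _truncated_window_mean(ts.samples ** 2, w)
    return ts.with_samples(np.sqrt(ms))


def moving_average(ts: TimeSeries, frame: float) -> TimeSeries:
    """Centered boxcar smoothing; constants are preserved, edges truncated."""
    w = int(round(frame * ts.rate))
    w = max(w, 1)
    return ts.with_samples(_truncated_window_mean(ts.samples, w))


def kernel_ifr(spikes: SpikeTrain, kernel_sd: float, rate: float,
               duration: float | None = None) -> RateTrace:
    """Instantaneous firing rate: unit-area Gaussians at each spike time,
    evaluated on a uniform grid at ``rate`` Hz.

    The trace integrates to the spike count (up to edge truncation for
    spikes within ~4 SD of the recording edges).
    """
    if not kernel_sd > 0:
        raise ValueError("kernel_sd must be positive")
    if duration is None:
        duration = spikes.duration
    n = int(round(duration * rate))
    out = np.zeros(n)
    if spikes.times.size == 0:
        return RateTrace(out, rate, kernel_sd, spikes.source.value)
    half = int(np.ceil(6 * kernel_sd * rate))
    offsets = np.arange(-half, half + 1)
    norm = 1.0 / (kernel_sd * np.sqrt(2 * np.pi))
    for t in spikes.times:
        center = t * rate
        i0 = int(round(center))
        idx = i0 + offsets
        valid = (idx >= 0) & (idx < n)
        dt = idx[valid] / rate - t
        out[idx[valid]] += norm * np.exp(-0.5 * (dt / kernel_sd) ** 2)
    return RateTrace(out, rate, kernel_sd, spikes.source.value)
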