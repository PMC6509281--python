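"""Domain types shared by every analysis stage.

Conventions used throughout the package:

* times are in seconds; intervals are half-open ``[start, end)``;
  sample ``i`` of a trace covers ``[t0 + i/rate, t0 + (i+1)/rate)``.
* phases are stored in radians wrapped to ``[-pi, pi)`` and reported in
  degrees ``[0, 360)``; 0 deg is the depth-positive peak of the
  delta-filtered LFP, so up states cluster near 180 deg.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "StateLabel",
    "SpikeSource",
    "TimeSeries",
    "SpikeTrain",
    "Interval",
    "StateSegmentation",
    "StimulationProtocol",
]


class StateLabel(str, Enum):
    """Cortical network state of an interval."""

    UP = "UP"
    DOWN = "DOWN"
    INDET = "INDET"


class SpikeSource(str, Enum):
    """Origin of a spike train."""

    PV = "PV"
    VPM = "VPM"
    OTHER = "OTHER"


@dataclass(frozen=True)
class TimeSeries:
    """Uniformly sampled voltage trace.

    Parameters
    ----------
    samples : ndarray
        Sample values (volts or normalized units); must be finite.
    rate : float
        Sampling rate in Hz, > 0.
    t0 : float
        Time of the first sample, seconds.
    channel_label : str
        Free-form channel name (e.g. ``"LFP"``, ``"juxta"``, ``"MUA"``).
    """

    samples: np.ndarray
    rate: float
    t0: float = 0.0
    channel_label: str = ""

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 1 or samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D array")
        if not np.all(np.isfinite(samples)):
            raise ValueError("samples must all be finite")
        if not self.rate > 0:
            raise ValueError(f"rate must be positive, got {self.rate}")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Total covered time in seconds (n / rate)."""
        return self.samples.size / self.rate

    @property
    def times(self) -> np.ndarray:
        """Time of each sample, seconds."""
        return self.t0 + np.arange(self.samples.size) / self.rate

    def index_at(self, t: float | np.ndarray) -> np.ndarray:
        """Sample index covering time ``t`` (clipped to the valid range)."""
        idx = np.floor((np.asarray(t) - self.t0) * self.rate).astype(int)
        return np.clip(idx, 0, self.samples.size - 1)

    def with_samples(self, samples: np.ndarray, rate: float | None = None) -> "TimeSeries":
        """Copy carrying new samples (and optionally a new rate)."""
        return TimeSeries(samples, self.rate if rate is None else rate,
                          self.t0, self.channel_label)


@dataclass(frozen=True)
class SpikeTrain:
    """Sorted spike times with a source label.

    ``times`` are strictly increasing and lie in ``[0, duration)``.
    """

    times: np.ndarray
    source: SpikeSource = SpikeSource.OTHER
    duration: float = 0.0

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float).ravel()
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "source", SpikeSource(self.source))
        if times.size and np.any(np.diff(times) <= 0):
            raise ValueError("spike times must be strictly increasing")
        if times.size and (times[0] < 0 or times[-1] >= self.duration):
            raise ValueError("spike times must lie in [0, duration)")

    def __len__(self) -> int:
        return self.times.size

    @property
    def rate(self) -> float:
        """Mean firing rate over the full duration, spikes/s."""
        if self.duration <= 0:
            return float("nan")
        return self.times.size / self.duration


@dataclass(frozen=True)
class Interval:
    """Half-open labeled time interval ``[start, end)``."""

    start: float
    end: float
    label: StateLabel

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"need start < end, got [{self.start}, {self.end})")
        object.__setattr__(self, "label", StateLabel(self.label))

    @property
    def duration(self) -> float:
        return self.end - self.start

    def contains(self, t: float | np.ndarray) -> np.ndarray:
        return (np.asarray(t) >= self.start) & (np.asarray(t) < self.end)


@dataclass(frozen=True)
class StateSegmentation:
    """Ordered, non-overlapping labeled intervals tiling a recording."""

    intervals: tuple[Interval, ...]
    rate: float

    def __init__(self, intervals: Iterable[Interval], rate: float) -> None:
        intervals = tuple(intervals)
        for a, b in zip(intervals[:-1], intervals[1:]):
            if b.start < a.end - 1e-12:
                raise ValueError(f"intervals overlap: [{a.start},{a.end}) and "
                                 f"[{b.start},{b.end})")
        object.__setattr__(self, "intervals", intervals)
        object.__setattr__(self, "rate", float(rate))

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def __eq__(self, other) -> bool:
        if not isinstance(other, StateSegmentation):
            return NotImplemented
        if len(self.intervals) != len(other.intervals) or self.rate != other.rate:
            return False
        return all(
            a.label == b.label
            and abs(a.start - b.start) < 1e-9
            and abs(a.end - b.end) < 1e-9
            for a, b in zip(self.intervals, other.intervals)
        )

    @property
    def extent(self) -> tuple[float, float]:
        return self.intervals[0].start, self.intervals[-1].end

    def of_label(self, label: StateLabel) -> list[Interval]:
        label = StateLabel(label)
        return [iv for iv in self.intervals if iv.label == label]

    def label_at(self, t: float | np.ndarray) -> np.ndarray:
        """State label at each time in ``t`` (object array of StateLabel)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        starts = np.array([iv.start for iv in self.intervals])
        idx = np.searchsorted(starts, t, side="right") - 1
        idx = np.clip(idx, 0, len(self.intervals) - 1)
        return np.array([self.intervals[i].label for i in idx], dtype=object)

    def sample_labels(self, n: int | None = None) -> np.ndarray:
        """Per-sample labels on the segmentation's own grid (int codes).

        Codes: DOWN=0, INDET=1, UP=2. ``n`` overrides the sample count.
        """
        start, end = self.extent
        if n is None:
            n = int(round((end - start) * self.rate))
        codes = {StateLabel.DOWN: 0, StateLabel.INDET: 1, StateLabel.UP: 2}
        out = np.full(n, codes[StateLabel.INDET], dtype=np.int8)
        for iv in self.intervals:
            i0 = int(np.ceil((iv.start - start) * self.rate - 1e-9))
            i1 = int(np.ceil((iv.end - start) * self.rate - 1e-9))
            out[max(i0, 0):min(i1, n)] = codes[iv.label]
        return out


@dataclass(frozen=True)
class StimulationProtocol:
    """Illumination epochs: sorted onsets with a common duration."""

    onsets: np.ndarray
    duration: float = 0.5
    wavelength_nm: float = 594.0

    def __post_init__(self) -> None:
        onsets = np.asarray(self.onsets, dtype=float).ravel()
        object.__setattr__(self, "onsets", onsets)
        if onsets.size and np.any(np.diff(onsets) < self.duration):
            raise ValueError("illumination epochs overlap")
        if not self.duration > 0:
            raise ValueError("duration must be positive")

    def __len__(self) -> int:
        return self.onsets.size

    @property
    def offsets(self) -> np.ndarray:
        return self.onsets + self.duration
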