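"""Readers and writers for the package's interchange formats.

Native trace container is HDF5 (one dataset per channel, attributes ``rate``,
``t0``, ``units``); CSV is accepted for interchange.  Spike trains travel as
one-column CSV (header ``time_s``), segmentations and stimulation tables as
TSV.  An optional adapter reads pClamp-originated ABF files through ``pyabf``
when that package is installed.
"""

from __future__ import annotations

import csv
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .core import (Interval, SpikeSource, SpikeTrain, StateLabel,
                   StateSegmentation, StimulationProtocol, TimeSeries)

__all__ = [
    "read_timeseries", "write_timeseries",
    "read_spiketrain", "write_spiketrain",
    "read_segmentation", "write_segmentation",
    "read_protocol", "write_protocol",
]

_CSV_RTOL = 1e-9


def read_timeseries(path: str | Path, format: str | None = None,
                    channel: str | None = None) -> TimeSeries:
    """Read a voltage trace from HDF5, two-column CSV, or ABF.

    ``format`` is inferred from the suffix when omitted (``.h5``/``.hdf5``,
    ``.csv``, ``.abf``).  CSV must have columns (t, value) with uniform
    sampling; HDF5 datasets must carry a ``rate`` attribute.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or {".h5": "hdf5", ".hdf5": "hdf5", ".csv": "csv",
                     ".abf": "abf"}.get(path.suffix.lower())
    if fmt == "hdf5":
        return _read_hdf5(path, channel)
    if fmt == "csv":
        return _read_csv(path)
    if fmt == "abf":
        return _read_abf(path, channel)
    raise ValueError(f"cannot infer format of {path}; pass format=")


def _read_hdf5(path: Path, channel: str | None) -> TimeSeries:
    with h5py.File(path, "r") as f:
        keys = list(f.keys())
        if not keys:
            raise ValueError(f"{path}: empty HDF5 container")
        key = channel if channel is not None else keys[0]
        ds = f[key]
        if "rate" not in ds.attrs:
            raise ValueError(f"{path}:{key}: missing required 'rate' attribute")
        return TimeSeries(ds[...].astype(float), float(ds.attrs["rate"]),
                          float(ds.attrs.get("t0", 0.0)), channel_label=key)


def _read_csv(path: Path) -> TimeSeries:
    arr = pd.read_csv(path, comment="#").to_numpy(dtype=float)
    if arr.ndim != 2 or arr.shape[1] < 2 or arr.shape[0] < 2:
        raise ValueError(f"{path}: need two columns (t, value) and >= 2 rows")
    t, v = arr[:, 0], arr[:, 1]
    dt = np.diff(t)
    dt0 = dt[0]
    if dt0 <= 0:
        raise ValueError(f"{path}: non-increasing time at row 1")
    bad = np.nonzero(np.abs(dt - dt0) > _CSV_RTOL * max(abs(dt0), 1.0))[0]
    if bad.size:
        raise ValueError(
            f"{path}: non-uniform sampling; first offending interval at row "
            f"{bad[0] + 1} (dt={dt[bad[0]]:g} vs {dt0:g})")
    return TimeSeries(v, 1.0 / dt0, t0=float(t[0]), channel_label=path.stem)


def _read_abf(path: Path, channel: str | None) -> TimeSeries:
    try:
        import pyabf  # type: ignore
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "reading pClamp ABF files requires the optional 'pyabf' package "
            "(pip install slowstates[abf]); alternatively export the trace "
            "to HDF5 or CSV") from exc
    abf = pyabf.ABF(str(path))  # pragma: no cover
    ch = int(channel) if channel is not None else 0  # pragma: no cover
    abf.setSweep(0, channel=ch)  # pragma: no cover
    return TimeSeries(np.asarray(abf.sweepY, dtype=float),  # pragma: no cover
                      float(abf.dataRate), channel_label=f"ABF{ch}")


def write_timeseries(ts: TimeSeries, path: str | Path,
                     channel: str | None = None, units: str = "V",
                     mode: str = "w") -> Path:
    """Write a trace into the HDF5 container (one dataset per channel)."""
    path = Path(path)
    key = channel or ts.channel_label or "trace"
    with h5py.File(path, mode) as f:
        if key in f:
            del f[key]
        ds = f.create_dataset(key, data=ts.samples)
        ds.attrs["rate"] = ts.rate
        ds.attrs["t0"] = ts.t0
        ds.attrs["units"] = units
    return path


def read_spiketrain(path: str | Path, source: SpikeSource | str = SpikeSource.OTHER,
                    duration: float | None = None) -> SpikeTrain:
    """Read a spike-time list (CSV, header ``time_s``)."""
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise ValueError(f"{path}: expected a 'time_s' column")
    times = df["time_s"].to_numpy(dtype=float)
    if duration is None:
        duration = float(times[-1]) + 1e-6 if times.size else 0.0
    return SpikeTrain(times, SpikeSource(source), duration)


def write_spiketrain(train: SpikeTrain, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame({"time_s": train.times}).to_csv(path, index=False,
                                                 float_format="%.6f")
    return path


def write_segmentation(seg: StateSegmentation, path: str | Path) -> Path:
    """Write a segmentation as TSV (start_s, end_s, label).

    Refuses to write overlapping intervals (the constructor enforces this,
    but the check is repeated here for segmentations built by other means).
    """
    ivs = list(seg.intervals)
    for a, b in zip(ivs[:-1], ivs[1:]):
        if b.start < a.end - 1e-12:
            raise ValueError("refusing to write overlapping intervals")
    path = Path(path)
    with open(path, "w", newline="") as f:
        w = csv.writer(f, delimiter="\t")
        w.writerow(["start_s", "end_s", "label"])
        w.writerow([f"# rate_hz={seg.rate:.6f}", "", ""])
        for iv in ivs:
            w.writerow([f"{iv.start:.6f}", f"{iv.end:.6f}", iv.label.value])
    return path


def read_segmentation(path: str | Path) -> StateSegmentation:
    path = Path(path)
    rate = 1000.0
    intervals = []
    with open(path) as f:
        r = csv.reader(f, delimiter="\t")
        header = next(r)
        if header[:3] != ["start_s", "end_s", "label"]:
            raise ValueError(f"{path}: unexpected header {header}")
        for row in r:
            if row and row[0].startswith("# rate_hz="):
                rate = float(row[0].split("=", 1)[1])
                continue
            if not row:
                continue
            intervals.append(Interval(float(row[0]), float(row[1]),
                                      StateLabel(row[2])))
    return StateSegmentation(intervals, rate)


def write_protocol(protocol: StimulationProtocol, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as f:
        w = csv.writer(f, delimiter="\t")
        w.writerow(["onset_s", "duration_s"])
        for onset in protocol.onsets:
            w.writerow([f"{onset:.6f}", f"{protocol.duration:.6f}"])
    return path


def read_protocol(path: str | Path) -> StimulationProtocol:
    df = pd.read_csv(path, sep="\t")
    onsets = df["onset_s"].to_numpy(dtype=float)
    duration = float(df["duration_s"].iloc[0]) if len(df) else 0.5
    return StimulationProtocol(onsets, duration)
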