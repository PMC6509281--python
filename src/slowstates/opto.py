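"""Latency of down-to-up transitions evoked by optogenetic PV inhibition.

Pipeline: (1) correct the brief (~4 ms) light artifact by subtracting the
across-trial mean of artifact-only trials and smoothing inside a 60-ms
window centered on each onset; (2) find putative down states as periods
where the beta/gamma evidence (10-ms RMS frames) is below its overall
median (alternative thresholds: half-maximum of the first density peak, or
mu + sigma of the lower component of a two-Gaussian fit); (3) for each
onset falling inside a putative down state, measure the latency to the
first crossing of the LFP temporal derivative below ``T = mu - k sigma``
(k = 4), where mu and sigma are the derivative statistics inside that down
state; (4) repeat with periodic surrogate onsets restricted to spontaneous
activity (k = 2, slower spontaneous slopes); (5) report the ratio of mean
evoked to mean spontaneous latency.

Sign convention: recordings are depth-referenced, the up state is
depth-negative, so a down-to-up transition is a steep negative deflection
(derivative below threshold).  Set ``sign=-1`` for the opposite convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import StimulationProtocol, TimeSeries
from .signal import moving_average
from .states import betagamma_evidence

__all__ = ["LatencyParams", "LatencyResult", "correct_light_artifact",
           "putative_down_mask", "evoked_latency", "spontaneous_latencies",
           "latency_ratio", "opto_latency_analysis"]


@dataclass(frozen=True)
class LatencyParams:
    artifact_window: float = 0.060   # s, centered on each onset
    artifact_smooth: float = 0.014   # s, moving average inside the window
    rms_frame: float = 0.010         # s, running-SD frame for the evidence
    smooth_frame: float = 0.050      # s
    threshold_method: str = "median"  # or "fwhm", "gmm2"
    k_evoked: float = 4.0
    k_spontaneous: float = 2.0
    spont_pre_guard: float = 0.050   # s before each onset
    spont_post_guard: float = 0.550  # s after each offset
    surrogate_period: float = 0.5    # s, grid of surrogate onsets
    deriv_smooth: float = 0.014      # s, moving average before the derivative
    sign: float = 1.0                # +1: up state depth-negative

    def __post_init__(self) -> None:
        if self.k_evoked <= 0 or self.k_spontaneous <= 0:
            raise ValueError("k multipliers must be positive")
        if self.threshold_method not in ("median", "fwhm", "gmm2"):
            raise ValueError("threshold_method must be median, fwhm or gmm2")


@dataclass
class LatencyResult:
    evoked: np.ndarray               # s per onset; NaN = censored/excluded
    spontaneous: np.ndarray          # s per surrogate onset (uncensored only)
    evoked_mean: float
    spontaneous_mean: float
    ratio: float
    threshold: float                 # putative-down evidence threshold used
    n_censored_evoked: int
    n_excluded_evoked: int           # onsets not inside a putative down state


def correct_light_artifact(lfp: TimeSeries, onsets: np.ndarray,
                           params: LatencyParams | None = None,
                           smooth: bool = True) -> TimeSeries:
    """Subtract the mean light artifact (and optionally smooth) around
    each onset.

    Artifact-only trials are those without a transition-like derivative
    excursion shortly after the onset (8-30 ms, past the ~4 ms artifact);
    their across-trial mean (baseline removed) is subtracted in the 60-ms
    window centered on *every* onset.  With ``smooth=True`` the window is
    additionally smoothed with a 14-ms moving average, crossfaded over the
    outer 10 ms so no discontinuity is introduced at the window edges (use
    this trace for derivative-based latency detection; use the
    subtract-only trace for evidence computation, where the smoothing
    would artificially suppress beta-gamma power).  Samples outside the
    windows are untouched.  With fewer than 2 artifact-only trials the
    correction is skipped with a warning.
    """
    p = params or LatencyParams()
    rate = lfp.rate
    half = int(round(p.artifact_window / 2 * rate))
    x = lfp.samples.copy()
    deriv = np.diff(lfp.samples, prepend=lfp.samples[0]) * p.sign

    clean_windows = []
    for onset in np.asarray(onsets, dtype=float):
        i = int(round(onset * rate))
        if i - half < 0 or i + half >= x.size:
            continue
        pre = deriv[max(i - int(0.15 * rate), 0):i - int(0.01 * rate)]
        seg = deriv[i + int(0.008 * rate):i + int(0.030 * rate)]
        if pre.size < 3 or seg.size == 0:
            continue
        thr = pre.mean() - 4.0 * pre.std()
        if not np.any(seg < thr):
            clean_windows.append(lfp.samples[i - half:i + half + 1])
    if len(clean_windows) < 2:
        warnings.warn("fewer than 2 artifact-only trials; "
                      "artifact correction skipped")
        return lfp
    template = np.mean(clean_windows, axis=0)
    # remove the template's baseline so only the artifact shape is subtracted
    guard = slice(half - int(0.002 * rate), half + int(0.008 * rate))
    baseline = np.mean(np.concatenate([template[:guard.start],
                                       template[guard.stop:]]))
    template = template - baseline

    w = max(int(round(p.artifact_smooth * rate)), 1)
    fade = int(round(0.010 * rate))
    n_win = 2 * half + 1
    blend = np.ones(n_win)
    if smooth and fade > 0:
        blend[:fade] = np.linspace(0.0, 1.0, fade)
        blend[-fade:] = np.linspace(1.0, 0.0, fade)
    for onset in np.asarray(onsets, dtype=float):
        i = int(round(onset * rate))
        if i - half < 0 or i + half >= x.size:
            continue
        win = x[i - half:i + half + 1] - template
        if smooth:
            c = np.concatenate(([0.0], np.cumsum(win)))
            idx = np.arange(win.size)
            lo = np.maximum(idx - w // 2, 0)
            hi = np.minimum(idx + w // 2 + 1, win.size)
            smoothed = (c[hi] - c[lo]) / (hi - lo)
            win = blend * smoothed + (1.0 - blend) * win
        x[i - half:i + half + 1] = win
    return lfp.with_samples(x)


def _first_peak_fwhm_threshold(s: np.ndarray) -> float:
    """Upper half-maximum of the first peak of the evidence density."""
    counts, edges = np.histogram(s, bins=60)
    centers = (edges[:-1] + edges[1:]) / 2
    # first local maximum that dominates its neighborhood
    for i in range(1, counts.size - 1):
        if counts[i] >= counts[i - 1] and counts[i] > counts[i + 1]:
            peak = i
            break
    else:
        peak = int(np.argmax(counts))
    half = counts[peak] / 2.0
    for j in range(peak, counts.size):
        if counts[j] <= half:
            return float(centers[j])
    return float(centers[-1])


def _gmm2_threshold(s: np.ndarray, seed: int = 0) -> float:
    """mu + sigma of the lower component of a two-Gaussian mixture."""
    from sklearn.mixture import GaussianMixture
    x = s[:: max(1, s.size // 20000)][:, None]
    gm = GaussianMixture(2, random_state=seed,
                         means_init=np.percentile(x, [25, 75])[:, None])
    gm.fit(x)
    lo = int(np.argmin(gm.means_.ravel()))
    return float(gm.means_.ravel()[lo]
                 + np.sqrt(gm.covariances_.ravel()[lo]))


def putative_down_mask(s_betagamma: np.ndarray, method: str = "median",
                       threshold: float | None = None,
                       ) -> tuple[np.ndarray, float]:
    """Boolean putative-down mask: evidence strictly below the threshold.

    ``threshold`` overrides the method (to reuse control-condition
    thresholds after a pharmacological manipulation).
    """
    s = np.asarray(s_betagamma, dtype=float)
    if np.ptp(s) <= 0:
        raise ValueError("constant evidence signal")
    if threshold is None:
        if method == "median":
            threshold = float(np.median(s))
        elif method == "fwhm":
            threshold = _first_peak_fwhm_threshold(s)
        elif method == "gmm2":
            threshold = _gmm2_threshold(s)
        else:
            raise ValueError(f"unknown method {method!r}")
    return s < threshold, float(threshold)


def _mask_interval(mask: np.ndarray, i: int) -> tuple[int, int] | None:
    """(start, end) of the contiguous True run containing sample i."""
    if i < 0 or i >= mask.size or not mask[i]:
        return None
    start = i
    while start > 0 and mask[start - 1]:
        start -= 1
    end = i
    while end < mask.size and mask[end]:
        end += 1
    return start, end


def evoked_latency(lfp: TimeSeries, onset: float, mask: np.ndarray,
                   k: float = 4.0, sign: float = 1.0,
                   deriv_smooth: float = 0.014) -> float:
    """Latency (s) from onset to the first derivative crossing below
    ``T = mu - k sigma``; NaN when the onset is not inside a putative down
    state, the state is too short, or no crossing occurs before its end.

    The discrete derivative is taken on a lightly smoothed trace
    (``deriv_smooth`` moving average) so that state-transition slopes, not
    per-sample noise, dominate the in-state derivative statistics.
    """
    rate = lfp.rate
    i = int(round(onset * rate))
    run = _mask_interval(mask, i)
    if run is None:
        return float("nan")
    start, end = run
    if end - start < 3:
        return float("nan")
    # include a margin past the state end: the centered evidence smoothing
    # and the band-pass filter's ringing pull the detected state edge up to
    # ~150 ms earlier than the transition itself, so the derivative
    # crossing of a transition ending this down state can fall just beyond
    # the masked run
    margin = int(round(0.150 * rate))
    seg_ts = TimeSeries(lfp.samples[start:min(end + margin, lfp.samples.size)],
                        rate)
    if deriv_smooth > 0:
        seg_ts = moving_average(seg_ts, deriv_smooth)
    deriv = np.diff(seg_ts.samples) * sign
    in_state = deriv[:end - start - 1]
    mu, sd = in_state.mean(), in_state.std()
    T = mu - k * sd
    cross = np.nonzero(deriv[i - start:] < T)[0]
    if cross.size == 0:
        return float("nan")
    return float(cross[0] + 1) / rate


def spontaneous_latencies(lfp: TimeSeries, mask: np.ndarray,
                          protocol: StimulationProtocol,
                          params: LatencyParams | None = None) -> np.ndarray:
    """Latencies from periodic surrogate onsets during spontaneous activity.

    Surrogate onsets lie on a regular grid (``surrogate_period``) and are
    kept only when at least ``spont_pre_guard`` before every illumination
    onset or ``spont_post_guard`` after every offset, and inside a putative
    down state.  Censored onsets are dropped.
    """
    p = params or LatencyParams()
    duration = lfp.duration
    grid = np.arange(p.surrogate_period, duration - 0.1, p.surrogate_period)
    keep = np.ones(grid.size, dtype=bool)
    for onset, offset in zip(protocol.onsets, protocol.offsets):
        keep &= (grid < onset - p.spont_pre_guard) | (
            grid > offset + p.spont_post_guard)
    out = []
    for t in grid[keep]:
        lat = evoked_latency(lfp, t, mask, p.k_spontaneous, p.sign,
                             p.deriv_smooth)
        if np.isfinite(lat):
            out.append(lat)
    if not out:
        raise ValueError("no valid surrogate onsets in spontaneous activity")
    return np.array(out)


def latency_ratio(evoked: np.ndarray, spontaneous: np.ndarray) -> float:
    """Mean evoked latency over mean spontaneous latency (censored
    entries excluded)."""
    ev = np.asarray(evoked, dtype=float)
    sp = np.asarray(spontaneous, dtype=float)
    ev = ev[np.isfinite(ev)]
    sp = sp[np.isfinite(sp)]
    if ev.size == 0 or sp.size == 0:
        raise ValueError("need at least one uncensored latency in each set")
    return float(ev.mean() / sp.mean())


def opto_latency_analysis(lfp: TimeSeries, protocol: StimulationProtocol,
                          params: LatencyParams | None = None,
                          threshold: float | None = None) -> LatencyResult:
    """Full latency pipeline on one optogenetic session.

    Pass ``threshold`` to reuse a control-condition putative-down threshold
    (e.g. when analyzing the muscimol condition of the same animal).
    """
    p = params or LatencyParams()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        # evidence trace: artifact subtracted but NOT smoothed (smoothing
        # would fake a beta-gamma power dip at every onset)
        sub_only = correct_light_artifact(lfp, protocol.onsets, p,
                                          smooth=False)
    corrected = correct_light_artifact(lfp, protocol.onsets, p, smooth=True)
    s_bg = betagamma_evidence(sub_only, rms_frame=p.rms_frame,
                              smooth_frame=p.smooth_frame)
    mask, thr = putative_down_mask(s_bg, p.threshold_method, threshold)

    evoked = np.array([evoked_latency(corrected, o, mask, p.k_evoked, p.sign,
                                      p.deriv_smooth)
                       for o in protocol.onsets])
    in_down = np.array([_mask_interval(mask, int(round(o * lfp.rate)))
                        is not None for o in protocol.onsets])
    n_excluded = int(np.count_nonzero(~in_down))
    n_censored = int(np.count_nonzero(in_down & ~np.isfinite(evoked)))

    spont = spontaneous_latencies(corrected, mask, protocol, p)
    ev = evoked[np.isfinite(evoked)]
    return LatencyResult(
        evoked, spont,
        float(ev.mean()) if ev.size else float("nan"),
        float(spont.mean()),
        latency_ratio(evoked, spont) if ev.size else float("nan"),
        thr, n_censored, n_excluded)
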