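"""Up/down-state segmentation of the LFP and state/spike summary metrics.

The segmentation combines two decision variables computed at a 1 kHz working
rate, each confined to [0, 1]:

* ``s_delta`` — phase evidence from the [0-1] and [1-2] Hz bands: per band a
  raised cosine ``(1 + cos(phi - phi_up)) / 2`` of the Hilbert phase (1 at
  the preferred up-state phase, 180 degrees; 0 at the opposite phase),
  averaged across bands;
* ``s_betagamma`` — [10, 51] Hz running RMS (5 ms frame) smoothed with a
  50 ms moving average and normalized so [min, 95th percentile] maps onto
  [0, 1] (values above the 95th percentile are clipped to 1).

Their average ``s_comb`` is fitted (below its 95th percentile) with a
three-Gaussian mixture; samples above ``mu_UP - 2 sigma_UP`` are up,
below ``mu_DOWN + 2 sigma_DOWN`` down, the rest indeterminate.  Runs are
post-processed: sub-50 ms indeterminate gaps between two same-label states
are merged, then sub-100 ms up/down runs are relabeled indeterminate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.mixture import GaussianMixture

from .config import AnalysisConfig
from .core import (Interval, SpikeTrain, StateLabel, StateSegmentation,
                   TimeSeries)
from .signal import hilbert_phase, moving_average, running_rms, elliptic_filter

__all__ = ["EvidenceTrace", "GMMFit", "StateMetrics", "DegenerateFitError",
           "delta_evidence", "betagamma_evidence", "combined_evidence",
           "fit_three_gaussians", "segment_states", "detect_states",
           "state_metrics", "evoked_rate_change"]

_CODE = {StateLabel.DOWN: 0, StateLabel.INDET: 1, StateLabel.UP: 2}


class DegenerateFitError(RuntimeError):
    """Raised when the mixture thresholds do not separate (theta_down >= theta_up)."""


@dataclass(frozen=True)
class EvidenceTrace:
    """The three decision variables at the working rate, all in [0, 1]."""

    s_delta: np.ndarray
    s_betagamma: np.ndarray
    s_comb: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        for name in ("s_delta", "s_betagamma", "s_comb"):
            v = getattr(self, name)
            if np.any((v < -1e-12) | (v > 1 + 1e-12)):
                raise ValueError(f"{name} must lie in [0, 1]")
        if not (len(self.s_delta) == len(self.s_betagamma) == len(self.s_comb)):
            raise ValueError("evidence traces must have equal length")


@dataclass(frozen=True)
class GMMFit:
    """Three-Gaussian mixture of s_comb with the derived state thresholds."""

    means: tuple[float, float, float]      # (down, indet, up), increasing
    sds: tuple[float, float, float]
    weights: tuple[float, float, float]
    log_likelihood: float
    n_iter: int

    @property
    def theta_up(self) -> float:
        return self.means[2] - 2 * self.sds[2]

    @property
    def theta_down(self) -> float:
        return self.means[0] + 2 * self.sds[0]

    @property
    def usable(self) -> bool:
        return self.theta_down < self.theta_up


@dataclass(frozen=True)
class StateMetrics:
    duration_mean: dict[str, float]
    duration_cv: dict[str, float]
    up_state_frequency: float            # up states per second of recording
    spike_fractions: dict[str, dict[str, float]]      # train -> label -> frac
    active_ratio: dict[str, dict[str, float]]         # train -> label -> ratio
    mean_count_per_active: dict[str, dict[str, float]]


def delta_evidence(lfp_1k: TimeSeries,
                   bands=((0.0, 1.0), (1.0, 2.0)),
                   preferred_phase_deg: float = 180.0) -> np.ndarray:
    """Phase evidence in [0, 1], averaged over the configured delta bands."""
    if not bands:
        raise ValueError("need at least one band")
    phi_up = np.deg2rad(preferred_phase_deg)
    acc = np.zeros(len(lfp_1k))
    for band in bands:
        lo, hi = band
        if lo <= 0:
            # band anchored at DC: low-pass at the upper edge; the mean is
            # removed before the analytic signal (DC carries no phase and
            # off-centers the Hilbert rotation)
            filtered = elliptic_filter(lfp_1k, "low", hi)
            import scipy.signal as sps
            phase = np.angle(sps.hilbert(filtered.samples
                                         - filtered.samples.mean()))
        else:
            phase = hilbert_phase(lfp_1k, band).phase
        acc += 0.5 * (1.0 + np.cos(phase - phi_up))
    return acc / len(bands)


def betagamma_evidence(lfp_1k: TimeSeries, band=(10.0, 51.0),
                       rms_frame: float = 0.005, smooth_frame: float = 0.050,
                       norm_percentile: float = 95.0) -> np.ndarray:
    """Power evidence in [0, 1] from the beta/low-gamma band.

    Pipeline: band-pass, running RMS, moving average, then normalize so the
    minimum maps to 0 and the ``norm_percentile`` percentile to 1 (clipping
    the top tail).  Scale-invariant by construction.
    """
    if np.ptp(lfp_1k.samples) <= 0:
        raise ValueError("constant trace: zero dynamic range for normalization")
    filtered = elliptic_filter(lfp_1k, "band", band)
    rms = running_rms(filtered, rms_frame)
    smooth = moving_average(rms, smooth_frame).samples
    lo = smooth.min()
    hi = np.percentile(smooth, norm_percentile)
    if hi - lo <= 1e-12 * max(abs(hi), 1.0):
        raise ValueError("constant trace: zero dynamic range for normalization")
    return np.clip((smooth - lo) / (hi - lo), 0.0, 1.0)


def combined_evidence(lfp_1k: TimeSeries,
                      config: AnalysisConfig | None = None) -> EvidenceTrace:
    """Compute s_delta, s_betagamma and their average s_comb."""
    cfg = config or AnalysisConfig()
    sd = delta_evidence(lfp_1k, cfg.delta_bands, cfg.preferred_phase_deg)
    sb = betagamma_evidence(lfp_1k, cfg.betagamma_band, cfg.rms_frame,
                            cfg.smooth_frame, cfg.norm_percentile)
    return EvidenceTrace(sd, sb, (sd + sb) / 2.0, lfp_1k.rate)


def fit_three_gaussians(s_comb: np.ndarray, seed: int = 0,
                        n_restarts: int = 10,
                        norm_percentile: float = 95.0,
                        max_fit_samples: int = 20000) -> GMMFit:
    """EM fit of a three-Gaussian mixture to s_comb (top tail excluded).

    Components are sorted by mean: lowest = down, middle = indeterminate,
    highest = up.  Initialization is quantile-based with jittered restarts;
    the best restart by log-likelihood wins.  Traces longer than
    ``max_fit_samples`` are decimated uniformly for the fit (the mixture
    parameters are distributional, not per-sample).
    """
    x = np.asarray(s_comb, dtype=float)
    x = x[x <= np.percentile(x, norm_percentile)]
    if x.size < 10 or np.ptp(x) <= 1e-12:
        raise DegenerateFitError("not enough dynamic range to fit a mixture")
    if x.size > max_fit_samples:
        x = x[:: int(np.ceil(x.size / max_fit_samples))]
    rng = np.random.default_rng(seed)
    init_means = np.percentile(x, [10, 50, 90])[:, None]
    X = x[:, None]
    best = None
    for r in range(max(n_restarts, 1)):
        jitter = 0.0 if r == 0 else rng.normal(0, 0.05, (3, 1))
        gm = GaussianMixture(
            n_components=3, covariance_type="full", tol=1e-6, max_iter=500,
            means_init=np.clip(init_means + jitter, x.min(), x.max()),
            random_state=int(rng.integers(2**31)), n_init=1, reg_covar=1e-10)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gm.fit(X)
        ll = gm.score(X) * x.size
        if best is None or ll > best[0]:
            best = (ll, gm)
    ll, gm = best
    order = np.argsort(gm.means_.ravel())
    means = tuple(float(m) for m in gm.means_.ravel()[order])
    sds = tuple(float(np.sqrt(gm.covariances_.ravel()[i])) for i in order)
    weights = tuple(float(w) for w in gm.weights_[order])
    return GMMFit(means, sds, weights, float(ll), int(gm.n_iter_))


def _runs(codes: np.ndarray) -> list[tuple[int, int, int]]:
    """(start, end, code) runs of a label array; end exclusive."""
    change = np.nonzero(np.diff(codes))[0] + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [codes.size]))
    return [(int(s), int(e), int(codes[s])) for s, e in zip(starts, ends)]


def segment_states(s_comb: np.ndarray, fit: GMMFit, rate: float = 1000.0,
                   min_dur: float = 0.100, min_gap: float = 0.050,
                   ) -> StateSegmentation:
    """Threshold s_comb and post-process runs into a state tiling.

    Samples strictly above ``theta_up`` are up, strictly below
    ``theta_down`` down, the rest (including exact threshold ties)
    indeterminate.  Post-processing, applied once and in this order:
    (1) indeterminate gaps shorter than ``min_gap`` flanked by two
    same-label states are merged into that label; (2) up/down runs shorter
    than ``min_dur`` are relabeled indeterminate.
    """
    if not fit.usable:
        raise DegenerateFitError(
            f"theta_down={fit.theta_down:.3f} >= theta_up={fit.theta_up:.3f}; "
            "mixture does not separate the states")
    codes = np.full(s_comb.size, _CODE[StateLabel.INDET], dtype=np.int8)
    codes[s_comb > fit.theta_up] = _CODE[StateLabel.UP]
    codes[s_comb < fit.theta_down] = _CODE[StateLabel.DOWN]

    gap = int(round(min_gap * rate))
    runs = _runs(codes)
    for i in range(1, len(runs) - 1):
        s, e, c = runs[i]
        if (c == _CODE[StateLabel.INDET] and e - s < gap
                and runs[i - 1][2] == runs[i + 1][2]
                and runs[i - 1][2] != _CODE[StateLabel.INDET]):
            codes[s:e] = runs[i - 1][2]

    dur = int(round(min_dur * rate))
    for s, e, c in _runs(codes):
        if c != _CODE[StateLabel.INDET] and e - s < dur:
            codes[s:e] = _CODE[StateLabel.INDET]

    inv = {v: k for k, v in _CODE.items()}
    intervals = [Interval(s / rate, e / rate, inv[c]) for s, e, c in _runs(codes)]
    return StateSegmentation(intervals, rate)


def detect_states(lfp_1k: TimeSeries, config: AnalysisConfig | None = None,
                  ) -> tuple[StateSegmentation, EvidenceTrace, GMMFit]:
    """Full detection pipeline on an LFP already at the working rate."""
    cfg = config or AnalysisConfig()
    ev = combined_evidence(lfp_1k, cfg)
    fit = fit_three_gaussians(ev.s_comb, cfg.gmm_seed, cfg.gmm_restarts,
                              cfg.norm_percentile)
    seg = segment_states(ev.s_comb, fit, lfp_1k.rate,
                         cfg.min_state_duration, cfg.min_interstate_gap)
    return seg, ev, fit


def state_metrics(seg: StateSegmentation,
                  spikes: list[SpikeTrain] | dict[str, SpikeTrain],
                  ) -> StateMetrics:
    """Per-state duration statistics and per-train spike/state summaries.

    ``active ratio`` is the fraction of states of a label containing at
    least one spike; undefined ratios (no states of a label) are NaN.
    """
    if not isinstance(spikes, dict):
        spikes = {f"{tr.source.value}_{i}": tr for i, tr in enumerate(spikes)}
    start, end = seg.extent
    total_time = end - start

    duration_mean, duration_cv = {}, {}
    for label in (StateLabel.UP, StateLabel.DOWN, StateLabel.INDET):
        durs = np.array([iv.duration for iv in seg.of_label(label)])
        duration_mean[label.value] = float(durs.mean()) if durs.size else float("nan")
        duration_cv[label.value] = (float(durs.std(ddof=1) / durs.mean())
                                    if durs.size > 1 and durs.mean() > 0
                                    else float("nan"))
    n_up = len(seg.of_label(StateLabel.UP))
    up_freq = n_up / total_time if total_time > 0 else float("nan")

    fractions, active, mean_count = {}, {}, {}
    for name, train in spikes.items():
        labels = seg.label_at(train.times) if len(train) else np.empty(0, object)
        frac = {}
        for label in (StateLabel.UP, StateLabel.DOWN, StateLabel.INDET):
            frac[label.value] = (float(np.mean([lab == label for lab in labels]))
                                 if len(train) else float("nan"))
        fractions[name] = frac
        act, mc = {}, {}
        for label in (StateLabel.UP, StateLabel.DOWN):
            ivs = seg.of_label(label)
            if not ivs:
                act[label.value] = float("nan")
                mc[label.value] = float("nan")
                continue
            counts = np.array([np.count_nonzero(iv.contains(train.times))
                               for iv in ivs])
            n_active = int(np.count_nonzero(counts))
            act[label.value] = n_active / len(ivs)
            mc[label.value] = (float(counts[counts > 0].mean())
                               if n_active else float("nan"))
        active[name] = act
        mean_count[name] = mc
    return StateMetrics(duration_mean, duration_cv, up_freq,
                        fractions, active, mean_count)


def evoked_rate_change(spikes: SpikeTrain, onsets: np.ndarray,
                       window: float = 0.100) -> dict:
    """Spike rate in ``window``-long windows before and after each onset.

    Returns per-onset pre/post rates (spikes/s) and their means.
    """
    onsets = np.asarray(onsets, dtype=float)
    pre = np.array([np.count_nonzero((spikes.times >= o - window)
                                     & (spikes.times < o)) / window
                    for o in onsets])
    post = np.array([np.count_nonzero((spikes.times >= o)
                                      & (spikes.times < o + window)) / window
                     for o in onsets])
    return {"pre": pre, "post": post,
            "pre_mean": float(pre.mean()) if pre.size else 0.0,
            "post_mean": float(post.mean()) if post.size else 0.0}
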