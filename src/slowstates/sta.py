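"""Spike-triggered VPM firing rate around PV spikes, surrogate null,
z-scores, pre/post comparison, FDR correction, and the binomial
population-combination test.

The causal question — does thalamic firing precede PV spikes in down
states? — is answered statistically: the VPM instantaneous firing rate
(IFR, Gaussian kernel) is averaged in windows before and after each PV
spike fired in a down state, and compared against 100 surrogate spike sets
placed in PV-silent down states while preserving the spike count, the
down-state phase-of-firing distribution, and the spikes-per-state
statistics.  Window conventions: with ``w`` the window length and ``i`` the
trigger sample, pre is ``[i-w, i)`` and post is ``(i, i+w]``; the trigger
sample itself belongs to neither, which makes time reversal swap the two
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.special import logsumexp, ndtr
from statsmodels.stats.multitest import multipletests

from .core import SpikeTrain, StateLabel, StateSegmentation
from .signal import PhaseTrace, RateTrace, kernel_ifr

__all__ = [
    "STAParams", "STAResult", "SurrogateEnsemble",
    "spike_triggered_ifr", "window_means", "generate_surrogates",
    "surrogate_zscore", "pre_post_comparison", "normalized_variation",
    "fdr_bh", "binomial_tail", "spike_triggered_analysis",
]


@dataclass(frozen=True)
class STAParams:
    kernel_sd: float = 0.0125     # s; 20 Hz equivalent low-pass
    window: float = 0.100         # s, pre/post windows
    curve_halfwidth: float = 0.5  # s, extent of the triggered-IFR curve
    n_surrogates: int = 100
    state: StateLabel = StateLabel.DOWN
    min_state_factor: float = 2.0  # silent states must exceed factor*window
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window <= 0 or self.kernel_sd <= 0:
            raise ValueError("window and kernel_sd must be positive")
        if self.n_surrogates < 2:
            raise ValueError("need at least 2 surrogates")


@dataclass
class SurrogateEnsemble:
    """Constrained surrogate PV spike sets with their window summaries."""

    spike_sets: list[np.ndarray]
    pre_means: np.ndarray         # per-surrogate mean pre-window rate
    post_means: np.ndarray
    n_spikes: int                 # per surrogate (equals the real count)
    max_spikes_per_state: int
    n_states_available: int

    @property
    def overall_mean(self) -> float:
        """Grand mean surrogate-triggered rate (pre and post pooled)."""
        return float(np.mean((self.pre_means + self.post_means) / 2.0))


@dataclass
class STAResult:
    lags: np.ndarray              # s, curve support
    mean_curve: np.ndarray        # triggered IFR mean over triggers
    sem_curve: np.ndarray
    n_triggers: int
    pre_rates: np.ndarray         # per-trigger mean rate in [-w, 0)
    post_rates: np.ndarray
    pre_mean: float
    post_mean: float
    z_pre: float
    z_post: float
    p_pre: float                  # one-tailed (excess rate) vs surrogates
    p_post: float
    surrogate_pre_pct: tuple[float, float]   # 5th, 95th percentiles
    surrogate_post_pct: tuple[float, float]
    surrogate_overall_mean: float
    norm_variation_pre_pct: float
    norm_variation_post_pct: float
    wilcoxon_p: float             # one-tailed pre > post, paired over triggers


def spike_triggered_ifr(vpm_ifr: RateTrace, triggers: np.ndarray,
                        window: float = 0.5,
                        ) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Average IFR segments aligned at trigger times.

    Returns (lags, mean, SEM-over-triggers, n_used).  Triggers closer than
    ``window`` to either recording edge are dropped.
    """
    w = int(round(window * vpm_ifr.rate))
    n = vpm_ifr.values.size
    idx = np.round(np.asarray(triggers, dtype=float) * vpm_ifr.rate).astype(int)
    idx = idx[(idx - w >= 0) & (idx + w + 1 <= n)]
    if idx.size == 0:
        raise ValueError("no trigger is at least one window from the edges")
    segs = np.stack([vpm_ifr.values[i - w:i + w + 1] for i in idx])
    mean = segs.mean(axis=0)
    sem = (segs.std(axis=0, ddof=1) / np.sqrt(idx.size)
           if idx.size > 1 else np.zeros_like(mean))
    lags = np.arange(-w, w + 1) / vpm_ifr.rate
    return lags, mean, sem, int(idx.size)


def window_means(vpm_ifr: RateTrace, triggers: np.ndarray,
                 window: float = 0.100) -> tuple[np.ndarray, np.ndarray]:
    """Per-trigger mean rate in pre ``[-w, 0)`` and post ``(0, +w]`` windows.

    Triggers without a full window on both sides are dropped.
    """
    w = int(round(window * vpm_ifr.rate))
    n = vpm_ifr.values.size
    c = np.concatenate(([0.0], np.cumsum(vpm_ifr.values)))
    idx = np.round(np.asarray(triggers, dtype=float) * vpm_ifr.rate).astype(int)
    idx = idx[(idx - w >= 0) & (idx + w + 1 <= n)]
    pre = (c[idx] - c[idx - w]) / w
    post = (c[idx + w + 1] - c[idx + 1]) / w
    return pre, post


def _down_spike_phases(spikes: SpikeTrain, phase_trace: PhaseTrace,
                       intervals) -> np.ndarray:
    mask = np.zeros(len(spikes), dtype=bool)
    for iv in intervals:
        mask |= iv.contains(spikes.times)
    return phase_trace.at_times(spikes.times[mask])


def generate_surrogates(seg: StateSegmentation, pv_spikes: SpikeTrain,
                        phase_trace: PhaseTrace, vpm_ifr: RateTrace,
                        params: STAParams | None = None,
                        seed: int | None = None) -> SurrogateEnsemble:
    """Surrogate PV spike sets in PV-silent down states.

    Each surrogate preserves (i) the total number of real down-state PV
    spikes, (ii) the down-state phase-of-firing distribution (phases are
    resampled from the real ones and mapped to the circularly nearest
    phase sample inside the chosen state), and (iii) the spikes-per-state
    statistics (counts resampled from the real per-state counts, states
    sampled without replacement within a surrogate, at most as many states
    as were really active).  Only silent states longer than
    ``min_state_factor x window`` are eligible.
    """
    p = params or STAParams()
    rng = np.random.default_rng(p.seed if seed is None else seed)
    state = StateLabel(p.state)
    intervals = seg.of_label(state)
    counts = np.array([np.count_nonzero(iv.contains(pv_spikes.times))
                       for iv in intervals])
    active_counts = counts[counts > 0]
    n_real = int(active_counts.sum())
    if n_real == 0:
        raise ValueError(f"no real PV spikes in {state.value} states")
    silent = [iv for iv, c in zip(intervals, counts)
              if c == 0 and iv.duration > p.min_state_factor * p.window]
    if not silent:
        raise ValueError(
            f"no PV-silent {state.value} states longer than "
            f"{p.min_state_factor * p.window:.3f} s; cannot build surrogates")
    max_per_state = int(active_counts.max())
    max_states = int(active_counts.size)

    real_phases = _down_spike_phases(pv_spikes, phase_trace, intervals)
    rate = phase_trace.rate

    # per-state phase lookup tables (sorted by phase for nearest search)
    tables = []
    for iv in silent:
        i0 = int(np.ceil(iv.start * rate))
        i1 = int(iv.end * rate)
        ph = phase_trace.phase[i0:i1]
        t = (np.arange(i0, i1)) / rate
        order = np.argsort(ph, kind="stable")
        tables.append((ph[order], t[order]))

    if len(silent) * max_per_state < n_real:
        raise ValueError(
            f"cannot place {n_real} surrogate spikes: {len(silent)} eligible "
            f"silent states x {max_per_state} spikes/state maximum; "
            "relax the constraints or record longer")

    # length-biased state sampling: a down state's chance of containing a
    # real spike grows ~proportionally with its duration (thinning of a
    # low-rate process), so sampling silent states with probability
    # proportional to duration mirrors the duration distribution of the
    # really active states; uniform sampling would over-represent short
    # states, whose windows bleed into the adjacent up states and bias the
    # null upward
    durations = np.array([iv.duration for iv in silent])
    weights = durations / durations.sum()

    spike_sets: list[np.ndarray] = []
    for _ in range(p.n_surrogates):
        order = rng.choice(len(silent), size=len(silent), replace=False,
                           p=weights)
        chosen = order[:min(max_states, len(silent))]
        # spikes are spread over the chosen states proportionally to their
        # durations (multinomial), mirroring the near-Poisson real process
        # whose per-state counts scale with duration, then capped at the
        # real per-state maximum with the excess pushed to spare states
        counts_assigned = np.zeros(len(silent), dtype=int)
        w = durations[chosen] / durations[chosen].sum()
        counts_assigned[chosen] = rng.multinomial(n_real, w)
        while True:
            over = counts_assigned > max_per_state
            excess = int(np.sum(counts_assigned[over] - max_per_state))
            if excess == 0:
                break
            counts_assigned[over] = max_per_state
            spare_in_chosen = chosen[counts_assigned[chosen] < max_per_state]
            if spare_in_chosen.size:
                spare = spare_in_chosen
            else:
                chosen = order[:min(chosen.size + 1, len(silent))]
                spare = chosen[counts_assigned[chosen] < max_per_state]
            w = durations[spare] / durations[spare].sum()
            counts_assigned[spare] += rng.multinomial(excess, w)
        times: list[np.ndarray] = []
        for j in np.nonzero(counts_assigned)[0]:
            phases = rng.choice(real_phases, size=counts_assigned[j],
                                replace=True)
            ph_sorted, t_sorted = tables[j]
            times.append(_nearest_phase_times(ph_sorted, t_sorted, phases))
        spike_sets.append(np.sort(np.concatenate(times)))

    pre = np.empty(p.n_surrogates)
    post = np.empty(p.n_surrogates)
    for k, ts_k in enumerate(spike_sets):
        pr, po = window_means(vpm_ifr, ts_k, p.window)
        # triggers near the edges are rare (states are interior); guard anyway
        pre[k] = pr.mean() if pr.size else np.nan
        post[k] = po.mean() if po.size else np.nan
    return SurrogateEnsemble(spike_sets, pre, post, n_real,
                             max_per_state, len(silent))


def _nearest_phase_times(ph_sorted: np.ndarray, t_sorted: np.ndarray,
                         phases: np.ndarray) -> np.ndarray:
    """Time of the circularly nearest phase sample; ties -> earliest."""
    out = np.empty(phases.size)
    for i, phi in enumerate(phases):
        d = np.abs(np.mod(ph_sorted - phi + np.pi, 2 * np.pi) - np.pi)
        best = np.nonzero(d == d.min())[0]
        out[i] = t_sorted[best].min()
    return out


def surrogate_zscore(real_mean: float, surrogate_means: np.ndarray,
                     ) -> tuple[float, float]:
    """z of the real window mean against the surrogate distribution and the
    one-tailed p = 1 - Phi(z) (excess rate)."""
    m = float(np.mean(surrogate_means))
    sd = float(np.std(surrogate_means, ddof=1))
    if sd == 0:
        raise ValueError("surrogate distribution has zero spread")
    z = (real_mean - m) / sd
    return float(z), float(1.0 - ndtr(z))


def pre_post_comparison(vpm_ifr: RateTrace, triggers: np.ndarray,
                        window: float = 0.100,
                        alternative: str = "greater") -> dict:
    """Per-trigger pre/post rates and a paired Wilcoxon signed-rank test.

    ``alternative="greater"`` tests pre > post.  With fewer than 5 usable
    triggers, or all-zero differences, the p-value is NaN.
    """
    pre, post = window_means(vpm_ifr, triggers, window)
    p = float("nan")
    if pre.size >= 5 and np.any(pre != post):
        p = float(stats.wilcoxon(pre, post, alternative=alternative).pvalue)
    return {"pre": pre, "post": post,
            "pre_mean": float(pre.mean()) if pre.size else float("nan"),
            "post_mean": float(post.mean()) if post.size else float("nan"),
            "p": p, "n": int(pre.size)}


def normalized_variation(pre: float, post: float,
                         surrogate_overall_mean: float) -> tuple[float, float]:
    """Pre/post rates as % variation around the surrogate grand mean."""
    if not surrogate_overall_mean > 0:
        raise ValueError("surrogate mean rate must be positive")
    f = 100.0 / surrogate_overall_mean
    return (float((pre - surrogate_overall_mean) * f),
            float((post - surrogate_overall_mean) * f))


def fdr_bh(pvals, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR: (rejected mask, adjusted p-values)."""
    pvals = np.asarray(pvals, dtype=float)
    if np.any((pvals < 0) | (pvals > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    rejected, adjusted, _, _ = multipletests(pvals, alpha=alpha,
                                             method="fdr_bh")
    return rejected, adjusted


def binomial_tail(n: int, k: int, p0: float) -> float:
    """Exact upper-tail binomial probability P(X >= k | n, p0).

    Computed in log space (stable for very small tails).  Used to combine
    the per-cell significance calls into a population-level test.
    """
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if not 0 < p0 < 1:
        raise ValueError("p0 must be in (0, 1)")
    if k == 0:
        return 1.0
    i = np.arange(k, n + 1)
    log_terms = (stats.binom.logpmf(i, n, p0))
    return float(np.exp(logsumexp(log_terms)))


def spike_triggered_analysis(seg: StateSegmentation, pv_spikes: SpikeTrain,
                             vpm_spikes: SpikeTrain, phase_trace: PhaseTrace,
                             params: STAParams | None = None,
                             seed: int | None = None,
                             vpm_ifr: RateTrace | None = None) -> STAResult:
    """Full spike-triggered pipeline for one recording.

    Computes the VPM IFR, the PV-spike-triggered curve in the chosen state,
    the constrained surrogate ensemble, z-scores and one-tailed p-values of
    the real pre/post window rates against the surrogate distribution, the
    paired pre-vs-post Wilcoxon test, and the normalized variations.
    """
    p = params or STAParams()
    if vpm_ifr is None:
        vpm_ifr = kernel_ifr(vpm_spikes, p.kernel_sd, phase_trace.rate,
                             duration=len(phase_trace) / phase_trace.rate)
    state = StateLabel(p.state)
    intervals = seg.of_label(state)
    mask = np.zeros(len(pv_spikes), dtype=bool)
    for iv in intervals:
        mask |= iv.contains(pv_spikes.times)
    triggers = pv_spikes.times[mask]
    if triggers.size == 0:
        raise ValueError(f"no PV spikes in {state.value} states")

    lags, mean_curve, sem_curve, n_used = spike_triggered_ifr(
        vpm_ifr, triggers, p.curve_halfwidth)
    pre, post = window_means(vpm_ifr, triggers, p.window)
    pre_mean, post_mean = float(pre.mean()), float(post.mean())

    ens = generate_surrogates(seg, pv_spikes, phase_trace, vpm_ifr, p, seed)
    z_pre, p_pre = surrogate_zscore(pre_mean, ens.pre_means)
    z_post, p_post = surrogate_zscore(post_mean, ens.post_means)
    nv_pre, nv_post = normalized_variation(pre_mean, post_mean,
                                           ens.overall_mean)
    wil = pre_post_comparison(vpm_ifr, triggers, p.window)
    return STAResult(
        lags, mean_curve, sem_curve, n_used, pre, post, pre_mean, post_mean,
        z_pre, z_post, p_pre, p_post,
        (float(np.percentile(ens.pre_means, 5)),
         float(np.percentile(ens.pre_means, 95))),
        (float(np.percentile(ens.post_means, 5)),
         float(np.percentile(ens.post_means, 95))),
        ens.overall_mean, nv_pre, nv_post, wil["p"])
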