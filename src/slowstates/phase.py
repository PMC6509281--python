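"""Phase-of-firing analysis: CDF rescaling, circular statistics, von Mises
fitting, and state-restricted phase / relative-time distributions.

Phase locking is quantified on *rescaled* phases: the empirical cumulative
distribution of the phase over all time samples of the recording maps the
observed (possibly asymmetric) phase occupancy onto the uniform circle, so a
spike train firing uniformly *in time* yields a uniform rescaled phase
distribution regardless of the LFP wave shape.  Departure from uniformity is
then assessed with the Rayleigh test (significance at p < 0.01), locking
strength is one minus the circular variance (the resultant length), and the
preferred phase is the circular mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special

from .core import SpikeTrain, StateLabel, StateSegmentation
from .signal import PhaseTrace

__all__ = [
    "PhaseLockingResult", "StateRestrictedDistribution",
    "rescale_phases", "rayleigh_test", "locking_stats", "fit_von_mises",
    "phase_locking", "state_restricted_distribution",
]

_TWO_PI = 2 * np.pi
_KAPPA_CAP = 1e3


@dataclass(frozen=True)
class PhaseLockingResult:
    preferred_phase_deg: float
    locking_strength: float            # 1 - circular variance, in [0, 1]
    rayleigh_p: float
    n_spikes: int
    hist_edges_deg: np.ndarray         # bin edges, degrees [0, 360]
    hist_density: np.ndarray           # normalized counts, sums to 1
    von_mises_mu_deg: float            # NaN when undefined (zero resultant)
    von_mises_kappa: float


@dataclass(frozen=True)
class StateRestrictedDistribution:
    state: StateLabel
    phase_range_deg: tuple[float, float]
    rescaled_phases: np.ndarray        # radians in [-pi, pi)
    hist_edges: np.ndarray             # rescaled-phase bin edges, radians
    hist_density: np.ndarray
    relative_times: np.ndarray         # (t - start)/(end - start), in [0, 1]
    median_relative_time: float
    n_spikes: int

    @property
    def empty(self) -> bool:
        return self.n_spikes == 0


def _wrap(angles: np.ndarray) -> np.ndarray:
    """Wrap to [-pi, pi)."""
    return np.mod(np.asarray(angles, dtype=float) + np.pi, _TWO_PI) - np.pi


def rescale_phases(trace_phases: np.ndarray,
                   spike_phases: np.ndarray) -> np.ndarray:
    """Map spike phases through the empirical CDF of the trace phases.

    ``phi' = 2 pi F(phi) - pi`` with F the empirical CDF over *all* time
    samples, interpolated linearly between sorted sample phases.  Applying
    the same map to the trace itself gives a uniform distribution.
    """
    trace_phases = np.asarray(trace_phases, dtype=float).ravel()
    if trace_phases.size == 0:
        raise ValueError("empty phase trace")
    s = np.sort(trace_phases)
    n = s.size
    spike_phases = np.atleast_1d(np.asarray(spike_phases, dtype=float))
    # mid-rank CDF, linear between order statistics
    cdf_at = (np.searchsorted(s, spike_phases, side="left")
              + np.searchsorted(s, spike_phases, side="right")) / (2.0 * n)
    return _wrap(_TWO_PI * cdf_at - np.pi)


def rayleigh_test(angles: np.ndarray) -> float:
    """Rayleigh test p-value for non-uniformity of circular data.

    Uses the standard approximation
    ``p = exp(sqrt(1 + 4n + 4(n^2 - R^2 n^2)) - (1 + 2n))`` where ``R`` is
    the resultant length.  Requires n >= 2.
    """
    angles = np.asarray(angles, dtype=float).ravel()
    n = angles.size
    if n < 2:
        raise ValueError("Rayleigh test needs at least 2 angles")
    R = np.abs(np.mean(np.exp(1j * angles)))
    Rn = R * n
    p = np.exp(np.sqrt(1 + 4 * n + 4 * (n * n - Rn * Rn)) - (1 + 2 * n))
    return float(min(p, 1.0))


def locking_stats(angles: np.ndarray) -> tuple[float, float]:
    """(preferred phase in degrees [0, 360), locking strength in [0, 1]).

    Strength is the resultant length (one minus the circular variance);
    the preferred phase is the circular mean.  Rotation-equivariant.
    """
    angles = np.asarray(angles, dtype=float).ravel()
    if angles.size == 0:
        raise ValueError("no angles")
    z = np.mean(np.exp(1j * angles))
    return float(np.rad2deg(np.angle(z)) % 360.0), float(np.abs(z))


def _a_ratio(kappa: float) -> float:
    """A(kappa) = I1(kappa)/I0(kappa), computed with scaled Bessels."""
    return special.i1e(kappa) / special.i0e(kappa)


def invert_a_ratio(rbar: float, tol: float = 1e-12) -> float:
    """Solve A(kappa) = rbar by Newton iteration (kappa capped at 1e3)."""
    if rbar <= 0:
        return 0.0
    if rbar >= _a_ratio(_KAPPA_CAP):
        return _KAPPA_CAP
    # standard small/large-rbar starting values
    if rbar < 0.53:
        k = 2 * rbar + rbar**3 + 5 * rbar**5 / 6
    elif rbar < 0.85:
        k = -0.4 + 1.39 * rbar + 0.43 / (1 - rbar)
    else:
        k = 1.0 / (rbar**3 - 4 * rbar**2 + 3 * rbar)
    for _ in range(100):
        a = _a_ratio(k)
        # A'(kappa) = 1 - A^2 - A/kappa
        da = 1 - a * a - a / k
        step = (a - rbar) / da
        k = min(max(k - step, 1e-12), _KAPPA_CAP)
        if abs(step) < tol:
            break
    return float(k)


def fit_von_mises(angles: np.ndarray) -> tuple[float, float]:
    """Von Mises fit: (mu in degrees, kappa >= 0, capped at 1e3).

    mu is the circular mean; kappa solves A(kappa) = resultant length.
    With zero resultant, kappa = 0 and mu is undefined (NaN).
    """
    angles = np.asarray(angles, dtype=float).ravel()
    if angles.size < 10:
        raise ValueError("von Mises fit needs at least 10 angles")
    mu, rbar = locking_stats(angles)
    if rbar == 0:
        return float("nan"), 0.0
    return mu, invert_a_ratio(rbar)


def phase_locking(phase_trace: PhaseTrace, spikes: SpikeTrain,
                  n_bins: int = 18, rescale: bool = True,
                  ) -> PhaseLockingResult:
    """Full phase-locking summary of one spike train against one LFP phase.

    Spike phases are read off the trace at spike times, rescaled by the
    all-sample phase CDF (unless ``rescale=False``), then summarized.
    """
    spike_phases = phase_trace.at_times(spikes.times)
    if rescale:
        spike_phases = rescale_phases(phase_trace.phase, spike_phases)
    deg = np.rad2deg(spike_phases) % 360.0
    edges = np.linspace(0.0, 360.0, n_bins + 1)
    counts, _ = np.histogram(deg, bins=edges)
    density = counts / counts.sum() if counts.sum() else counts.astype(float)
    pref, strength = locking_stats(spike_phases)
    p = rayleigh_test(spike_phases) if len(spikes) >= 2 else float("nan")
    if len(spikes) >= 10:
        mu, kappa = fit_von_mises(spike_phases)
    else:
        mu, kappa = float("nan"), float("nan")
    return PhaseLockingResult(pref, strength, p, len(spikes), edges, density,
                              mu, kappa)


def _in_range_deg(deg: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Membership in a circular degree range [lo, hi] that may wrap 0."""
    deg = np.mod(deg, 360.0)
    if lo <= hi:
        return (deg >= lo) & (deg <= hi)
    return (deg >= lo) | (deg <= hi)


def _unwrap_from(deg: np.ndarray, lo: float) -> np.ndarray:
    """Angles as offsets >= 0 from the range start (handles wrapping)."""
    return np.mod(np.mod(deg, 360.0) - lo, 360.0)


def state_restricted_distribution(seg: StateSegmentation,
                                  phase_trace: PhaseTrace,
                                  spikes: SpikeTrain,
                                  state: StateLabel,
                                  phase_range_deg: tuple[float, float] | None = None,
                                  n_bins: int = 18,
                                  ) -> StateRestrictedDistribution:
    """Phase and relative-time distributions of spikes within one state.

    Spikes are kept when they fall in an interval of the requested label
    *and* their phase lies in the state's phase range ([95, 255] degrees
    for up, [295, 75] for down — the down range wraps through 0).  Kept
    phases are rescaled by the CDF of same-state trace phases within the
    range; relative time is (t - start)/(end - start) within each spike's
    own interval.
    """
    state = StateLabel(state)
    if phase_range_deg is None:
        phase_range_deg = {StateLabel.UP: (95.0, 255.0),
                           StateLabel.DOWN: (295.0, 75.0)}[state]
    lo, hi = phase_range_deg

    # trace phases belonging to this state (INDET samples never included)
    n = len(phase_trace)
    labels = seg.sample_labels(n)
    code = {StateLabel.DOWN: 0, StateLabel.INDET: 1, StateLabel.UP: 2}[state]
    trace_deg = np.rad2deg(phase_trace.phase) % 360.0
    state_trace_deg = trace_deg[labels == code]
    state_trace_deg = state_trace_deg[_in_range_deg(state_trace_deg, lo, hi)]

    spike_labels = seg.label_at(spikes.times) if len(spikes) else np.empty(0, object)
    spike_deg = np.rad2deg(phase_trace.at_times(spikes.times)) % 360.0
    keep = np.array([lab == state for lab in spike_labels], dtype=bool)
    keep &= _in_range_deg(spike_deg, lo, hi)
    kept_times = spikes.times[keep]
    kept_deg = spike_deg[keep]

    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    if kept_times.size == 0:
        return StateRestrictedDistribution(
            state, phase_range_deg, np.empty(0), edges,
            np.zeros(n_bins), np.empty(0), float("nan"), 0)

    # rescale within-range offsets by the within-range state-phase CDF
    trace_off = np.sort(_unwrap_from(state_trace_deg, lo))
    spike_off = _unwrap_from(kept_deg, lo)
    m = trace_off.size
    cdf = (np.searchsorted(trace_off, spike_off, side="left")
           + np.searchsorted(trace_off, spike_off, side="right")) / (2.0 * m)
    rescaled = _wrap(_TWO_PI * cdf - np.pi)

    rel = np.empty(kept_times.size)
    for iv in seg.of_label(state):
        inside = iv.contains(kept_times)
        rel[inside] = (kept_times[inside] - iv.start) / iv.duration
    counts, _ = np.histogram(rescaled, bins=edges)
    density = counts / counts.sum()
    return StateRestrictedDistribution(
        state, phase_range_deg, rescaled, edges, density,
        rel, float(np.median(rel)), int(kept_times.size))
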