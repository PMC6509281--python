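"""Synthetic thalamo-cortical slow-oscillation recordings with ground truth.

The generator emulates the statistical structure the analyses assume:

* rhythmic alternation of up and down states at 0.2-1 Hz (semi-Markov
  two-state process with gamma-distributed durations);
* an LFP that is depth-positive during down states and depth-negative during
  up states (raised-cosine ramps at transitions), carrying band-limited
  [10, 51] Hz noise whose SD is larger in up states, on a 1/f background;
* a PV interneuron spike train strongly locked to the up-state phase with
  occasional down-state spikes, and a VPM multi-unit train more weakly
  locked: its up/down rate contrast is mild (spike-fraction difference
  ~0.16 versus ~0.46 for PV), so VPM fires in most down states;
* an optional causal VPM->PV coupling: each VPM spike fired in a down state
  transiently raises the PV intensity at a configurable lag;
* optogenetic sessions in which illumination onsets falling inside a down
  state evoke a down-to-up transition at a programmed latency.

Everything is deterministic under a fixed seed.  Default rates reproduce the
mean firing rates of the recordings the analyses were designed for
(PV ~3.4 spikes/s, VPM ~10 spikes/s).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .core import (Interval, SpikeSource, SpikeTrain, StateLabel,
                   StateSegmentation, StimulationProtocol, TimeSeries)
from .signal import PhaseTrace

__all__ = ["SynthParams", "GroundTruth", "Session", "OptoSession",
           "generate_states", "ideal_phase", "generate_lfp",
           "generate_spikes", "generate_voltage_traces",
           "generate_opto_session", "generate_session"]

# phase anchors of the idealized slow-oscillation cycle: an up state spans
# [90, 270] degrees, a down state [270, 450); mid-down = 0 = depth-positive
_UP_START = np.pi / 2
_UP_END = 3 * np.pi / 2

_OVERFLOW_RATE = 1e4  # spikes/s; intensity above this aborts thinning


@dataclass(frozen=True)
class SynthParams:
    """Knobs of the generator; defaults are the study conditions."""

    # state durations (gamma: mean seconds, shape)
    up_mean: float = 0.5
    up_shape: float = 4.0
    down_mean: float = 0.8
    down_shape: float = 4.0
    # LFP waveform
    delta_amp: float = 1.0
    ramp_down_to_up: float = 0.040   # s; down->up transitions are fast
    ramp_up_to_down: float = 0.080   # s; up->down transitions are slower
    betagamma_sd_down: float = 0.05  # [10,51] Hz noise SD in down states
    betagamma_ratio: float = 3.0     # up-state SD / down-state SD, > 1
    pink_sd: float = 0.05            # 1/f background SD
    # firing rates (spikes/s) per state
    pv_rate_up: float = 8.0
    pv_rate_down: float = 0.6
    vpm_rate_up: float = 15.1
    vpm_rate_down: float = 6.8
    # phase locking
    pv_kappa: float = 1.4
    vpm_kappa: float = 0.5
    preferred_phase_deg: float = 192.0
    # VPM -> PV coupling in down states
    coupling_lag: float = 0.020      # s
    coupling_sd: float = 0.005       # s, Gaussian bump SD
    coupling_gain: float = 0.1       # expected extra PV spikes per VPM spike
    # optogenetics
    opto_latency_mean: float = 0.11  # s, control conditions
    opto_latency_sd: float = 0.02
    stim_duration: float = 0.5       # s
    artifact_amp: float = 0.4
    artifact_duration: float = 0.004
    # muscimol-like mode
    muscimol_latency_mean: float = 0.25
    muscimol_latency_sd: float = 0.10
    muscimol_down_factor: float = 1.5
    muscimol_pv_suppression: float = 0.3
    # spike-waveform insertion (multiples of the noise SD)
    juxta_amp: float = 10.0
    mua_amp: float = 12.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("up_mean", "up_shape", "down_mean", "down_shape"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        for name in ("pv_rate_up", "pv_rate_down", "vpm_rate_up",
                     "vpm_rate_down", "coupling_gain"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def muscimol_like(self) -> "SynthParams":
        """Conditions after thalamic silencing: longer down states,
        suppressed PV down-state firing, slower evoked transitions."""
        return replace(
            self,
            down_mean=self.down_mean * self.muscimol_down_factor,
            pv_rate_down=self.pv_rate_down * self.muscimol_pv_suppression,
            vpm_rate_up=0.05, vpm_rate_down=0.01,
            opto_latency_mean=self.muscimol_latency_mean,
            opto_latency_sd=self.muscimol_latency_sd,
            coupling_gain=0.0,
        )


@dataclass
class GroundTruth:
    states: StateSegmentation
    pv: SpikeTrain | None = None
    vpm: SpikeTrain | None = None
    coupling_lag: float | None = None
    onsets: np.ndarray | None = None
    evoked_latencies: np.ndarray | None = None  # NaN where no transition inserted


@dataclass
class Session:
    lfp: TimeSeries
    pv: SpikeTrain
    vpm: SpikeTrain
    phase: PhaseTrace
    truth: GroundTruth


@dataclass
class OptoSession:
    lfp: TimeSeries
    protocol: StimulationProtocol
    truth: GroundTruth


def generate_states(params: SynthParams, total_duration: float,
                    seed: int | None = None) -> list[Interval]:
    """Alternating DOWN/UP tiling of ``[0, total_duration)``.

    Durations are i.i.d. gamma with the configured means and shapes,
    floored at 100 ms; the final interval is truncated at the end.
    """
    if not total_duration > 0:
        raise ValueError("total_duration must be positive")
    rng = np.random.default_rng(params.seed if seed is None else seed)
    intervals: list[Interval] = []
    t = 0.0
    label = StateLabel.DOWN
    while t < total_duration:
        if label == StateLabel.DOWN:
            mean, shape = params.down_mean, params.down_shape
        else:
            mean, shape = params.up_mean, params.up_shape
        d = max(rng.gamma(shape, mean / shape), 0.1)
        end = min(t + d, total_duration)
        intervals.append(Interval(t, end, label))
        t = end
        label = StateLabel.UP if label == StateLabel.DOWN else StateLabel.DOWN
    return intervals


def ideal_phase(states: Sequence[Interval], rate: float) -> PhaseTrace:
    """Idealized slow-oscillation phase, piecewise linear in time.

    Each up state sweeps [90, 270] degrees and each down state
    [270, 450) degrees, so mid-down sits at 0 (the depth-positive LFP peak)
    and mid-up at 180, matching the package phase convention.
    """
    end = states[-1].end
    n = int(round(end * rate))
    t = np.arange(n) / rate
    phase = np.empty(n)
    for iv in states:
        i0 = int(np.ceil(iv.start * rate - 1e-9))
        i1 = min(int(np.ceil(iv.end * rate - 1e-9)), n)
        frac = (t[i0:i1] - iv.start) / iv.duration
        if iv.label == StateLabel.UP:
            phase[i0:i1] = _UP_START + frac * np.pi
        else:
            phase[i0:i1] = _UP_END + frac * np.pi
    phase = np.mod(phase + np.pi, 2 * np.pi) - np.pi
    return PhaseTrace(phase, rate, (0.0, 2.0))


def _state_wave(states: Sequence[Interval], rate: float,
                params: SynthParams) -> np.ndarray:
    """Square alternation (+A down, -A up) with raised-cosine ramps
    starting at each boundary."""
    end = states[-1].end
    n = int(round(end * rate))
    t = np.arange(n) / rate
    A = params.delta_amp
    wave = np.where(_label_array(states, n, rate) == 2, -A, A).astype(float)
    for prev, nxt in zip(states[:-1], states[1:]):
        if prev.label == nxt.label:
            continue
        if nxt.label == StateLabel.UP:
            ramp, lo, hi = params.ramp_down_to_up, A, -A
        else:
            ramp, lo, hi = params.ramp_up_to_down, -A, A
        i0 = int(np.ceil(nxt.start * rate - 1e-9))
        i1 = min(int(np.ceil((nxt.start + ramp) * rate)), n)
        if i1 <= i0:
            continue
        frac = (t[i0:i1] - nxt.start) / ramp
        wave[i0:i1] = lo + (hi - lo) * 0.5 * (1 - np.cos(np.pi * frac))
    return wave


def _label_array(states: Sequence[Interval], n: int, rate: float) -> np.ndarray:
    """Per-sample codes DOWN=0, INDET=1, UP=2."""
    return StateSegmentation(states, rate).sample_labels(n)


def _pink_noise(n: int, sd: float, rng: np.random.Generator) -> np.ndarray:
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1] if n > 1 else 1.0
    spec /= np.sqrt(f)
    out = np.fft.irfft(spec, n)
    s = out.std()
    return out * (sd / s) if s > 0 else out


def generate_lfp(states: Sequence[Interval], params: SynthParams,
                 rate: float = 1000.0, seed: int | None = None) -> TimeSeries:
    """LFP trace consistent with a state tiling.

    Depth-positive baseline in down states, depth-negative in up states,
    with raised-cosine ramps at transitions; plus [10, 51] Hz band-limited
    noise whose SD is ``betagamma_ratio`` times larger in up states; plus a
    1/f background.
    """
    if rate < 300:
        raise ValueError("rate must be >= 300 Hz to represent the "
                         "beta-gamma band")
    from .signal import elliptic_filter  # local import to avoid cycle at module load
    rng = np.random.default_rng(params.seed if seed is None else seed)
    n = int(round(states[-1].end * rate))
    wave = _state_wave(states, rate, params)

    bg = np.zeros(n)
    if params.betagamma_sd_down > 0:
        white = TimeSeries(rng.standard_normal(n), rate)
        band = elliptic_filter(white, "band", (10.0, 51.0)).samples
        s = band.std()
        if s > 0:
            band /= s
        envelope = np.where(_label_array(states, n, rate) == 2,
                            params.betagamma_sd_down * params.betagamma_ratio,
                            params.betagamma_sd_down)
        # soften envelope steps over ~20 ms so the noise SD ramps smoothly
        k = int(round(0.02 * rate))
        if k > 1:
            kern = np.hanning(2 * k + 1)
            kern /= kern.sum()
            envelope = np.convolve(envelope, kern, mode="same")
        bg = band * envelope

    pink = _pink_noise(n, params.pink_sd, rng) if params.pink_sd > 0 else 0.0
    return TimeSeries(wave + bg + pink, rate, channel_label="LFP")


def _intensity(states: Sequence[Interval], phase: PhaseTrace,
               rate_up: float, rate_down: float, kappa: float,
               mu_deg: float) -> np.ndarray:
    """Per-sample intensity: state base rate x normalized von Mises gain.

    The gain is normalized within each state label so the realized mean
    rate in that state equals the configured base rate.
    """
    n = phase.phase.size
    labels = _label_array(states, n, phase.rate)
    mu = np.deg2rad(mu_deg)
    gain = np.exp(kappa * np.cos(phase.phase - mu))
    lam = np.zeros(n)
    for code, base in ((2, rate_up), (0, rate_down)):
        mask = labels == code
        if mask.any():
            g = gain[mask]
            lam[mask] = base * g / g.mean()
    return lam


def _thin(lam: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Sample an inhomogeneous Poisson process by thinning."""
    lam_max = float(lam.max())
    if lam_max > _OVERFLOW_RATE:
        raise ValueError(
            f"intensity peaks at {lam_max:.0f} spikes/s (> {_OVERFLOW_RATE:.0f}); "
            "reduce coupling_gain or widen coupling_sd")
    if lam_max <= 0:
        return np.empty(0)
    duration = lam.size / rate
    n_cand = rng.poisson(lam_max * duration)
    t_cand = np.sort(rng.uniform(0, duration, n_cand))
    idx = np.minimum((t_cand * rate).astype(int), lam.size - 1)
    keep = rng.uniform(0, lam_max, n_cand) < lam[idx]
    times = t_cand[keep]
    return times[np.concatenate(([True], np.diff(times) > 0))]


def generate_spikes(states: Sequence[Interval], lfp_phase: PhaseTrace,
                    params: SynthParams, seed: int | None = None,
                    ) -> tuple[SpikeTrain, SpikeTrain]:
    """PV and VPM spike trains locked to the slow-oscillation phase.

    Both are inhomogeneous Poisson processes (thinning) with state-dependent
    base rates and von Mises phase gains (``pv_kappa`` >> ``vpm_kappa``).
    With ``coupling_gain > 0`` every VPM spike fired in a down state adds a
    transient Gaussian bump (lag ``coupling_lag``, SD ``coupling_sd``, area
    ``coupling_gain``) to the PV intensity, making PV down-state spikes tend
    to follow VPM spikes.
    """
    rng = np.random.default_rng(params.seed if seed is None else seed)
    rate = lfp_phase.rate
    duration = lfp_phase.phase.size / rate
    lam_vpm = _intensity(states, lfp_phase, params.vpm_rate_up,
                         params.vpm_rate_down, params.vpm_kappa,
                         params.preferred_phase_deg)
    vpm_times = _thin(lam_vpm, rate, rng)

    lam_pv = _intensity(states, lfp_phase, params.pv_rate_up,
                        params.pv_rate_down, params.pv_kappa,
                        params.preferred_phase_deg)
    if params.coupling_gain > 0 and vpm_times.size:
        labels = _label_array(states, lam_pv.size, rate)
        down_vpm = vpm_times[labels[np.minimum((vpm_times * rate).astype(int),
                                               labels.size - 1)] == 0]
        half = int(np.ceil(4 * params.coupling_sd * rate))
        offs = np.arange(-half, half + 1)
        bump = (params.coupling_gain
                * np.exp(-0.5 * (offs / rate / params.coupling_sd) ** 2)
                / (params.coupling_sd * np.sqrt(2 * np.pi)))
        for tv in down_vpm:
            c = int(round((tv + params.coupling_lag) * rate))
            idx = c + offs
            ok = (idx >= 0) & (idx < lam_pv.size)
            lam_pv[idx[ok]] += bump[ok]
    pv_times = _thin(lam_pv, rate, rng)
    return (SpikeTrain(pv_times, SpikeSource.PV, duration),
            SpikeTrain(vpm_times, SpikeSource.VPM, duration))


def _biphasic(rate: float, positive_first: bool) -> np.ndarray:
    """Stereotyped biphasic spike waveform, peak-to-trough < 3 ms,
    unit dominant-lobe amplitude."""
    t = np.arange(-0.001, 0.0025, 1 / rate)
    main = np.exp(-0.5 * (t / 2.5e-4) ** 2)
    counter = -0.45 * np.exp(-0.5 * ((t - 8e-4) / 4e-4) ** 2)
    w = main + counter
    return w if positive_first else -w


def generate_voltage_traces(spikes: tuple[SpikeTrain, SpikeTrain] | SpikeTrain,
                            params: SynthParams, rate: float = 20000.0,
                            seed: int | None = None,
                            ) -> tuple[TimeSeries, TimeSeries]:
    """Raw voltage fixtures for the spike detectors.

    Inserts positive-dominant waveforms at PV spike times (juxtasomal trace)
    and negative-dominant waveforms at VPM times (MUA trace) on unit-SD
    Gaussian noise; waveform amplitudes are ``juxta_amp`` / ``mua_amp``
    noise-SD multiples.
    """
    if isinstance(spikes, SpikeTrain):
        spikes = (spikes, spikes)
    pv, vpm = spikes
    wave_len = 0.0035
    for train in (pv, vpm):
        if train.duration > 0 and train.rate * wave_len > 0.5:
            raise ValueError("spike rate too high: waveforms would overlap "
                             "more than half the time")
    rng = np.random.default_rng(params.seed if seed is None else seed)
    out = []
    for train, amp, positive in ((pv, params.juxta_amp, True),
                                 (vpm, params.mua_amp, False)):
        n = int(round(train.duration * rate))
        trace = rng.standard_normal(n)
        w = amp * _biphasic(rate, positive)
        lead = int(round(0.001 * rate))  # waveform peak sits at the spike time
        for t in train.times:
            i0 = int(round(t * rate)) - lead
            j0, j1 = max(i0, 0), min(i0 + w.size, n)
            trace[j0:j1] += w[j0 - i0:j1 - i0]
        out.append(TimeSeries(trace, rate,
                              channel_label="juxta" if positive else "MUA"))
    return out[0], out[1]


def generate_session(params: SynthParams, duration: float = 300.0,
                     seed: int | None = None, rate: float = 1000.0,
                     with_lfp: bool = True) -> Session:
    """Full spontaneous-activity session: states, LFP, phase, PV and VPM."""
    seed = params.seed if seed is None else seed
    ss = np.random.SeedSequence(seed).spawn(3)
    states = generate_states(params, duration, int(ss[0].generate_state(1)[0] % 2**31))
    phase = ideal_phase(states, rate)
    lfp = (generate_lfp(states, params, rate,
                        int(ss[1].generate_state(1)[0] % 2**31))
           if with_lfp else TimeSeries(np.zeros(len(phase)), rate))
    pv, vpm = generate_spikes(states, phase, params,
                              int(ss[2].generate_state(1)[0] % 2**31))
    truth = GroundTruth(StateSegmentation(states, rate), pv, vpm,
                        params.coupling_lag if params.coupling_gain > 0 else None)
    return Session(lfp, pv, vpm, phase, truth)


def generate_opto_session(params: SynthParams, n_trials: int,
                          seed: int | None = None, rate: float = 1000.0,
                          trial_length: float = 5.0,
                          ) -> OptoSession:
    """Optogenetic session of consecutive ``trial_length``-second trials.

    One illumination onset per trial, placed uniformly at random in the
    trial interior.  When an onset falls inside a true down state (with
    enough residual down time), a down-to-up transition is inserted at
    ``onset + latency`` with latency drawn from the configured normal
    distribution (floored at 20 ms).  A 4-ms half-cosine artifact is added
    at every onset.  For muscimol-like conditions pass
    ``params.muscimol_like()``.
    """
    if n_trials < 1:
        raise ValueError("need at least one trial")
    seed = params.seed if seed is None else seed
    ss = np.random.SeedSequence(seed).spawn(3)
    duration = n_trials * trial_length
    states = generate_states(params, duration,
                             int(ss[0].generate_state(1)[0] % 2**31))
    rng = np.random.default_rng(int(ss[1].generate_state(1)[0] % 2**31))

    onsets = np.array([i * trial_length
                       + rng.uniform(0.5, trial_length - 1.5)
                       for i in range(n_trials)])
    latencies = np.full(n_trials, np.nan)
    for k, onset in enumerate(onsets):
        idx = next((i for i, iv in enumerate(states)
                    if iv.start <= onset < iv.end), None)
        if idx is None or states[idx].label != StateLabel.DOWN:
            continue
        lat = max(rng.normal(params.opto_latency_mean, params.opto_latency_sd),
                  0.02)
        t_tr = onset + lat
        iv = states[idx]
        if t_tr >= iv.end - 0.01:
            continue  # the spontaneous transition happens first
        # truncate the down state and extend the following up state backwards
        new = [Interval(iv.start, t_tr, StateLabel.DOWN)]
        if idx + 1 < len(states):
            new.append(Interval(t_tr, states[idx + 1].end, StateLabel.UP))
            states = states[:idx] + new + states[idx + 2:]
        else:
            new.append(Interval(t_tr, iv.end, StateLabel.UP))
            states = states[:idx] + new
        latencies[k] = lat

    lfp = generate_lfp(states, params, rate,
                       int(ss[2].generate_state(1)[0] % 2**31))
    samples = lfp.samples.copy()
    n_art = int(round(params.artifact_duration * rate))
    artifact = params.artifact_amp * np.sin(
        np.pi * np.arange(n_art) / max(n_art - 1, 1))
    for onset in onsets:
        i0 = int(round(onset * rate))
        j1 = min(i0 + n_art, samples.size)
        samples[i0:j1] += artifact[:j1 - i0]
    lfp = lfp.with_samples(samples)

    protocol = StimulationProtocol(onsets, params.stim_duration)
    truth = GroundTruth(StateSegmentation(states, rate), onsets=onsets,
                        evoked_latencies=latencies)
    return OptoSession(lfp, protocol, truth)
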