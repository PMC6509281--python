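# Methods

`slowstates` analyzes cortical local field potential (LFP) recordings of the
slow oscillation — the 0.2–1 Hz alternation between active (up) and silent
(down) network states seen under anesthesia and deep sleep — together with
simultaneously recorded spike trains from cortical parvalbumin-positive (PV)
interneurons (juxtasomal, single cell) and the thalamic VPM nucleus
(multi-unit activity, MUA). The pipeline asks when each population fires
within the up/down cycle and whether thalamic firing statistically precedes
PV spikes during down states, and it measures how quickly optogenetic PV
inhibition during a down state evokes a down-to-up transition.

Conventions: times in seconds, intervals half-open `[start, end)`; sample
`i` covers `[t0 + i/rate, t0 + (i+1)/rate)`. Phases are radians in
`[-pi, pi)` internally and degrees `[0, 360)` in reports; 0° is the
depth-positive peak of the delta-filtered LFP (mid down state), so up states
cluster near 180°. In this depth-recording convention the up state is
depth-negative, and a down-to-up transition is a steep negative deflection.

## Data selection

Recordings are screened per consecutive 5-s trial with the synchronization
index: Welch power (2-s Hann segments, 50% overlap, band edges interpolated)
in [0.1, 4] Hz divided by [4, 100] Hz. Trials with index > 4 are
synchronized (slow-oscillation) epochs; for white noise the index equals the
bandwidth ratio ≈ 0.041.

## Up/down-state detection

The raw LFP is low-pass filtered below 500 Hz (elliptic, order 4, 0.1 dB
passband ripple, 40 dB stopband, applied forward–backward for zero phase —
the family's order and ripple are choices of this package; zero-phase
application preserves transition timing at the cost of doubling the ripple)
and decimated to the 1 kHz working rate. Two decision variables in [0, 1]
are computed:

- **Delta phase evidence** `s_delta`: for each of the bands [0–1] and
  [1–2] Hz, the Hilbert phase of the band-filtered trace is mapped through
  the raised cosine `(1 + cos(phi − 180°))/2` — 1 at the preferred up-state
  phase, 0 at the opposite phase — and the per-band evidences are averaged.
  For the DC-anchored [0–1] band the trace is low-passed at 1 Hz and
  demeaned before the analytic signal (a DC offset de-centers the Hilbert
  rotation). The raised cosine is the simplest monotone phase evidence
  satisfying the [0, 1] contract; it sits behind a function boundary so a
  likelihood-table variant can replace it.
- **Beta/gamma power evidence** `s_betagamma`: band-pass [10, 51] Hz,
  running RMS in a centered 5-ms frame, 50-ms centered moving average, then
  an affine map sending [minimum, 95th percentile] to [0, 1] with the top
  tail clipped. Scale-invariant by construction. Running frames are
  centered; the original direction is unspecified, and centering avoids a
  systematic boundary lag.

Their average `s_comb` (excluding its top 5th percentile) is fitted with a
three-Gaussian mixture by EM (scikit-learn, quantile-initialized means with
10 jittered restarts, seeded; traces are decimated to ≤ 20 000 samples for
the fit — the mixture is distributional, and the parameters are unchanged at
the reported precision). Components sorted by mean represent down,
indeterminate and up states. Samples strictly above
`theta_up = mu_UP − 2 sigma_UP` are up, strictly below
`theta_down = mu_DOWN + 2 sigma_DOWN` down, everything else (ties included)
indeterminate; a fit with `theta_down ≥ theta_up` is degenerate and refuses
to segment. Post-processing, applied once and in this order: indeterminate
gaps < 50 ms flanked by two same-label states are merged into that label,
then up/down runs < 100 ms are relabeled indeterminate — this order never
creates sub-100-ms states. After a pharmacological manipulation the mixture
is re-fitted on the new data.

On default 600-s synthetic sessions the segmentation agrees with the
generator's truth on ≥ 90% of up/down-classified samples with a median
boundary error below 25 ms (the residual error is dominated by the 50-ms
evidence smoothing and the band-pass ringing at transitions).

## Spike detection

*Juxtasomal*: 300 Hz high-pass (elliptic, zero-phase), threshold at 6× the
noise SD; each supra-threshold excursion yields one spike at its positive
peak, and peaks closer than 1 ms are merged keeping the larger (a noise dip
can split one action potential into two excursions). *Multi-unit (precise
timing spike detection)*: band-pass [300, 3000] Hz; each relative maximum is
paired with the deepest relative minimum within ±3 ms (peak lifetime); pairs
whose peak-to-peak amplitude exceeds 8.5× the noise SD (the configurable
midpoint of the stated 8–9 range) become events stamped at the negative
peak. A minimum already claimed by an event cannot found a second one (the
rebound maximum after a spike would otherwise re-trigger on ringing), and
overlap is resolved largest-first: events within the 1-ms refractory period
of an accepted event are discarded, and within the peak lifetime they are
discarded only when smaller than 60% of the accepted amplitude — ringing of
a merged waveform rather than a second spike. The noise SD defaults to the
Gaussian-scaled median absolute value `median(|x|)/0.6745`, robust to spike
contamination; the raw SD is available for parity checks. Both estimators
make detection invariant to amplitude rescaling, and raising the threshold
multiplier never adds detections.

## Phase locking

The instantaneous slow-oscillation phase is the angle of the Hilbert
transform of the [0.1, 4] Hz-filtered LFP. To cancel wave-shape asymmetry,
all phases are rescaled by the empirical cumulative distribution of the
phase over every time sample (`phi' = 2 pi F(phi) − pi`, mid-rank CDF,
linear between order statistics): after rescaling, the all-sample phase
distribution is uniform, so any non-uniformity of the spike-phase
distribution reflects genuine locking. Significance uses the Rayleigh
approximation `p = exp(sqrt(1 + 4n + 4(n² − R²n²)) − (1 + 2n))` at the 0.01
level; locking strength is the resultant length (one minus the circular
variance); the preferred phase is the circular mean; the von Mises
concentration solves `I1(kappa)/I0(kappa) = R̄` by Newton iteration (capped
at 10³). For state-restricted distributions, spikes are kept when their
interval label matches and their phase lies in the state's 5th–95th
percentile range — [95, 255]° for up, [295, 75]° for down (wrapping through
0°; all range logic lives on the circle) — and are rescaled by the
within-range CDF of same-state trace phases (indeterminate samples
excluded). Relative firing time is `(t − start)/(end − start)` within each
spike's own interval.

## Spike-triggered thalamic firing rate and surrogate null

The VPM instantaneous firing rate (IFR) is the spike train convolved with a
unit-area Gaussian kernel (SD 12.5 ms ≈ 20 Hz low-pass; the scan range
1.25–12.5 ms is configurable), conserving spike count. PV spikes fired in
down states trigger IFR segments; the statistics are the mean rates in the
100-ms pre-window `[−w, 0)` and post-window `(0, +w]` — the trigger sample
belongs to neither, which makes time reversal swap the two windows exactly.

The null preserves everything about PV down-state firing except its timing
relative to VPM: 100 surrogate spike sets are placed in PV-silent down
states, each preserving the real total spike count, the real down-state
phase-of-firing distribution (phases resampled from the real spike phases
and mapped to the circularly nearest phase sample inside the chosen state,
ties to the earliest), the real maximum spikes per state, and the real
number of sampled states. Silent states shorter than twice the window are
ineligible (the windows must fit). Two sampling choices matter for
calibration: states are sampled with probability proportional to their
duration, and each surrogate's spikes are spread over its states
multinomially in proportion to duration (capped at the real per-state
maximum). Both mirror the real process — a near-Poisson train occupies
states length-biased and with counts scaling with duration — and without
them the null systematically swaps long states for short ones, whose
windows bleed into the adjacent high-rate up states and bias the z-score
(measured mean z ≈ −0.5 under independence). With them the one-tailed test
`z = (real − mean_surr)/sd_surr`, `p = 1 − Phi(z)` rejects at 5.0% under
independence (60-run measurement; the acceptance suite re-measures over
200 runs) and detects the generator's 20-ms VPM→PV coupling in ≥ 80% of
runs at the default gain.

Supporting statistics: the per-trigger paired pre-vs-post Wilcoxon
signed-rank test (one-tailed toward pre excess); pre/post rates normalized
to the surrogate grand mean, reported as percent variation;
Benjamini–Hochberg FDR (statsmodels step-up, cross-checked in the tests
against an exhaustive oracle); and the exact binomial upper tail
`P(X ≥ k | n, p0)` computed in log space, used to combine per-cell
significance calls into a population statistic. For `m` significant cells
out of `n` at per-test level `p0`, the pipeline's convention passes
`k = m + 1`.

## Evoked down-to-up transition latency

Each 5-s optogenetic trial carries a 500-ms illumination; the light artifact
(~4 ms) is corrected by subtracting the across-trial mean of artifact-only
trials (those without a transition-like derivative excursion 8–30 ms after
onset) inside a 60-ms window centered on every onset, then smoothing that
window with a 14-ms moving average crossfaded over the outer 10 ms so no
edge discontinuity is introduced. The putative-down mask is the set of
samples where `s_betagamma` (10-ms RMS frames here) is below its overall
median — computed on the artifact-subtracted but *unsmoothed* trace, since
the window smoothing would suppress beta/gamma power and fake a down-state
dip at every onset. Alternative thresholds (half-maximum of the first
density peak; mu + sigma of the lower component of a two-Gaussian fit) are
provided, and control-condition thresholds can be reused after a
manipulation.

For an onset inside a putative down state, the LFP derivative is taken on a
14-ms moving-averaged trace (so transition slopes, not per-sample noise,
dominate the in-state statistics), mu and sigma are computed from the
derivative within that state, and the latency is the time to the first
sample with derivative below `T = mu − k sigma` (k = 4 evoked; k = 2 for
the slower spontaneous slopes). The search extends 150 ms past the masked
run's end because the centered evidence smoothing and filter ringing pull
the detected state edge earlier than the transition itself; trials without
a crossing are censored and excluded from means (the handling is a choice
of this package). Spontaneous latencies use periodic surrogate onsets
(default 0.5-s grid; the period is unstated in the original procedure and a
grid-phase robustness check is provided) restricted to spontaneous activity
— ≥ 50 ms before every onset or ≥ 550 ms after every offset — and the
summary is the ratio of mean evoked to mean spontaneous latency.

A known property of the `mu − k sigma` rule on this generator: Gaussian-like
band noise crosses a k-sigma threshold at a scale-free rate (~2% of samples
at k = 2 regardless of noise amplitude), so spontaneous latencies are
noise-crossing-dominated and shorter than the residual down time. Evoked
latencies are transition-dominated (the evoked ramp is far steeper than
k = 4 noise excursions) and are recovered within 10 ms of the programmed
values; they are also robust to the putative-down threshold method, whereas
the spontaneous side — and hence the absolute ratio — is not. The
control-versus-muscimol contrast of the ratio, the quantity of interest,
is insensitive to these choices.

## Synthetic data generator

The generator emulates the statistical structure the analyses assume; it is
a stand-in for the recordings, not a biophysical model, and all
distributional choices below are package choices.

- **States**: semi-Markov alternation with gamma-distributed durations
  (up: mean 0.5 s, down: mean 0.8 s, shape 4, floored at 100 ms), putting
  the cycle at ~0.77 Hz, inside the 0.2–1 Hz slow-oscillation band.
- **LFP**: depth-positive baseline in down states, depth-negative in up
  states with raised-cosine ramps (40 ms down→up, 80 ms up→down — fast
  rising transitions, slower falling ones); [10, 51] Hz band-limited noise
  whose SD is 3× larger in up states (envelope softened over 20 ms); a 1/f
  background.
- **Phase**: the idealized phase is piecewise linear in time — an up state
  sweeps [90°, 270°], a down state [270°, 450°) — so mid-down is 0°
  (depth-positive peak) and mid-up 180°, approximating the 5th–95th
  percentile state ranges used by the state-restricted analyses.
- **Spikes**: inhomogeneous Poisson by thinning (exact and seedable);
  intensity = state base rate × a von Mises phase gain normalized within
  each state (PV kappa 1.4 as in the recordings' von Mises fits, VPM 0.5).
  Rates: PV 8.0 up / 0.6 down sp/s (mean 3.45, matching PV interneurons'
  ~3.4 sp/s with an up−down spike-fraction difference of ~0.46); VPM
  15.1 up / 6.8 down sp/s (mean 10.0, matching the VPM MUA's ~10 sp/s with
  a fraction difference of ~0.16 — the milder contrast is what makes VPM
  locking weaker than PV locking). With a Poisson train at these rates
  nearly every down state contains VPM spikes; matching a lower VPM
  active-down-state ratio would require an over-dispersed (bursty) process
  and would invert the locking order, so the rate contrast takes precedence.
- **Coupling**: each VPM spike in a down state adds a Gaussian bump
  (lag 20 ms, SD 5 ms, area `gain` = expected extra PV spikes, default 0.1)
  to the PV intensity — a causal VPM→PV drive confined to down states.
- **Optogenetics**: one onset per 5-s trial, uniform in the trial interior;
  an onset inside a true down state truncates it at onset + latency with
  latency ~ Normal(0.11, 0.02) s under control conditions, floored at
  20 ms. The muscimol-like mode multiplies the down-duration mean by 1.5,
  suppresses PV down-state firing to 30%, nearly silences VPM, and draws
  latencies from Normal(0.25, 0.10) s — the reported dispersion of the
  muscimol-condition latencies (±0.4 s) exceeds their mean and would make
  most draws negative under any location-scale law, so the SD is clamped
  at 0.10 s. A 4-ms half-cosine artifact (amplitude 0.4) is added at every
  onset.
- **Voltage fixtures**: stereotyped biphasic waveforms (positive-dominant
  juxtasomal, negative-dominant MUA, peak-to-trough < 3 ms) at the spike
  times on unit-SD Gaussian noise at 20 kHz, amplitudes 10× / 12× the noise
  SD. Spikes closer than the waveform span merge and are documented as
  unresolvable.

Everything is deterministic under a fixed seed (independent sub-seeds per
stage). What passing tests show: the pipeline recovers state boundaries,
locking order, programmed coupling lags and programmed latencies *under
these conditions* — stationary rates, Poisson spiking, stereotyped
waveforms, Gaussian noise. Real recordings add non-stationarity, bursting,
electrode drift, movement artifacts and unit contamination that the
generator deliberately omits; results on real data should be accompanied by
the same calibration checks the test suite runs here.

## Numerical choices and degenerate inputs

Filters are realized as second-order sections (stable at the delta bands'
very low normalized cutoffs) and applied forward–backward. Running windows
truncate at the trace edges. The EM fit converges at a per-sample
log-likelihood change of 1e-6 or 500 iterations, best of 10 restarts.
Kappa inversion caps at 10³; a zero resultant yields kappa 0 with an
undefined mean. Zero traces, constant evidence, degenerate mixtures, empty
spike sets, zero-spread surrogate distributions and unsatisfiable surrogate
constraints all raise informative errors rather than returning silently
wrong numbers. Problem sizes in the test suite (600-s sessions for state
detection, 240-s for the surrogate analyses, 60-s for spike detection,
200/50 runs for calibration/power) were chosen as the smallest that make
the statistical assertions stable.

## Out of scope

Spike sorting (the MUA is analyzed as a population signal), wavelet or
spectrogram analysis, streaming detection, and the linear mixed-effects
confirmation of the latency contrasts: the pipeline exports a tidy
per-trial latency table, and a model such as
`latency ~ treatment * stimulation + (1 | animal:treatment) + (1 | animal:stimulation)`
can be fitted in any standard mixed-model tool (e.g. `lme4`). Circular
group comparisons (Watson–Williams) are likewise delegated to standard
circular-statistics routines.
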