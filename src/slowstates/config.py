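"""Analysis configuration: every numeric parameter of the pipeline in one place.

Defaults are the values used throughout the analyses (filter bands, evidence
post-processing frames, detection thresholds, surrogate counts, derivative
thresholds).  The object serializes to/from JSON with round-trip identity so a
run can be reproduced from its sidecar config file.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path


@dataclass
class AnalysisConfig:
    # -- working rates -----------------------------------------------------
    working_rate: float = 1000.0        # Hz, after low-pass + downsample
    lowpass_hz: float = 500.0           # anti-alias low-pass before decimation

    # -- synchronization index --------------------------------------------
    sync_trial_len: float = 5.0         # s
    sync_low_band: tuple[float, float] = (0.1, 4.0)
    sync_high_band: tuple[float, float] = (4.0, 100.0)
    sync_threshold: float = 4.0         # index > 4 -> synchronized epoch

    # -- up/down-state detection ------------------------------------------
    delta_bands: tuple[tuple[float, float], ...] = ((0.0, 1.0), (1.0, 2.0))
    preferred_phase_deg: float = 180.0  # phase of the up state
    betagamma_band: tuple[float, float] = (10.0, 51.0)
    rms_frame: float = 0.005            # s, running RMS frame
    smooth_frame: float = 0.050         # s, moving-average frame
    norm_percentile: float = 95.0       # top tail excluded from normalization
    gmm_restarts: int = 10
    gmm_seed: int = 0
    min_state_duration: float = 0.100   # s
    min_interstate_gap: float = 0.050   # s

    # -- spike detection ---------------------------------------------------
    juxta_highpass_hz: float = 300.0
    juxta_threshold_mult: float = 6.0
    ptsd_band: tuple[float, float] = (300.0, 3000.0)
    ptsd_peak_lifetime: float = 0.003   # s
    ptsd_threshold_mult: float = 8.5    # the stated 8-9 range, midpoint
    ptsd_refractory: float = 0.001      # s
    noise_sd_estimator: str = "robust_mad"  # or "raw_sd"

    # -- phase locking ------------------------------------------------------
    phase_band: tuple[float, float] = (0.1, 4.0)
    rayleigh_alpha: float = 0.01
    histogram_bins: int = 18            # 20-degree bins
    up_phase_range_deg: tuple[float, float] = (95.0, 255.0)
    down_phase_range_deg: tuple[float, float] = (295.0, 75.0)  # wraps through 0

    # -- spike-triggered analysis -------------------------------------------
    sta_kernel_sd: float = 0.0125       # s (20 Hz equivalent low-pass)
    sta_window: float = 0.100           # s, pre/post windows
    sta_curve_halfwidth: float = 0.5    # s, plotted triggered-IFR extent
    n_surrogates: int = 100
    sta_seed: int = 0

    # -- evoked-transition latency ------------------------------------------
    artifact_window: float = 0.060      # s, centered on onset
    artifact_smooth: float = 0.014      # s, moving average inside the window
    opto_rms_frame: float = 0.010       # s (latency pipeline uses 10 ms)
    k_evoked: float = 4.0
    k_spontaneous: float = 2.0
    spont_pre_guard: float = 0.050      # s before each onset
    spont_post_guard: float = 0.550     # s after each offset
    surrogate_onset_period: float = 0.5  # s, grid of surrogate onsets
    trial_length: float = 5.0           # s

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "AnalysisConfig":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        data = json.loads(text)
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name not in data:
                continue
            v = data[f.name]
            # JSON has no tuples; restore the declared shapes
            if isinstance(v, list):
                v = tuple(tuple(x) if isinstance(x, list) else x for x in v)
            kwargs[f.name] = v
        return cls(**kwargs)
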