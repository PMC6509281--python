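"""Detect spikes from synthetic juxtasomal and multi-unit voltage traces.

Inserts known spike waveforms (10x and 12x the noise SD) on Gaussian noise
at 20 kHz, then runs the hard-threshold juxtasomal detector and the
precise-timing (PTSD) multi-unit detector and scores them against the
ground-truth spike times.
"""

import numpy as np

from slowstates import (SynthParams, detect_juxtasomal, detect_ptsd,
                        generate_spikes, generate_states,
                        generate_voltage_traces, ideal_phase)

params = SynthParams(coupling_gain=0.0)
states = generate_states(params, 60.0, seed=41)
phase = ideal_phase(states, 1000.0)
pv, vpm = generate_spikes(states, phase, params, seed=42)
juxta, mua = generate_voltage_traces((pv, vpm), params, 20000.0, seed=43)

for name, true, det in (("juxtasomal (PV)", pv, detect_juxtasomal(juxta)),
                        ("PTSD (VPM MUA)", vpm, detect_ptsd(mua))):
    matched, used, errs = 0, np.zeros(len(det), bool), []
    for t in true.times:
        d = np.abs(det.times - t)
        i = int(np.argmin(d))
        if d[i] <= 0.0005 and not used[i]:
            matched += 1
            used[i] = True
            errs.append(d[i])
    print(f"{name}: {len(true)} true spikes, {len(det)} detected; "
          f"recall {matched / len(true):.1%}, "
          f"precision {matched / len(det):.1%}, "
          f"median timing error {1e3 * np.median(errs):.3f} ms")

print()
print("Recall is the fraction of inserted spikes recovered within 0.5 ms;")
print("precision is the fraction of detections that match a real spike.")
print("Both detectors should exceed 95% at these waveform amplitudes.")
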