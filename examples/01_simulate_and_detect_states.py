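"""Simulate a slow-oscillation session and segment it into up/down states.

Generates 300 s of synthetic LFP with ground-truth state boundaries, runs
the evidence/mixture/threshold detector, and compares the segmentation
against the truth.
"""

import numpy as np

from slowstates import SynthParams, detect_states, generate_session

session = generate_session(SynthParams(), duration=300.0, seed=1)
seg, evidence, fit = detect_states(session.lfp)

truth = session.truth.states.sample_labels()
detected = seg.sample_labels(len(truth))
classified = detected != 1  # samples called up or down (not indeterminate)
agreement = np.mean(truth[classified] == detected[classified])

det_bounds = np.array([iv.start for iv in seg.intervals[1:]])
errors = [np.min(np.abs(det_bounds - iv.start))
          for iv in session.truth.states.intervals[1:]]

print(f"mixture thresholds: theta_down={fit.theta_down:.3f}, "
      f"theta_up={fit.theta_up:.3f}")
print(f"detected {len(seg.of_label('UP'))} up states, "
      f"{len(seg.of_label('DOWN'))} down states in 300 s")
print(f"sample-wise up/down agreement with ground truth: {agreement:.1%}")
print(f"median boundary error: {1000 * np.median(errors):.1f} ms")
print()
print("The agreement is the fraction of up/down-classified milliseconds")
print("whose label matches the generator's truth; the boundary error is")
print("how far each true state transition lies from the nearest detected")
print("one.  Values near 98% and below 25 ms mean the evidence variables")
print("and the three-Gaussian thresholds recover the slow oscillation.")
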