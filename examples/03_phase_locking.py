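"""Quantify phase locking of PV and VPM spikes to the slow oscillation.

Extracts the delta-band ([0.1, 4] Hz) Hilbert phase of a synthetic LFP,
rescales it by its cumulative distribution so the all-sample phase
occupancy is uniform, and summarizes each train's phase-of-firing
distribution: Rayleigh test, locking strength (one minus the circular
variance), preferred phase, and a von Mises fit.
"""

from slowstates import SynthParams, generate_session, hilbert_phase, phase_locking

session = generate_session(SynthParams(), duration=240.0, seed=2)
phase = hilbert_phase(session.lfp, band=(0.1, 4.0))

for name, train in (("PV interneuron", session.pv),
                    ("VPM multi-unit", session.vpm)):
    res = phase_locking(phase, train)
    print(f"{name}: n={res.n_spikes} spikes")
    print(f"  Rayleigh p = {res.rayleigh_p:.2e} "
          f"({'locked' if res.rayleigh_p < 0.01 else 'not locked'} at 0.01)")
    print(f"  locking strength = {res.locking_strength:.3f}, "
          f"preferred phase = {res.preferred_phase_deg:.0f} deg")
    print(f"  von Mises fit: mu = {res.von_mises_mu_deg:.0f} deg, "
          f"kappa = {res.von_mises_kappa:.2f}")

print()
print("0 deg is the depth-positive LFP peak (mid down state); up states")
print("occupy phases around 180 deg, so both trains prefer ~180 deg.")
print("PV locking is stronger than VPM locking, matching the recordings")
print("these synthetic sessions emulate.")
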