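"""Substitution-method round trip: simulate a specimen pair, then analyze it.

A single-cycle 1 MHz burst is propagated through a simulated water path
with and without a 6 mm specimen whose true properties match the
without-fiber muscle material; the analysis pipeline (DC removal, x8
upsampling, cross-correlation delay, Hann-windowed Hilbert envelope)
recovers the speed of sound and attenuation from the waveforms alone.
"""

import tmmchar as tc

water = tc.WaterReference()  # 1481 m/s, 1.000 g/cm3
truth = tc.MediumProperties(
    speed_of_sound_c=1578.3, density_rho=1.04, attenuation_alpha=0.50
)
geom = tc.SpecimenGeometry(mode="solid_acoustic", thickness_d=6e-3)

pair = tc.simulate_pair(truth, geom, water,
                        tc.SimulationConfig(noise_sd=1e-3, n_averages=64, seed=7))
props, meas = tc.characterize_specimen(pair, density=1.04)

print(f"time offset      {meas.delta_t * 1e9:8.1f} ns   (positive: specimen faster than water)")
print(f"speed of sound   {props.speed_of_sound_c:8.1f} m/s  (truth 1578.3)")
print(f"attenuation      {props.attenuation_alpha:8.3f} dB/cm/MHz (truth 0.50)")
print(f"impedance        {props.impedance_Z:8.3f} MRayls")
# The recovered speed should sit within ~2 m/s of truth: the 1 ns delay
# resolution maps to ~0.2 m/s at this thickness, and 64-fold averaging
# suppresses the added noise.
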