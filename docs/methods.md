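# Methods

## The substitution measurement and its analysis

The through-transmission substitution method estimates a specimen's
speed of sound and attenuation by difference against a water path of
known properties. The analysis chain operates on a calibration/specimen
pair of uniformly sampled voltage records:

1. **DC removal.** The record mean is subtracted; AC-coupled scopes
   still leave a residual offset that would bias both the correlation
   and the envelope.
2. **Upsampling.** Both records are interpolated ×8 by polyphase FIR
   resampling (`scipy.signal.resample_poly`), taking the native 8 ns
   period at 125 MSPS to 1 ns. Polyphase interpolation is used rather
   than FFT resampling to avoid wrap-around artifacts at the record
   edges; the band-limited interpolation contract is tested against
   analytic sines and Gaussian bursts.
3. **Delay.** Δt is the lag maximizing the full cross-correlation of
   specimen against calibration, with positive Δt meaning the specimen
   pulse arrives earlier (faster than water). The resolution is exactly
   one upsampled sample period: no sub-sample (parabolic) peak
   interpolation is applied, so a reported delay is always an integer
   number of nanoseconds at the default settings. Ties in the
   correlation maximum — possible for periodic inputs — are broken
   toward the smallest-magnitude lag. Differing record start times
   (`t0`) enter the delay additively.
4. **Amplitude.** Each record is multiplied by a Hann window centered
   at the sample of maximum absolute voltage, then the peak of the
   Hilbert-transform envelope is taken. The window span defaults to
   4 µs — four carrier periods at 1 MHz — wide enough that its flat
   center preserves the pulse peak, narrow enough to reject reflections
   and late arrivals; the span is configurable because the appropriate
   value scales with the burst length. Window segments falling outside
   the record are zero.
5. **Properties.** `c_spec = 1/(1/c_water − Δt/d)` and
   `α = 20 log10(P_cal/P_spec)/(100 d f_c)`. In liquid-specimen mode the
   liquid replaces the whole water column, so `d` is the full
   transmitter-to-hydrophone path. A zero offset returns the water
   reference speed identically (the relation reduces to `c = c_water`,
   applied as an exact identity rather than a double reciprocal).
   A negative attenuation triggers a warning, not an error: on a thin,
   low-loss specimen, noise can push the specimen envelope above the
   calibration envelope. The reported property clamp is at zero.

Interface reflection losses are *not* subtracted from the attenuation.
For water-matched media the energy transmission coefficient
T_E = 1 − Γ² of the two specimen faces exceeds 0.99, so the insertion
loss is attributed to bulk attenuation; T_E is reported alongside so the
user can judge the approximation for mismatched media.

The water reference defaults to 1481 m/s and 1.000 g/cm³ with zero
attenuation, with no temperature correction — the package treats the
reference speed as a calibration constant supplied by the user.

## Mechanical analysis

Load–displacement records are converted to engineering stress
(load / initial contact area) and engineering strain
(displacement / initial reference length); no geometry update and no
pre-compression offset are applied. For compression the contact area
defaults to the 10 mm indenter cross-section — the load path — rather
than the 40 mm specimen face; both are configurable since either
convention appears in practice. For tension the dogbone cross-section
(6 × 2.5 mm) and the 59 mm gauge length are the defaults. Compression
records are reported as positive magnitudes. Raw machine data need not
be monotonic in displacement; pairs are stably sorted by strain so the
curve satisfies its non-decreasing invariant without breaking the
(strain, stress) pairing — the windowed OLS fit is order-independent, so
this is purely representational.

Young's modulus is the OLS slope of stress on strain over the closed
[0.10, 0.20] strain window, reported with the in-window point count and
R². The window excludes the compliant toe/settling region below 10%
strain and the onset of nonlinearity above 20%; its bounds are inclusive
and configurable. Replicate summaries use the sample standard deviation
(n−1), reported as absent for a single replicate.

Geometry validation enforces the buckling rule for compression
specimens — height : smallest planar dimension ≤ 1:4, inclusive — and
that the 2 mm indentation depth is smaller than the specimen thickness.

## The forward simulator

The generator inverts the analysis relations, which makes parameter
recovery a meaningful end-to-end check rather than a tautology: the
simulator writes time-domain waveforms, and the estimators must undo the
sampling, windowing and correlation to get the parameters back.

* The excitation is a single-cycle 1 MHz sine burst sampled at
  125 MSPS, evaluated analytically at arbitrary fractional delays (no
  resampling in the generator).
* The calibration burst arrives after a 35 µs path delay (inside the
  30–40 µs range a ~5 cm water path implies); the specimen burst is
  advanced by d·(1/c_water − 1/c_medium) and scaled by
  10^(−α·100d·f_c/20).
* Attenuation acts as a pure amplitude scale at the carrier frequency.
  The analysis measures only the envelope-peak ratio at f_c, so a
  dispersive (frequency-resolved) loss model would add parameters the
  measurement cannot constrain.
* Two-interface transmission losses (amplitude factor T_E, which at
  normal incidence equals the product of the two pressure transmission
  coefficients) are off by default, matching the negligible-reflection
  treatment; a flag enables them for sensitivity studies.
* Noise is white Gaussian per sweep with a residual DC offset;
  progressive n-fold averaging is simulated by averaging independent
  sweeps, so the √n noise reduction holds by construction and is
  verified empirically on the pre-pulse region. A seed is mandatory
  whenever noise is enabled; identical configurations are bit-identical.

The mechanical generator produces a piecewise curve — zero stress up to
an optional toe strain (< 0.10 by construction, so it can never reach
the fit window), then linear with the requested modulus — sampled at the
40 Hz machine rate implied by the protocol's displacement rate, with
multiplicative Gaussian amplitude noise.

What the simulator does **not** emulate: diffraction and beam spreading,
scattering heterogeneity (the fiber-network materials' high attenuation
arises physically from scattering, which here is represented only by its
net amplitude effect), transducer impulse response, multipath
reflections, temperature drift, and viscoelastic time dependence in the
mechanical tests. Passing recovery tests therefore demonstrates the
correctness of the estimators under the stated signal model, not
robustness to every artifact of a physical tank.

## Reference tables and compliance

The packaged JSON tables transcribe the literature target ranges, the
material recipes (data only — no recipe→property model is attempted) and
the measured properties of the five developed materials, including known
internal inconsistencies, verbatim: the without-fiber muscle attenuation
appears as 0.50 (table) with the alternative text value 0.25 recorded in
a note; attenuation SDs larger than their means are kept as printed; and
printed impedances, which derive from unrounded inputs, are stored
separately from the ρ·c product of the rounded values (they agree within
0.01 MRayls, the tolerance used by the integrity tests).

Compliance checks use inclusive bounds and report the relative deviation
to the nearest violated bound, the convention used when quoting a value
as "x% below the lower bound". Properties without a literature range
(the soft-tissue modulus) are marked `no_range`, not failed.

Bladder geometry: the phantom body is two half tri-axial ellipsoids with
shared in-plane semi-axes, V = (2π/3)·a·b·(c_top + c_bottom) in mL for
cm inputs; the design dimensions (3.25, 2.75, 2 + 4.75 cm) give
126.4 mL against the ~125 mL design target. Wall thickness is checked
against the 2.2–4.4 mm anatomical range.

## Numerical and testing choices

* All internal computation is SI; conversions to reporting units happen
  at the boundary (`impedance_mrayls`, kPa properties). This removes
  any ambiguity about the 100·d unit factor in the attenuation formula.
* Waveform CSVs written by the package carry exact metadata
  (`sampling_rate_hz`, `t0_s`) in comment lines, so read(write(w)) == w
  bitwise; foreign scope exports are parsed by inferring the rate from
  the **median** time step (robust to one corrupted row) and rejecting
  files whose steps deviate from the median by more than 0.1%.
* Acceptance-style recovery tests run at the measurement's own scale
  (6 mm specimens, 60 µs records, 200 noisy replicates cycling the five
  packaged materials, 500-replicate modulus Monte Carlo); the whole
  suite completes in well under a minute on one core.
* Energy conservation Γ² + T_E = 1 is asserted to 4 machine epsilons:
  with T_E computed as 1 − Γ², bitwise equality is not an IEEE
  guarantee for small Γ², though it holds on every pair tested.

## Known limitations

* No diffraction or beam-spreading correction, and no spectral-ratio
  (frequency-resolved) attenuation estimate — the attenuation is a
  single-frequency insertion-loss value at f_c.
* The delay estimator assumes one dominant pulse per record; strong
  reverberation would require gating before analysis.
* The water reference is a constant; measurements at a different bath
  temperature must override `WaterReference.speed_of_sound` themselves.
* Compression moduli depend on the contact-area convention (indenter
  vs specimen face); results using the other convention scale by the
  area ratio.
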