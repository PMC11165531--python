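"""Substitution-method DSP stages and property relations."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import tmmchar as tc
from tmmchar.errors import (
    DegenerateSignalError,
    NonphysicalDelayError,
    ParameterError,
)
from .conftest import forward_delay

FS = 1.25e8


def _sine(freq=1e6, amp=0.08, n=5000, fs=FS, offset=0.0):
    t = np.arange(n) / fs
    return tc.Waveform(amp * np.sin(2 * np.pi * freq * t) + offset, fs)


class TestRemoveDc:
    def test_constant_becomes_zero(self):
        w = tc.Waveform(np.full(100, 0.3), FS)
        assert np.allclose(tc.remove_dc(w).samples, 0.0)

    def test_zero_mean_sine_unchanged(self):
        w = _sine(n=5000)  # integer number of periods at 125 MSPS
        assert np.allclose(tc.remove_dc(w).samples, w.samples, atol=1e-12)

    def test_offset_sine_recovers_pure_sine(self):
        clean = _sine(n=5000)
        shifted = tc.Waveform(clean.samples + 0.05, FS)
        assert np.allclose(tc.remove_dc(shifted).samples, clean.samples, atol=1e-12)
        assert abs(np.mean(tc.remove_dc(shifted).samples)) < 1e-12 * np.std(
            shifted.samples
        )


class TestUpsample:
    def test_factor_one_is_identity(self):
        w = _sine()
        assert tc.upsample(w, 1) == w

    def test_sine_matches_analytic_interior(self):
        w = _sine(n=2500)
        up = tc.upsample(w, 8)
        assert up.sampling_rate == 8 * FS
        t = np.arange(up.n) / up.sampling_rate
        expected = 0.08 * np.sin(2 * np.pi * 1e6 * t)
        interior = slice(16, up.n - 16)
        assert np.max(np.abs(up.samples[interior] - expected[interior])) < 0.01 * 0.08

    def test_gaussian_burst_peak_location_preserved(self):
        t = np.arange(5000) / FS
        tp = 20e-6
        w = tc.Waveform(np.exp(-(((t - tp) / 2e-6) ** 2)), FS)
        up = tc.upsample(w, 8)
        peak_t = np.argmax(up.samples) / up.sampling_rate
        assert abs(peak_t - tp) <= 1 / up.sampling_rate + 1e-15

    def test_rejects_factor_below_one(self):
        with pytest.raises(ParameterError):
            tc.upsample(_sine(), 0)


def _burst_pair(shift_raw_samples=0, n=6000):
    """Calibration burst mid-record plus a copy advanced by whole raw samples."""
    cfg = tc.SimulationConfig(record_duration=n / FS)
    cal = tc.simulate_pair(
        tc.MediumProperties(1481.0), tc.SpecimenGeometry("solid_acoustic", 6e-3),
        cfg=cfg,
    ).calibration
    spec_samples = np.roll(cal.samples, -shift_raw_samples)
    return cal, tc.Waveform(spec_samples, FS, label="specimen")


class TestEstimateDelay:
    def test_identical_records_give_zero(self):
        cal, _ = _burst_pair()
        assert tc.estimate_delay(cal, cal) == 0.0

    def test_shift_of_250_upsampled_samples(self):
        # 250 ns advance constructed analytically in the generator
        med = tc.MediumProperties(1578.3)
        geom = tc.SpecimenGeometry("solid_acoustic", 6e-3)
        pair = tc.simulate_pair(med, geom)
        dt = tc.estimate_delay(pair.calibration, pair.specimen)
        expected = forward_delay(1578.3, 6e-3)  # 249.76 ns
        assert dt == pytest.approx(expected, abs=1.0e-9)

    def test_three_raw_samples_recovered_exactly(self):
        cal, spec = _burst_pair(shift_raw_samples=3)
        dt = tc.estimate_delay(cal, spec)
        assert dt == 3 / FS  # 24 ns, exact at 1 ns resolution

    def test_all_zero_record_rejected(self):
        cal, _ = _burst_pair()
        flat = tc.Waveform(np.zeros(cal.n), FS)
        with pytest.raises(DegenerateSignalError):
            tc.estimate_delay(cal, flat)

    def test_mismatched_rates_rejected(self):
        cal, spec = _burst_pair(3)
        other = tc.Waveform(spec.samples, FS * 2)
        with pytest.raises(ParameterError):
            tc.estimate_delay(cal, other)

    def test_record_start_offset_enters_delay(self):
        """A specimen record that starts later but holds the same samples
        represents a later arrival by exactly the t0 difference."""
        cal, _ = _burst_pair()
        shifted_t0 = tc.Waveform(cal.samples, FS, t0=cal.t0 + 1e-6)
        assert tc.estimate_delay(cal, shifted_t0) == pytest.approx(-1e-6)


class TestEnvelopeAmplitude:
    def test_sine_amplitude_within_two_percent(self):
        w = _sine(amp=0.08, n=5000)
        assert tc.envelope_amplitude(w) == pytest.approx(0.08, rel=0.02)

    def test_gaussian_burst_peak(self):
        t = np.arange(6000) / FS
        env = 0.1 * np.exp(-(((t - 24e-6) / 3e-6) ** 2))
        w = tc.Waveform(env * np.sin(2 * np.pi * 1e6 * t), FS)
        assert tc.envelope_amplitude(w) == pytest.approx(0.1, rel=0.02)

    @given(st.floats(min_value=1e-3, max_value=1e3))
    def test_positive_homogeneity(self, a):
        w = _sine(amp=0.05, n=3000)
        base = tc.envelope_amplitude(w)
        scaled = tc.Waveform(a * w.samples, FS)
        assert tc.envelope_amplitude(scaled) == pytest.approx(a * base, rel=1e-9)

    def test_window_shorter_than_two_samples_rejected(self):
        w = _sine()
        with pytest.raises(ParameterError):
            tc.envelope_amplitude(w, tc.AnalysisConfig(hann_window_span=1e-9))


class TestSpeedOfSound:
    def test_zero_offset_returns_water_speed_exactly(self, water):
        assert tc.speed_of_sound(0.0, 0.006, water) == 1481.0

    @pytest.mark.parametrize("c_true", [1578.3, 1445.3])
    def test_inverts_forward_delay(self, c_true, water):
        dt = forward_delay(c_true, 6e-3)
        assert tc.speed_of_sound(dt, 6e-3, water) == pytest.approx(c_true, rel=1e-12)

    def test_nonphysical_delay_rejected(self, water):
        # offset larger than the entire water transit of the thickness
        with pytest.raises(NonphysicalDelayError):
            tc.speed_of_sound(5e-6, 0.001, water)

    @given(
        c=st.floats(min_value=1400, max_value=1700),
        d=st.floats(min_value=4e-3, max_value=10e-3),
    )
    def test_self_inverse_property(self, c, d):
        assert tc.speed_of_sound(forward_delay(c, d), d) == pytest.approx(
            c, rel=1e-9
        )


class TestAttenuation:
    def test_unity_ratio_gives_zero(self):
        m = tc.AcousticMeasurement(0.0, 0.05, 0.05, 1.0)
        assert tc.attenuation(m, 0.01) == 0.0

    def test_closed_form_one_db(self):
        m = tc.AcousticMeasurement(0.0, 10 ** (1 / 20), 1.0, 1.0)
        assert tc.attenuation(m, 0.01) == pytest.approx(1.0, rel=1e-12)

    def test_muscle_ratio_round_trips(self):
        # ratio constructed as 10^(5.56 * 0.6 / 20) must map back to 5.56
        m = tc.AcousticMeasurement(0.0, 10 ** (5.56 * 0.6 / 20), 1.0, 1.0)
        assert tc.attenuation(m, 6e-3) == pytest.approx(5.56, rel=1e-12)

    def test_negative_attenuation_warns_not_raises(self):
        m = tc.AcousticMeasurement(0.0, 1.0, 1.1, 1.0)
        with pytest.warns(UserWarning, match="negative attenuation"):
            assert tc.attenuation(m, 6e-3) < 0


class TestImpedanceAndReflection:
    @pytest.mark.parametrize(
        "rho, c, z",
        [(1.04, 1578.3, 1.64), (1.03, 1445.3, 1.49), (1.000, 1481.0, 1.481)],
    )
    def test_impedance_values(self, rho, c, z):
        assert round(tc.impedance(rho, c), 2) == pytest.approx(z, abs=5e-3)

    def test_matched_impedance_transmits_fully(self):
        r = tc.reflection_transmission(1.6, 1.6)
        assert r.gamma == 0.0 and r.T_E == 1.0

    def test_muscle_water_transmission(self):
        z_w = tc.impedance(1.000, 1481.0)
        assert round(tc.reflection_transmission(z_w, 1.69).T_E, 4) == 0.9957

    def test_near_matched_transmission(self):
        z_w = tc.impedance(1.000, 1481.0)
        assert tc.reflection_transmission(z_w, 1.50).T_E == pytest.approx(
            0.99996, abs=5e-6
        )

    @given(
        z1=st.floats(min_value=0.5, max_value=3.0),
        z2=st.floats(min_value=0.5, max_value=3.0),
    )
    def test_gamma_antisymmetric_and_energy_conserving(self, z1, z2):
        a = tc.reflection_transmission(z1, z2)
        b = tc.reflection_transmission(z2, z1)
        assert a.gamma == -b.gamma
        assert abs(a.R_E + a.T_E - 1.0) <= 4 * np.finfo(float).eps

    def test_reflection_grows_with_mismatch_at_fixed_sum(self):
        s = 3.0
        gammas = [
            abs(tc.reflection_transmission((s - d) / 2, (s + d) / 2).gamma)
            for d in np.linspace(0.0, 1.0, 20)
        ]
        assert np.all(np.diff(gammas) > 0)


class TestDensityFromMass:
    def test_unity(self):
        assert tc.density_from_mass(0.050, 50e-6)[0] == pytest.approx(1.00)

    def test_soft_tissue_inverse(self):
        assert tc.density_from_mass(0.0535, 50e-6)[0] == pytest.approx(1.07)

    def test_replicates_mean_and_sd(self):
        mean, sd = tc.density_from_mass(0.05, 50e-6, replicates=[1.06, 1.07, 1.08])
        assert mean == pytest.approx(1.07)
        assert sd == pytest.approx(0.01)

    def test_nonpositive_rejected(self):
        with pytest.raises(ParameterError):
            tc.density_from_mass(0.0, 50e-6)


class TestCharacterizeSpecimen:
    def test_liquid_mode_uses_full_path(self, water):
        med = tc.MediumProperties(1533.4, 1.07, 0.59)
        geom = tc.SpecimenGeometry("liquid_acoustic", thickness_d=0.05)
        cfg = tc.SimulationConfig(path_delay=36e-6)
        pair = tc.simulate_pair(med, geom, water, cfg)
        props, _ = tc.characterize_specimen(pair)
        assert props.speed_of_sound_c == pytest.approx(1533.4, abs=2.0)
        assert props.attenuation_alpha == pytest.approx(0.59, abs=0.05)

    def test_wrong_mode_rejected(self, water):
        med = tc.MediumProperties(1500.0)
        geom = tc.SpecimenGeometry("solid_acoustic", thickness_d=6e-3)
        pair = tc.simulate_pair(med, geom)
        pair.geometry = tc.SpecimenGeometry("compression", thickness_d=6e-3)
        with pytest.raises(ParameterError, match="mode"):
            tc.characterize_specimen(pair)

    def test_stage_name_attached_to_errors(self):
        geom = tc.SpecimenGeometry("solid_acoustic", thickness_d=6e-3)
        flat_cal = tc.Waveform(np.zeros(1000), FS)
        flat_spec = tc.Waveform(np.zeros(1000), FS)
        pair = tc.WaveformPair(flat_cal, flat_spec, geom)
        with pytest.raises(DegenerateSignalError, match="estimate_delay"):
            tc.characterize_specimen(pair)

    def test_density_attaches_impedance(self):
        med = tc.MediumProperties(1507.1, 1.00, 0.48)
        geom = tc.SpecimenGeometry("solid_acoustic", thickness_d=6e-3)
        pair = tc.simulate_pair(med, geom)
        props, _ = tc.characterize_specimen(pair, density=1.00)
        assert props.impedance_Z == pytest.approx(1.507, abs=0.005)
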