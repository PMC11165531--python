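"""Forward simulator of the substitution measurement and mechanical tests.

The acoustic generative model inverts the analysis relations: a
single-cycle sine burst at the excitation frequency travels the water
path with a fixed propagation delay; inserting a specimen of thickness d
advances the arrival by d*(1/c_water - 1/c_medium) and scales the
amplitude by 10^(-alpha * 100 d * f_c / 20).  Interface reflection losses
(the two-boundary energy factor) are negligible for water-matched media
and are off by default; a flag enables them for sensitivity studies.
White Gaussian noise and a residual DC offset emulate the hydrophone
chain; progressive on-scope averaging of ``n_averages`` sweeps reduces
the noise standard deviation by sqrt(n_averages) by construction.

The mechanical generator produces a near-linear engineering stress-strain
curve with an optional compliant toe region below a configurable strain,
sampled at the 40 Hz machine rate, with multiplicative amplitude noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .acoustic import reflection_transmission
from .domain import (
    MechanicalCurve,
    MediumProperties,
    SpecimenGeometry,
    Waveform,
    WaterReference,
    impedance_mrayls,
)
from .errors import ConfigurationError, ParameterError
from .io import WaveformPair
from .mechanical import TestProtocol

__all__ = [
    "SimulationConfig",
    "make_burst",
    "simulate_pair",
    "simulate_stress_strain",
]


@dataclass
class SimulationConfig:
    """Parameters of the simulated acquisition.

    fc : float
        Transmit center frequency, MHz (1 MHz piezo disc).
    n_cycles : int
        Cycles per burst (single-cycle excitation by default).
    sampling_rate : float
        Scope rate in Hz; 125 MSPS native.
    path_delay : float
        Water-path propagation delay in seconds.  35 us sits inside the
        30-40 us observed for a ~5 cm tank path.
    record_duration : float
        Length of each record in seconds.
    noise_sd : float
        Per-sweep additive white-noise SD in volts (before averaging).
    dc_offset : float
        Residual DC offset in volts despite AC coupling.
    n_averages : int
        Number of progressively averaged sweeps.
    seed : int, optional
        Mandatory whenever noise_sd > 0; identical configs (including
        seed) produce bit-identical waveforms.
    """

    fc: float = 1.0
    n_cycles: int = 1
    sampling_rate: float = 1.25e8
    path_delay: float = 35e-6
    record_duration: float = 60e-6
    noise_sd: float = 0.0
    dc_offset: float = 0.0
    n_averages: int = 1
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not (self.fc > 0 and self.sampling_rate > 0):
            raise ParameterError("fc and sampling_rate must be positive")
        if self.n_cycles < 1:
            raise ParameterError("n_cycles must be >= 1")
        if self.n_averages < 1:
            raise ParameterError("n_averages must be >= 1")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        if self.noise_sd > 0 and self.seed is None:
            raise ConfigurationError("seed is mandatory when noise_sd > 0")

    @property
    def n_samples(self) -> int:
        return int(round(self.record_duration * self.sampling_rate))


def _burst_at(cfg: SimulationConfig, amplitude: float, delay: float) -> np.ndarray:
    """Analytically sampled sine burst starting at ``delay`` seconds."""
    t = np.arange(cfg.n_samples) / cfg.sampling_rate
    tau = t - delay
    span = cfg.n_cycles / (cfg.fc * 1e6)
    v = amplitude * np.sin(2 * np.pi * cfg.fc * 1e6 * tau)
    v[(tau < 0) | (tau >= span)] = 0.0
    return v


def make_burst(cfg: SimulationConfig, amplitude: float = 1.0) -> Waveform:
    """Noise-free single(-or-multi)-cycle sine burst starting at t = 0.

    The nonzero support is exactly ``n_cycles / fc`` (1 us for one cycle
    at 1 MHz); samples outside it are zero.
    """
    if not amplitude > 0:
        raise ParameterError("amplitude must be positive")
    return Waveform(
        samples=_burst_at(cfg, amplitude, 0.0),
        sampling_rate=cfg.sampling_rate,
        label="burst",
    )


def _noisy(
    clean: np.ndarray, cfg: SimulationConfig, rng: Optional[np.random.Generator]
) -> np.ndarray:
    out = clean + cfg.dc_offset
    if cfg.noise_sd > 0:
        assert rng is not None
        noise = rng.normal(0.0, cfg.noise_sd, size=(cfg.n_averages, clean.size))
        out = out + noise.mean(axis=0)
    return out


def simulate_pair(
    medium: MediumProperties,
    geom: SpecimenGeometry,
    water: Optional[WaterReference] = None,
    cfg: Optional[SimulationConfig] = None,
    amplitude: float = 0.05,
    interface_losses: bool = False,
) -> WaveformPair:
    """Simulate a calibration/specimen waveform pair for one medium.

    The calibration burst arrives after ``cfg.path_delay``; the specimen
    burst is advanced by d*(1/c_water - 1/c_medium) (earlier for
    faster-than-water media) and scaled by the attenuation factor
    10^(-alpha * 100 d * fc / 20).  With ``interface_losses`` the
    amplitude is additionally multiplied by the water<->medium two-boundary
    energy transmission factor T_E = 1 - Gamma^2 (which for normal
    incidence equals the product of the two pressure transmission
    coefficients).  Noise draws for the two records are independent.
    """
    water = water or WaterReference()
    cfg = cfg or SimulationConfig()
    if geom.mode not in ("solid_acoustic", "liquid_acoustic"):
        raise ParameterError("geometry mode must be solid_acoustic or liquid_acoustic")
    if geom.thickness_d is None or not geom.thickness_d > 0:
        raise ParameterError("geometry thickness_d must be positive")
    d = geom.thickness_d

    delta_t = d * (1.0 / water.speed_of_sound - 1.0 / medium.speed_of_sound_c)
    spec_delay = cfg.path_delay - delta_t
    if spec_delay < 0:
        raise ConfigurationError(
            f"specimen arrival {spec_delay:.3e} s precedes record start; "
            "increase path_delay"
        )
    scale = 10.0 ** (-medium.attenuation_alpha * 100.0 * d * cfg.fc / 20.0)
    if interface_losses:
        if medium.density_rho is None:
            raise ParameterError("interface_losses requires medium.density_rho")
        z_med = impedance_mrayls(medium.density_rho, medium.speed_of_sound_c)
        scale *= reflection_transmission(water.impedance, z_med).T_E

    rng = np.random.default_rng(cfg.seed) if cfg.noise_sd > 0 else None
    cal = _noisy(_burst_at(cfg, amplitude, cfg.path_delay), cfg, rng)
    spec = _noisy(_burst_at(cfg, amplitude * scale, spec_delay), cfg, rng)
    fs = cfg.sampling_rate
    return WaveformPair(
        calibration=Waveform(samples=cal, sampling_rate=fs, label="calibration"),
        specimen=Waveform(samples=spec, sampling_rate=fs, label="specimen"),
        geometry=geom,
    )


def simulate_stress_strain(
    E: float,
    protocol: TestProtocol,
    toe_strain: float = 0.0,
    noise_rel: float = 0.0,
    seed: Optional[int] = None,
) -> MechanicalCurve:
    """Near-linear engineering stress-strain curve with an optional toe.

    Stress is zero up to ``toe_strain`` and rises linearly with slope
    ``E`` (Pa) beyond it; strain is sampled at the machine's 40 Hz
    acquisition rate given the protocol's displacement rate.
    Multiplicative zero-mean Gaussian noise of relative SD ``noise_rel``
    emulates load-cell noise; output is deterministic for a fixed seed.

    ``toe_strain`` must stay below 0.10 so the toe cannot contaminate the
    standard 10-20% fit window.
    """
    if not E > 0:
        raise ParameterError("E must be positive")
    if not 0.0 <= toe_strain < 0.10:
        raise ParameterError("toe_strain must be in [0, 0.10)")
    if noise_rel < 0:
        raise ParameterError("noise_rel must be >= 0")
    disp_step = protocol.rate / 40.0  # displacement per 40 Hz sample
    n = max(int(round(protocol.max_displacement / disp_step)) + 1, 2)
    strain = np.arange(n) * disp_step / protocol.reference_length
    stress = np.where(strain > toe_strain, E * (strain - toe_strain), 0.0)
    if noise_rel > 0:
        rng = np.random.default_rng(seed)
        stress = stress * (1.0 + rng.normal(0.0, noise_rel, size=n))
    return MechanicalCurve(strain=strain, stress=stress, test_mode=protocol.mode)
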