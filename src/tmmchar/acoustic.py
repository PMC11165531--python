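"""Substitution-method acoustic analysis.

The through-transmission substitution method compares a pulse transmitted
through a pure water path (calibration) with the same pulse transmitted
after inserting a specimen of thickness ``d``.  The arrival-time offset
gives the specimen speed of sound,

    c_spec = 1 / (1/c_water - delta_t / d),

with delta_t > 0 when the specimen waveform arrives earlier (specimen
faster than water), and the envelope-peak amplitude ratio gives the
attenuation coefficient

    alpha = 20/(100 d f_c) * log10(P_cal / P_spec)   [dB cm^-1 MHz^-1]

with d in meters (100 d = path in cm) and f_c the excitation frequency in
MHz.  The DSP chain mirrors standard practice for narrowband hydrophone
records: mean subtraction, x8 polyphase upsampling (125 MSPS -> 1 ns
resolution), integer-lag cross-correlation for the delay, and a Hann
window centered on the pulse followed by a Hilbert-transform envelope for
the amplitude.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np
from scipy import signal

from .domain import (
    AcousticMeasurement,
    MediumProperties,
    Waveform,
    WaterReference,
    impedance_mrayls,
)
from .errors import (
    DegenerateSignalError,
    NonphysicalDelayError,
    ParameterError,
    TmmError,
)

__all__ = [
    "AnalysisConfig",
    "remove_dc",
    "upsample",
    "estimate_delay",
    "envelope_amplitude",
    "speed_of_sound",
    "attenuation",
    "impedance",
    "reflection_transmission",
    "ReflectionTransmission",
    "characterize_specimen",
    "density_from_mass",
]

log = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    """Tunable parameters of the acoustic analysis.

    upsample_factor : int
        Polyphase interpolation factor; 8 turns the 8 ns native resolution
        into 1 ns.
    hann_window_span : float
        Span of the Hann window around the pulse peak, seconds.  The
        default 4 us covers four carrier periods at 1 MHz.
    water : WaterReference
        Properties of the calibration water path.
    excitation_fc : float
        Transmit center frequency in MHz.
    """

    upsample_factor: int = 8
    hann_window_span: float = 4e-6
    water: WaterReference = field(default_factory=WaterReference)
    excitation_fc: float = 1.0

    def __post_init__(self) -> None:
        if self.upsample_factor < 1:
            raise ParameterError("upsample_factor must be >= 1")
        if not self.hann_window_span > 0:
            raise ParameterError("hann_window_span must be positive")
        if not self.excitation_fc > 0:
            raise ParameterError("excitation_fc must be positive")


def remove_dc(w: Waveform) -> Waveform:
    """Subtract the record mean (residual DC offset of AC-coupled scopes)."""
    return Waveform(
        samples=w.samples - np.mean(w.samples),
        sampling_rate=w.sampling_rate,
        t0=w.t0,
        label=w.label,
    )


def upsample(w: Waveform, factor: int) -> Waveform:
    """Band-limited polyphase upsampling by an integer factor.

    Uses polyphase FIR interpolation (not FFT resampling) to avoid
    wrap-around artifacts at the record edges.  ``factor == 1`` returns the
    waveform unchanged.
    """
    if factor < 1:
        raise ParameterError("upsample factor must be >= 1")
    if factor == 1:
        return w
    up = signal.resample_poly(w.samples, factor, 1)
    return Waveform(
        samples=up,
        sampling_rate=w.sampling_rate * factor,
        t0=w.t0,
        label=w.label,
    )


def estimate_delay(cal: Waveform, spec: Waveform, cfg: Optional[AnalysisConfig] = None) -> float:
    """Arrival-time offset of the specimen pulse relative to calibration.

    Both records are mean-subtracted and upsampled by
    ``cfg.upsample_factor``, then the full cross-correlation of specimen
    against calibration is maximized over integer lags.  The result is
    positive when the specimen pulse occurs earlier than the calibration
    pulse; resolution is exactly one upsampled sample period (no
    sub-sample interpolation).  Ties in the correlation maximum are broken
    toward the smallest-magnitude lag.

    Raises
    ------
    DegenerateSignalError
        If either record is all-zero after DC removal.
    ParameterError
        If the sampling rates differ.
    """
    cfg = cfg or AnalysisConfig()
    if cal.sampling_rate != spec.sampling_rate:
        raise ParameterError("calibration and specimen sampling rates differ")
    cal_u = upsample(remove_dc(cal), cfg.upsample_factor)
    spec_u = upsample(remove_dc(spec), cfg.upsample_factor)
    if not np.any(cal_u.samples) or not np.any(spec_u.samples):
        raise DegenerateSignalError(
            "all-zero waveform: cross-correlation maximum undefined"
        )
    xc = signal.correlate(spec_u.samples, cal_u.samples, mode="full")
    lags = signal.correlation_lags(spec_u.n, cal_u.n, mode="full")
    peak = xc.max()
    candidates = lags[np.flatnonzero(xc == peak)]
    lag = int(candidates[np.argmin(np.abs(candidates))])
    fs_up = cal.sampling_rate * cfg.upsample_factor
    # positive lag means the specimen pulse sits LATER in its record;
    # arrival-offset sign flips, plus any difference in record start times
    return (cal.t0 - spec.t0) - lag / fs_up


def envelope_amplitude(w: Waveform, cfg: Optional[AnalysisConfig] = None) -> float:
    """Peak of the analytic-signal envelope of the Hann-windowed pulse.

    The Hann window (span ``cfg.hann_window_span``) is centered at the
    sample of maximum absolute voltage; its nearly flat center preserves
    the peak amplitude while the cosine taper suppresses the spectral edge
    effects of the subsequent Hilbert transform.  Portions of the window
    falling outside the record are treated as zero-padding.
    """
    cfg = cfg or AnalysisConfig()
    n_win = int(round(cfg.hann_window_span * w.sampling_rate))
    if n_win < 2:
        raise ParameterError(
            f"hann_window_span {cfg.hann_window_span} s spans <2 samples at "
            f"{w.sampling_rate} Hz"
        )
    center = int(np.argmax(np.abs(w.samples)))
    win = signal.windows.hann(n_win, sym=True)
    start = center - n_win // 2
    # overlap of [start, start+n_win) with [0, n)
    lo = max(start, 0)
    hi = min(start + n_win, w.n)
    gated = np.zeros(w.n)
    gated[lo:hi] = w.samples[lo:hi] * win[lo - start : hi - start]
    envelope = np.abs(signal.hilbert(gated))
    return float(envelope.max())


def speed_of_sound(delta_t: float, d: float, water: Optional[WaterReference] = None) -> float:
    """Specimen speed of sound from the substitution-method time offset.

    ``delta_t > 0`` means the specimen waveform arrived earlier than the
    calibration waveform, hence a faster-than-water specimen.

    Raises
    ------
    NonphysicalDelayError
        If ``1/c_water - delta_t/d <= 0`` (the offset is too large for the
        thickness to admit a positive speed).
    """
    water = water or WaterReference()
    if not d > 0:
        raise ParameterError("thickness d must be positive")
    if delta_t == 0.0:
        # exact identity: the relation reduces to c_spec = c_water
        return water.speed_of_sound
    denom = 1.0 / water.speed_of_sound - delta_t / d
    if denom <= 0:
        raise NonphysicalDelayError(
            f"delta_t={delta_t:.3e} s too large for thickness d={d:.3e} m "
            f"(denominator {denom:.3e} <= 0)"
        )
    return 1.0 / denom


def attenuation(meas: AcousticMeasurement, d: float) -> float:
    """Attenuation coefficient in dB cm^-1 MHz^-1 from the amplitude ratio.

    alpha = 20 log10(P_cal/P_spec) / (100 d f_c), with d in meters and the
    excitation frequency in MHz.  A negative result (specimen apparently
    amplifying) is physically suspect but can arise from noise on thin,
    low-loss specimens; it is returned with a warning rather than raised.
    """
    if not d > 0:
        raise ParameterError("thickness d must be positive")
    alpha = (
        20.0
        * np.log10(meas.pressure_cal / meas.pressure_spec)
        / (100.0 * d * meas.excitation_fc)
    )
    if alpha < 0:
        warnings.warn(
            f"negative attenuation {alpha:.3f} dB/cm/MHz: specimen amplitude "
            "exceeds calibration (noise on a thin, low-loss specimen?)",
            stacklevel=2,
        )
    return float(alpha)


def impedance(rho: float, c: float) -> float:
    """Acoustic impedance Z = rho*c in MRayls from (g/cm^3, m/s)."""
    if not (rho > 0 and c > 0):
        raise ParameterError("density and speed of sound must be positive")
    return impedance_mrayls(rho, c)


class ReflectionTransmission(NamedTuple):
    gamma: float  # pressure reflection coefficient
    R_E: float  # energy reflection coefficient, gamma^2
    T_E: float  # energy transmission coefficient, 1 - gamma^2


def reflection_transmission(Z1: float, Z2: float) -> ReflectionTransmission:
    """Pressure reflection and energy reflection/transmission at an interface.

    Gamma = (Z2 - Z1)/(Z2 + Z1); the energy reflection coefficient is
    Gamma^2 and energy transmission is its complement (energy, not
    pressure, coefficients sum to one).
    """
    if not (Z1 > 0 and Z2 > 0):
        raise ParameterError("impedances must be positive")
    gamma = (Z2 - Z1) / (Z2 + Z1)
    r = gamma * gamma
    return ReflectionTransmission(gamma=gamma, R_E=r, T_E=1.0 - r)


def characterize_specimen(
    pair,
    cfg: Optional[AnalysisConfig] = None,
    density: Optional[float] = None,
) -> tuple[MediumProperties, AcousticMeasurement]:
    """Run the full substitution-method analysis on one waveform pair.

    Pipeline: DC removal -> x8 upsampling -> cross-correlation delay ->
    Hann-windowed Hilbert-envelope amplitudes -> speed of sound and
    attenuation.  In ``liquid_acoustic`` mode ``thickness_d`` is the full
    transmitter-to-hydrophone path (the liquid replaces the entire water
    column).  When ``density`` (g/cm^3) is supplied the impedance is
    attached in MRayls.

    Returns the derived :class:`MediumProperties` and the raw
    :class:`AcousticMeasurement`; stage failures are re-raised with the
    stage name attached.
    """
    cfg = cfg or AnalysisConfig()
    geom = pair.geometry
    if geom.mode not in ("solid_acoustic", "liquid_acoustic"):
        raise ParameterError(
            f"geometry mode must be solid_acoustic or liquid_acoustic, got {geom.mode!r}"
        )
    if geom.thickness_d is None or not geom.thickness_d > 0:
        raise ParameterError("geometry thickness_d must be positive")
    d = geom.thickness_d

    def _stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except TmmError as e:
            raise type(e)(f"[{name}] {e}") from e

    delta_t = _stage("estimate_delay", estimate_delay, pair.calibration, pair.specimen, cfg)
    log.info("delay: delta_t = %.3f ns", delta_t * 1e9)

    fs_up_cfg = AnalysisConfig(
        upsample_factor=1,
        hann_window_span=cfg.hann_window_span,
        water=cfg.water,
        excitation_fc=cfg.excitation_fc,
    )
    cal_u = upsample(remove_dc(pair.calibration), cfg.upsample_factor)
    spec_u = upsample(remove_dc(pair.specimen), cfg.upsample_factor)
    p_cal = _stage("envelope_amplitude", envelope_amplitude, cal_u, fs_up_cfg)
    p_spec = _stage("envelope_amplitude", envelope_amplitude, spec_u, fs_up_cfg)
    log.info("envelope peaks: cal = %.4g V, spec = %.4g V", p_cal, p_spec)

    meas = AcousticMeasurement(
        delta_t=delta_t,
        pressure_cal=p_cal,
        pressure_spec=p_spec,
        excitation_fc=cfg.excitation_fc,
    )
    c = _stage("speed_of_sound", speed_of_sound, delta_t, d, cfg.water)
    alpha = _stage("attenuation", attenuation, meas, d)
    props = MediumProperties(
        speed_of_sound_c=c,
        density_rho=density,
        attenuation_alpha=max(alpha, 0.0),
        impedance_Z=impedance(density, c) if density is not None else None,
    )
    if alpha < 0:
        log.warning("negative attenuation %.3f clipped to 0 in reported properties", alpha)
    log.info("result: c = %.1f m/s, alpha = %.3f dB/cm/MHz", c, props.attenuation_alpha)
    return props, meas


def density_from_mass(
    mass: float,
    volume: float,
    replicates: Optional[Sequence[float]] = None,
) -> tuple[float, Optional[float]]:
    """Density in g/cm^3 from a mass (kg) and volume (m^3) measurement.

    With ``replicates`` (a list of replicate densities in g/cm^3, e.g.
    repeated 50 mL weighings) the mean and sample standard deviation
    (n-1 denominator) are returned; SD is None for a single measurement.
    """
    if not (mass > 0 and volume > 0):
        raise ParameterError("mass and volume must be positive")
    if replicates is not None:
        reps = np.asarray(replicates, dtype=float)
        if reps.size == 0:
            raise ParameterError("replicates must be non-empty when given")
        sd = float(np.std(reps, ddof=1)) if reps.size > 1 else None
        return float(np.mean(reps)), sd
    # kg/m^3 -> g/cm^3
    return mass / volume * 1e-3, None
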