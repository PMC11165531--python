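"""Shared domain types and unit conventions.

All internal computation is in SI (seconds, meters, pascals).  Reported
quantities follow the conventions of the ultrasound-phantom literature:
speed of sound in m/s, attenuation in dB cm^-1 MHz^-1, density in g/cm^3,
acoustic impedance in MRayls and Young's modulus in kPa.  The MRayl
convention used throughout is

    Z [MRayls] = rho [g/cm^3] * c [m/s] * 1e-3

which equals the SI product rho*c (kg m^-2 s^-1) divided by 1e6.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Any, Optional, Sequence

import numpy as np

from .errors import GeometryError, ParameterError

__all__ = [
    "Waveform",
    "SpecimenGeometry",
    "MediumProperties",
    "WaterReference",
    "AcousticMeasurement",
    "MechanicalCurve",
    "LiteratureRange",
    "MaterialRecord",
    "validate_geometry",
    "impedance_mrayls",
    "INDENTATION_DEPTH_M",
    "COMPRESSION_ASPECT_LIMIT",
]

#: Indentation depth of the compression protocol (2 mm plunge).
INDENTATION_DEPTH_M = 2e-3

#: Maximum allowed specimen height : planar-dimension ratio (inclusive) for
#: compression specimens; prevents buckling at large strains.
COMPRESSION_ASPECT_LIMIT = 0.25

GEOMETRY_MODES = ("solid_acoustic", "liquid_acoustic", "compression", "tension")


def impedance_mrayls(density_g_cm3: float, speed_m_s: float) -> float:
    """Acoustic impedance Z = rho*c in MRayls from (g/cm^3, m/s) inputs."""
    return density_g_cm3 * speed_m_s * 1e-3


class _Serializable:
    """JSON-dict round-trip mixin for the report format."""

    def to_dict(self) -> dict[str, Any]:
        out: dict[str, Any] = {"type": type(self).__name__}
        for f in fields(self):  # type: ignore[arg-type]
            v = getattr(self, f.name)
            if isinstance(v, np.ndarray):
                v = v.tolist()
            elif isinstance(v, _Serializable):
                v = v.to_dict()
            out[f.name] = v
        return out

    @classmethod
    def from_dict(cls, d: dict[str, Any]):
        d = {k: v for k, v in d.items() if k != "type"}
        for f in fields(cls):  # type: ignore[arg-type]
            if f.name in d and isinstance(d[f.name], dict) and "type" in d[f.name]:
                sub = _REGISTRY[d[f.name]["type"]]
                d[f.name] = sub.from_dict(d[f.name])
        return cls(**d)


@dataclass
class Waveform(_Serializable):
    """A uniformly sampled voltage record.

    Parameters
    ----------
    samples : array-like of float
        Voltage samples in volts; length >= 2.
    sampling_rate : float
        Samples per second (Hz); the native oscilloscope rate is 125 MSPS.
    t0 : float
        Time of the first sample in seconds (trigger-relative).
    label : str
        Free-text tag such as ``"calibration"`` or ``"specimen:skin"``.
    """

    samples: np.ndarray
    sampling_rate: float
    t0: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise ParameterError("Waveform requires a 1-D sample array of length >= 2")
        if not (self.sampling_rate > 0 and np.isfinite(self.sampling_rate)):
            raise ParameterError("sampling_rate must be positive and finite")
        if not np.all(np.isfinite(self.samples)):
            raise ParameterError("Waveform samples must be finite")

    @property
    def n(self) -> int:
        return int(self.samples.size)

    @property
    def duration(self) -> float:
        """Record span (n-1)/fs in seconds."""
        return (self.n - 1) / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        """Sample times t0 + k/fs in seconds."""
        return self.t0 + np.arange(self.n) / self.sampling_rate

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Waveform):
            return NotImplemented
        return (
            np.array_equal(self.samples, other.samples)
            and self.sampling_rate == other.sampling_rate
            and self.t0 == other.t0
            and self.label == other.label
        )


@dataclass(eq=True)
class SpecimenGeometry(_Serializable):
    """Physical dimensions, mass and test mode of one specimen.

    ``thickness_d`` is the acoustic path through the specimen; in
    ``liquid_acoustic`` mode it is the full transmitter-to-hydrophone
    distance (the liquid fills the whole path).
    """

    mode: str
    thickness_d: Optional[float] = None  # m
    diameter: Optional[float] = None  # m, cylindrical specimens
    gauge_length: Optional[float] = None  # m, dogbone elongated region
    cross_section_width: Optional[float] = None  # m
    cross_section_thickness: Optional[float] = None  # m
    mass: Optional[float] = None  # kg
    volume: Optional[float] = None  # m^3

    def __post_init__(self) -> None:
        if self.mode not in GEOMETRY_MODES:
            raise ParameterError(
                f"mode must be one of {GEOMETRY_MODES}, got {self.mode!r}"
            )


@dataclass(eq=True)
class MediumProperties(_Serializable):
    """Derived acoustic properties of a medium.

    speed_of_sound_c in m/s, density_rho in g/cm^3, attenuation_alpha in
    dB cm^-1 MHz^-1, impedance_Z in MRayls (optional, derived).
    """

    speed_of_sound_c: float
    density_rho: Optional[float] = None
    attenuation_alpha: float = 0.0
    impedance_Z: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.speed_of_sound_c > 0:
            raise ParameterError("speed_of_sound_c must be positive")
        if self.density_rho is not None and not self.density_rho > 0:
            raise ParameterError("density_rho must be positive")
        if self.attenuation_alpha < 0:
            raise ParameterError("attenuation_alpha must be >= 0")
        if self.impedance_Z is not None and self.density_rho is not None:
            expected = impedance_mrayls(self.density_rho, self.speed_of_sound_c)
            if abs(self.impedance_Z - expected) > 0.005 * expected:
                raise ParameterError(
                    f"impedance_Z={self.impedance_Z} inconsistent with "
                    f"rho*c={expected:.4f} MRayls (>0.5%)"
                )


@dataclass(eq=True)
class WaterReference(_Serializable):
    """Reference properties of the water path used in the substitution method.

    Defaults: 1481 m/s, 1.000 g/cm^3, 0 dB cm^-1 MHz^-1.  No temperature
    model is applied; the reference speed is a constant.
    """

    speed_of_sound: float = 1481.0
    density: float = 1.000
    attenuation: float = 0.0

    def __post_init__(self) -> None:
        if not (self.speed_of_sound > 0 and self.density > 0):
            raise ParameterError("water speed_of_sound and density must be positive")
        if self.attenuation < 0:
            raise ParameterError("water attenuation must be >= 0")

    @property
    def impedance(self) -> float:
        """Water impedance in MRayls."""
        return impedance_mrayls(self.density, self.speed_of_sound)


@dataclass(eq=True)
class AcousticMeasurement(_Serializable):
    """Raw observables extracted from one calibration/specimen pair.

    ``delta_t`` is positive when the specimen waveform arrives EARLIER than
    the calibration waveform (specimen faster than water).
    """

    delta_t: float  # s
    pressure_cal: float  # V, envelope maximum of calibration waveform
    pressure_spec: float  # V, envelope maximum of specimen waveform
    excitation_fc: float  # MHz

    def __post_init__(self) -> None:
        if not self.pressure_cal > 0:
            raise ParameterError("pressure_cal must be positive")
        if not self.pressure_spec > 0:
            raise ParameterError("pressure_spec must be positive")
        if not self.excitation_fc > 0:
            raise ParameterError("excitation_fc must be positive")


@dataclass
class MechanicalCurve(_Serializable):
    """Engineering stress-strain series for one mechanical test."""

    strain: np.ndarray  # dimensionless, non-decreasing
    stress: np.ndarray  # Pa
    test_mode: str = "compression"

    def __post_init__(self) -> None:
        self.strain = np.asarray(self.strain, dtype=float)
        self.stress = np.asarray(self.stress, dtype=float)
        if self.strain.shape != self.stress.shape or self.strain.size < 2:
            raise ParameterError("strain and stress must share a length >= 2")
        if np.any(np.diff(self.strain) < 0):
            raise ParameterError("strain must be non-decreasing")
        if self.test_mode not in ("compression", "tension"):
            raise ParameterError("test_mode must be 'compression' or 'tension'")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MechanicalCurve):
            return NotImplemented
        return (
            np.array_equal(self.strain, other.strain)
            and np.array_equal(self.stress, other.stress)
            and self.test_mode == other.test_mode
        )


TISSUES = ("muscle", "soft_tissue", "adipose", "skin")
PROPERTIES = (
    "youngs_modulus_kPa",
    "speed_m_s",
    "attenuation_dB_cm_MHz",
    "density_g_cm3",
    "impedance_MRayls",
)


@dataclass(eq=True)
class LiteratureRange(_Serializable):
    """A literature min-max target range for one (tissue, property) pair.

    ``low``/``high`` are None when the literature reports no range (the
    soft-tissue Young's modulus).
    """

    tissue: str
    property: str
    low: Optional[float] = None
    high: Optional[float] = None

    def __post_init__(self) -> None:
        if self.tissue not in TISSUES:
            raise ParameterError(f"unknown tissue {self.tissue!r}; valid: {TISSUES}")
        if self.property not in PROPERTIES:
            raise ParameterError(
                f"unknown property {self.property!r}; valid: {PROPERTIES}"
            )
        if self.low is not None and self.high is not None and self.low > self.high:
            raise ParameterError("range low must be <= high")

    @property
    def has_range(self) -> bool:
        return self.low is not None and self.high is not None

    def contains(self, value: float) -> bool:
        """Inclusive-bounds membership test."""
        if not self.has_range:
            raise ParameterError("no range defined for this property")
        return self.low <= value <= self.high  # type: ignore[operator]


@dataclass(eq=True)
class MaterialRecord(_Serializable):
    """One measured tissue-mimicking material: name, acoustic properties,
    optional Young's modulus and per-property standard deviations."""

    name: str
    acoustic: MediumProperties
    youngs_modulus_kPa: Optional[float] = None
    std_devs: Optional[dict] = None
    tissue: Optional[str] = None
    notes: Optional[str] = None


_REGISTRY = {
    c.__name__: c
    for c in (
        Waveform,
        SpecimenGeometry,
        MediumProperties,
        WaterReference,
        AcousticMeasurement,
        MechanicalCurve,
        LiteratureRange,
        MaterialRecord,
    )
}


def from_dict(d: dict[str, Any]):
    """Rehydrate any domain type from its ``to_dict`` form."""
    return _REGISTRY[d["type"]].from_dict(d)


def validate_geometry(geom: SpecimenGeometry) -> list[dict[str, Any]]:
    """Check a specimen geometry against the test-protocol rules.

    Returns a list of violation records (empty when all rules hold); each
    record names the rule and the offending values.  Rules:

    * compression: height : planar-dimension ratio <= 1:4 (inclusive), so the
      specimen cannot buckle under deep indentation;
    * compression: the 2 mm indentation depth must be smaller than the
      specimen thickness;
    * acoustic modes: thickness_d must be strictly positive.

    Raises
    ------
    GeometryError
        If a field required by the declared mode is missing.
    """
    violations: list[dict[str, Any]] = []

    def _require(name: str) -> float:
        v = getattr(geom, name)
        if v is None:
            raise GeometryError(f"geometry field {name!r} required for mode {geom.mode!r}")
        return v

    if geom.mode in ("solid_acoustic", "liquid_acoustic"):
        d = _require("thickness_d")
        if not d > 0:
            violations.append(
                {"rule": "acoustic_thickness_positive", "thickness_d": d}
            )
    elif geom.mode == "compression":
        h = _require("thickness_d")
        dia = _require("diameter")
        ratio = h / dia
        if ratio > COMPRESSION_ASPECT_LIMIT:
            violations.append(
                {
                    "rule": "compression_aspect_ratio",
                    "height": h,
                    "planar_dimension": dia,
                    "ratio": ratio,
                    "limit": COMPRESSION_ASPECT_LIMIT,
                }
            )
        if not INDENTATION_DEPTH_M < h:
            violations.append(
                {
                    "rule": "indentation_depth_below_thickness",
                    "indentation_depth": INDENTATION_DEPTH_M,
                    "thickness": h,
                }
            )
    elif geom.mode == "tension":
        _require("gauge_length")
        _require("cross_section_width")
        _require("cross_section_thickness")
    return violations
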