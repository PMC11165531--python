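"""Engineering stress-strain conversion and Young's-modulus extraction.

Load-displacement records from a universal testing machine are converted
to engineering stress (load / initial contact area) and engineering strain
(displacement / initial reference length), and the Young's modulus is the
ordinary-least-squares slope of stress on strain restricted to the
10-20% strain window — a region past the initial toe/settling effects but
still within the near-linear regime of soft hydrogels.

For compression the contact area defaults to the indenter cross-section
(the load path), not the larger specimen face; for tension it is the
dogbone cross-section and the reference length is the gauge (elongated
region) length.  Both are configurable on :class:`TestProtocol`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .domain import MechanicalCurve
from .errors import InsufficientDataError, ParameterError

__all__ = [
    "TestProtocol",
    "ModulusFit",
    "DEFAULT_STRAIN_WINDOW",
    "to_stress_strain",
    "fit_modulus",
    "summarize_replicates",
    "compression_protocol",
    "tension_protocol",
]

#: strain window for the modulus fit, inclusive bounds
DEFAULT_STRAIN_WINDOW = (0.10, 0.20)


@dataclass
class TestProtocol:
    """Geometry and kinematics of one mechanical test.

    contact_area : m^2 (compression: indenter cross-section; tension:
    dogbone cross-section).  reference_length : m (compression: specimen
    thickness; tension: gauge length).  ``rate`` and ``max_displacement``
    are metadata used by the simulator's 40 Hz sampling.
    """

    mode: str
    contact_area: float
    reference_length: float
    max_displacement: float = 2e-3
    rate: float = 0.5e-3 / 60.0  # m/s

    def __post_init__(self) -> None:
        if self.mode not in ("compression", "tension"):
            raise ParameterError("mode must be 'compression' or 'tension'")
        if not self.contact_area > 0:
            raise ParameterError("contact_area must be positive")
        if not self.reference_length > 0:
            raise ParameterError("reference_length must be positive")


def compression_protocol(
    indenter_diameter: float = 10e-3,
    thickness: float = 6e-3,
    max_displacement: float = 2e-3,
    rate: float = 0.5e-3 / 60.0,
) -> TestProtocol:
    """Protocol for cylindrical-specimen indentation (10 mm indenter,
    ~6 mm thick specimen, 2 mm plunge at 0.5 mm/min)."""
    return TestProtocol(
        mode="compression",
        contact_area=math.pi * (indenter_diameter / 2) ** 2,
        reference_length=thickness,
        max_displacement=max_displacement,
        rate=rate,
    )


def tension_protocol(
    width: float = 6e-3,
    thickness: float = 2.5e-3,
    gauge_length: float = 59e-3,
    max_displacement: float = 50e-3,
    rate: float = 500e-3 / 60.0,
) -> TestProtocol:
    """Protocol for dogbone tension (6 x 2.5 mm section, 59 mm gauge,
    500 mm/min stretch to failure)."""
    return TestProtocol(
        mode="tension",
        contact_area=width * thickness,
        reference_length=gauge_length,
        max_displacement=max_displacement,
        rate=rate,
    )


@dataclass
class ModulusFit:
    """Result of a windowed OLS modulus fit."""

    youngs_modulus: float  # Pa
    strain_window: tuple
    n_points: int
    r_squared: float

    @property
    def youngs_modulus_kPa(self) -> float:
        return self.youngs_modulus / 1e3


def to_stress_strain(
    record: Sequence[tuple[float, float]], protocol: TestProtocol
) -> MechanicalCurve:
    """Convert (displacement m, load N) pairs to an engineering curve.

    strain = displacement / reference_length, stress = load / contact_area.
    Compression records are reported as positive magnitudes.  Raw machine
    data need not be monotonic: pairs are stably sorted by strain so the
    resulting curve is non-decreasing without breaking the pairing.
    """
    arr = np.asarray(record, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] != 2:
        raise ParameterError("record must contain >= 2 (displacement, load) pairs")
    strain = arr[:, 0] / protocol.reference_length
    stress = arr[:, 1] / protocol.contact_area
    if protocol.mode == "compression":
        strain = np.abs(strain)
        stress = np.abs(stress)
    order = np.argsort(strain, kind="stable")
    return MechanicalCurve(
        strain=strain[order], stress=stress[order], test_mode=protocol.mode
    )


def fit_modulus(
    curve: MechanicalCurve,
    window: tuple = DEFAULT_STRAIN_WINDOW,
) -> ModulusFit:
    """OLS slope of stress on strain over a closed strain window.

    The default 10-20% window excludes the compliant toe region at small
    strain and the onset of nonlinearity at large strain.

    Raises
    ------
    InsufficientDataError
        If fewer than 2 samples fall inside the window (or all in-window
        strains coincide, leaving the slope undefined).
    """
    lo, hi = window
    mask = (curve.strain >= lo) & (curve.strain <= hi)
    n = int(np.sum(mask))
    if n < 2 or np.ptp(curve.strain[mask]) == 0:
        raise InsufficientDataError(
            f"only {n} samples with distinct strain inside [{lo}, {hi}]"
        )
    res = stats.linregress(curve.strain[mask], curve.stress[mask])
    return ModulusFit(
        youngs_modulus=float(res.slope),
        strain_window=(lo, hi),
        n_points=n,
        r_squared=float(res.rvalue**2) if np.isfinite(res.rvalue) else 1.0,
    )


def summarize_replicates(
    fits: Sequence[ModulusFit],
) -> tuple[float, Optional[float]]:
    """Mean and sample SD (n-1) of replicate moduli, in kPa.

    SD is None for a single replicate, matching the "value (SD)"
    reporting convention.
    """
    if len(fits) == 0:
        raise ParameterError("at least one fit required")
    vals = np.array([f.youngs_modulus_kPa for f in fits])
    sd = float(np.std(vals, ddof=1)) if vals.size > 1 else None
    return float(np.mean(vals)), sd
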