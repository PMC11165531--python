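"""Packaged reference tables, literature-compliance checks and
bladder-phantom geometry arithmetic.

Three tables ship with the package as JSON data: literature target ranges
per tissue and property, the material recipes (stored as data only), and
the measured properties of the developed tissue-mimicking materials.
Compliance checks compare a measured record against the literature ranges
with inclusive bounds and report the relative deviation to the nearest
violated bound when outside.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Any, Optional, Sequence

from .domain import (
    TISSUES,
    LiteratureRange,
    MaterialRecord,
    MediumProperties,
)
from .errors import ParameterError

__all__ = [
    "load_literature_ranges",
    "load_material_records",
    "load_recipes",
    "ComplianceCheck",
    "ComplianceReport",
    "check_against_literature",
    "BladderGeometry",
    "ellipsoid_volume",
    "expansion_percent",
    "acoustic_path_length",
    "render_report",
    "SCHEMA_VERSION",
]

SCHEMA_VERSION = 1

#: healthy unexpanded bladder wall thickness bounds in mm (men 2.2-4.4,
#: women 2.5-4.4; the union is used for the check)
WALL_THICKNESS_RANGE_MM = (2.2, 4.4)


def _load(name: str) -> dict:
    with resources.files("tmmchar.data").joinpath(name).open() as fh:
        return json.load(fh)


def load_literature_ranges() -> list[LiteratureRange]:
    """Literature target ranges, one entry per (tissue, property)."""
    raw = _load("table1_literature.json")
    return [LiteratureRange(**r) for r in raw["ranges"]]


def load_recipes() -> dict[str, dict[str, float]]:
    """Material recipes as weight-ratio dictionaries (data only)."""
    return _load("table2_recipes.json")["recipes"]


def load_material_records() -> list[MaterialRecord]:
    """Measured properties of the developed materials."""
    raw = _load("table3_materials.json")
    out = []
    for m in raw["materials"]:
        acoustic = MediumProperties(
            speed_of_sound_c=m["speed_m_s"],
            density_rho=m["density_g_cm3"],
            attenuation_alpha=m["attenuation_dB_cm_MHz"],
            # printed impedances come from unrounded inputs; attach separately
            impedance_Z=None,
        )
        std = dict(m.get("std_devs") or {})
        std["impedance_MRayls_printed"] = m["impedance_MRayls"]
        out.append(
            MaterialRecord(
                name=m["name"],
                acoustic=acoustic,
                youngs_modulus_kPa=m.get("youngs_modulus_kPa"),
                std_devs=std,
                tissue=m["tissue"],
                notes=m.get("notes"),
            )
        )
    return out


def printed_impedance(record: MaterialRecord) -> float:
    """The impedance as printed in the source table (MRayls)."""
    return record.std_devs["impedance_MRayls_printed"]  # type: ignore[index]


@dataclass(eq=True)
class ComplianceCheck:
    property: str
    measured: float
    low: Optional[float]
    high: Optional[float]
    status: str  # pass | fail | no_range
    relative_deviation: float  # 0 when inside; to nearest violated bound otherwise


@dataclass
class ComplianceReport:
    material: str
    checks: list[ComplianceCheck] = field(default_factory=list)

    @property
    def all_pass(self) -> bool:
        return all(c.status != "fail" for c in self.checks)

    def to_dict(self) -> dict[str, Any]:
        return {
            "material": self.material,
            "checks": [vars(c) for c in self.checks],
        }


def _measured_properties(record: MaterialRecord) -> dict[str, float]:
    props: dict[str, float] = {}
    if record.youngs_modulus_kPa is not None:
        props["youngs_modulus_kPa"] = record.youngs_modulus_kPa
    a = record.acoustic
    props["speed_m_s"] = a.speed_of_sound_c
    props["attenuation_dB_cm_MHz"] = a.attenuation_alpha
    if a.density_rho is not None:
        props["density_g_cm3"] = a.density_rho
    if record.std_devs and "impedance_MRayls_printed" in record.std_devs:
        props["impedance_MRayls"] = record.std_devs["impedance_MRayls_printed"]
    elif a.impedance_Z is not None:
        props["impedance_MRayls"] = a.impedance_Z
    return props


def check_against_literature(
    record: MaterialRecord,
    ranges: Optional[Sequence[LiteratureRange]] = None,
    tissue: Optional[str] = None,
) -> ComplianceReport:
    """Compare a material record against the literature target ranges.

    Bounds are inclusive; a measured value outside its range is reported
    with the relative deviation to the nearest violated bound (the
    convention used when a property sits "x% below the lower bound").
    Properties with no literature range are marked ``no_range``.
    """
    ranges = list(ranges) if ranges is not None else load_literature_ranges()
    tissue = tissue or record.tissue
    if tissue not in TISSUES:
        raise ParameterError(
            f"unknown tissue {tissue!r} for material {record.name!r}; valid: {TISSUES}"
        )
    by_prop = {r.property: r for r in ranges if r.tissue == tissue}
    report = ComplianceReport(material=record.name)
    for prop, value in sorted(_measured_properties(record).items()):
        rng = by_prop.get(prop)
        if rng is None or not rng.has_range:
            report.checks.append(
                ComplianceCheck(prop, value, None, None, "no_range", 0.0)
            )
            continue
        lo, hi = rng.low, rng.high
        if lo <= value <= hi:  # type: ignore[operator]
            report.checks.append(ComplianceCheck(prop, value, lo, hi, "pass", 0.0))
        else:
            bound = lo if value < lo else hi  # nearest violated bound
            dev = abs(value - bound) / abs(bound) if bound != 0 else math.inf
            report.checks.append(ComplianceCheck(prop, value, lo, hi, "fail", dev))
    return report


@dataclass(eq=True)
class BladderGeometry:
    """Two half tri-axial ellipsoids sharing in-plane semi-axes a, b (cm)
    with different half-heights c_top, c_bottom (cm); wall thickness in mm."""

    a: float
    b: float
    c_top: float
    c_bottom: float
    wall_thickness: float = 3.0

    def __post_init__(self) -> None:
        for name in ("a", "b", "c_top", "c_bottom", "wall_thickness"):
            if not getattr(self, name) > 0:
                raise ParameterError(f"{name} must be positive")

    @property
    def wall_thickness_in_range(self) -> bool:
        lo, hi = WALL_THICKNESS_RANGE_MM
        return lo <= self.wall_thickness <= hi


def ellipsoid_volume(geom: BladderGeometry) -> float:
    """Outer enclosed volume of the two-half-ellipsoid body, in mL.

    Each half contributes (2*pi/3) a b c, so V = (2*pi/3) a b (c_top +
    c_bottom) with lengths in cm (cm^3 == mL).
    """
    return (2.0 * math.pi / 3.0) * geom.a * geom.b * (geom.c_top + geom.c_bottom)


def expansion_percent(v0: float, v1: float) -> float:
    """Relative volume change 100*(v1 - v0)/v0 in percent."""
    if not v0 > 0:
        raise ParameterError("v0 must be positive")
    return 100.0 * (v1 - v0) / v0


def acoustic_path_length(delay: float, speed_of_sound: float = 1481.0) -> float:
    """Path length (m) implied by a propagation delay through a medium."""
    if not (delay > 0 and speed_of_sound > 0):
        raise ParameterError("delay and speed_of_sound must be positive")
    return delay * speed_of_sound


def _fmt_sd(value: float, sd: Optional[float], nd: int = 2) -> str:
    if sd is None:
        return f"{value:.{nd}f}"
    return f"{value:.{nd}f} ({sd:.{nd}f})"


def render_report(
    records: Sequence[MaterialRecord],
    reports: Optional[Sequence[ComplianceReport]] = None,
) -> tuple[str, str]:
    """Deterministic JSON + plain-text summary of material records.

    Records are ordered by name, properties alphabetically; the text table
    mirrors the "value (SD)" convention with speed at 1 decimal, impedance
    at 2 decimals and coefficients at 4.
    """
    records = sorted(records, key=lambda r: r.name)
    reports_by_name = {r.material: r for r in (reports or [])}

    json_obj: dict[str, Any] = {"schema_version": SCHEMA_VERSION, "materials": []}
    lines = [
        f"{'material':<22}{'E (kPa)':>16}{'c (m/s)':>16}"
        f"{'alpha (dB/cm/MHz)':>20}{'rho (g/cm3)':>14}{'Z (MRayls)':>12}"
    ]
    for rec in records:
        sd = rec.std_devs or {}
        a = rec.acoustic
        entry: dict[str, Any] = {
            "name": rec.name,
            "tissue": rec.tissue,
            "speed_m_s": a.speed_of_sound_c,
            "attenuation_dB_cm_MHz": a.attenuation_alpha,
            "density_g_cm3": a.density_rho,
            "impedance_MRayls": sd.get(
                "impedance_MRayls_printed",
                round(a.density_rho * a.speed_of_sound_c * 1e-3, 2)
                if a.density_rho
                else None,
            ),
            "youngs_modulus_kPa": rec.youngs_modulus_kPa,
            "std_devs": {k: v for k, v in sorted(sd.items())},
        }
        if rec.name in reports_by_name:
            entry["compliance"] = reports_by_name[rec.name].to_dict()
        json_obj["materials"].append(entry)
        e_txt = (
            _fmt_sd(rec.youngs_modulus_kPa, sd.get("youngs_modulus_kPa"), 1)
            if rec.youngs_modulus_kPa is not None
            else "-"
        )
        lines.append(
            f"{rec.name:<22}"
            f"{e_txt:>16}"
            f"{_fmt_sd(a.speed_of_sound_c, sd.get('speed_m_s'), 1):>16}"
            f"{_fmt_sd(a.attenuation_alpha, sd.get('attenuation_dB_cm_MHz'), 2):>20}"
            f"{_fmt_sd(a.density_rho, sd.get('density_g_cm3'), 2) if a.density_rho else '-':>14}"
            f"{entry['impedance_MRayls']:>12.2f}"
        )
    return json.dumps(json_obj, indent=2, sort_keys=True), "\n".join(lines)
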