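"""CSV input/output for oscilloscope waveform exports and mechanical tests.

The canonical waveform dialect written by :func:`write_waveform_csv` is
comma-separated with ``#``-prefixed metadata lines carrying the exact
sampling rate, start time and label, followed by a ``time_s,voltage_V``
header and full-precision rows.  :func:`read_waveform_csv` also accepts
foreign two-column exports (e.g. PicoScope) with arbitrary text header
lines: the time unit is auto-detected from the header when possible and the
sampling rate is inferred from the median time step.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from .domain import SpecimenGeometry, Waveform
from .errors import FormatError

__all__ = [
    "WaveformPair",
    "read_waveform_csv",
    "write_waveform_csv",
    "read_mechanical_csv",
]

log = logging.getLogger(__name__)

_TIME_UNITS = {"s": 1.0, "ms": 1e-3, "us": 1e-6}
#: max relative deviation of time steps from their median before the file is
#: rejected as non-uniformly sampled
_UNIFORMITY_TOL = 1e-3

_META_RE = re.compile(r"^#\s*(\w+)\s*=\s*(.*)$")


@dataclass
class WaveformPair:
    """A calibration/specimen waveform pair sharing one acquisition setup."""

    calibration: Waveform
    specimen: Waveform
    geometry: SpecimenGeometry

    def __post_init__(self) -> None:
        if self.calibration.sampling_rate != self.specimen.sampling_rate:
            raise FormatError(
                "calibration and specimen waveforms must share a sampling rate "
                f"({self.calibration.sampling_rate} != {self.specimen.sampling_rate})"
            )
        ratio = self.calibration.n / self.specimen.n
        if not (0.5 <= ratio <= 2.0):
            raise FormatError(
                "calibration and specimen record lengths differ by more than 2x "
                f"({self.calibration.n} vs {self.specimen.n})"
            )


def _detect_time_unit(header_lines: list[str]) -> Optional[str]:
    text = " ".join(header_lines).lower().replace("µ", "u").replace("(", " ").replace(")", " ")
    # longest-token first so "us"/"ms" beat a bare "s"
    for unit in ("us", "ms"):
        if re.search(rf"\b{unit}\b", text):
            return unit
    if re.search(r"\b(s|sec|seconds)\b", text):
        return "s"
    return None


def _split_numeric(path: Path) -> tuple[list[str], np.ndarray, dict[str, str]]:
    """Separate header/metadata lines from two-column numeric rows."""
    header: list[str] = []
    meta: dict[str, str] = {}
    rows: list[tuple[float, float]] = []
    with open(path, "r") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            m = _META_RE.match(line)
            if m:
                meta[m.group(1)] = m.group(2)
                continue
            parts = [p.strip() for p in line.split(",")]
            if len(parts) >= 2:
                try:
                    rows.append((float(parts[0]), float(parts[1])))
                    continue
                except ValueError:
                    pass
            if rows:
                raise FormatError(f"non-numeric row after data started in {path}")
            header.append(line)
    return header, np.asarray(rows, dtype=float), meta


def read_waveform_csv(
    path, time_unit_hint: Optional[str] = None
) -> Waveform:
    """Read a two-column (time, voltage) CSV into a :class:`Waveform`.

    The sampling rate is inferred from the median time step (robust to a
    corrupted first row); the time unit is taken from the header text when
    detectable, else from ``time_unit_hint``, else assumed seconds.  Files
    written by :func:`write_waveform_csv` round-trip exactly via their
    metadata lines.

    Raises
    ------
    FormatError
        Fewer than 2 numeric rows, or time steps deviating from their
        median by more than 0.1% (non-uniform sampling).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"waveform file not found: {path}")
    header, data, meta = _split_numeric(path)
    if data.shape[0] < 2:
        raise FormatError(f"{path}: fewer than 2 numeric rows")

    if "sampling_rate_hz" in meta:
        # canonical dialect: exact metadata round-trip
        return Waveform(
            samples=data[:, 1],
            sampling_rate=float(meta["sampling_rate_hz"]),
            t0=float(meta.get("t0_s", data[0, 0])),
            label=meta.get("label", ""),
        )

    unit = _detect_time_unit(header) or time_unit_hint or "s"
    if unit not in _TIME_UNITS:
        raise FormatError(f"unknown time unit hint {unit!r}; use one of s/ms/us")
    scale = _TIME_UNITS[unit]
    t = data[:, 0] * scale
    dt = np.diff(t)
    med = float(np.median(dt))
    if med <= 0:
        raise FormatError(f"{path}: time column is not increasing")
    if np.max(np.abs(dt - med)) > _UNIFORMITY_TOL * med:
        raise FormatError(
            f"{path}: non-uniform time steps (max deviation "
            f"{np.max(np.abs(dt - med)) / med:.2e} relative to median)"
        )
    return Waveform(samples=data[:, 1], sampling_rate=1.0 / med, t0=float(t[0]))


def write_waveform_csv(path, w: Waveform) -> None:
    """Write a waveform in the package's canonical CSV dialect."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# tmmchar waveform v1\n")
        fh.write(f"# sampling_rate_hz = {float(w.sampling_rate)!r}\n")
        fh.write(f"# t0_s = {float(w.t0)!r}\n")
        fh.write(f"# label = {w.label}\n")
        fh.write("time_s,voltage_V\n")
        t = w.times
        for ti, vi in zip(t, w.samples):
            fh.write(f"{float(ti)!r},{float(vi)!r}\n")


#: displacements more negative than this (in meters) trigger a warning before
#: being clamped to zero; smaller negatives are treated as load-cell zeroing
#: noise and clamped silently
_NEG_DISP_TOL = -10e-6


def read_mechanical_csv(path) -> list[tuple[float, float]]:
    """Read a (displacement mm, load N) CSV into SI (m, N) pairs.

    Machine data need not be monotonic in displacement.  Displacements below
    -10 um are clamped to zero with a logged warning; smaller negative
    values are clamped silently.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"mechanical file not found: {path}")
    _, data, _ = _split_numeric(path)
    if data.shape[0] < 2:
        raise FormatError(f"{path}: fewer than 2 numeric rows")
    disp_m = data[:, 0] * 1e-3
    if np.any(disp_m < _NEG_DISP_TOL):
        log.warning(
            "%s: %d displacement values below -10 um clamped to 0",
            path,
            int(np.sum(disp_m < _NEG_DISP_TOL)),
        )
    disp_m = np.clip(disp_m, 0.0, None)
    return [(float(d), float(f)) for d, f in zip(disp_m, data[:, 1])]
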