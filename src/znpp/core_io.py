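"""Domain types for emission spectra and measurement sessions, plus readers/writers.

The acquisition protocol this module mirrors: an optical fibre probe on the
wet vermillion of the lower lip acquires, per measurement cycle, one emission
spectrum excited at 425 nm, one excited at 407 nm, and one dark spectrum, each
with a 200-ms integration time.  A cycle is repeated 10 times per tissue site
and 10 valid sites are acquired per subject, so a complete session holds
10 x 10 = 100 cycles eligible for quantitation.

Calibration subtracts the dark spectrum and divides by the integration time,
yielding intensities in counts per millisecond.  Negative calibrated values
are legitimate (the 407-weighted difference spectrum dips below zero near the
protoporphyrin IX bands) and are never clipped.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "WavelengthGrid",
    "Spectrum",
    "MeasurementCycle",
    "Site",
    "Session",
    "SpectrumParseError",
    "GridMismatchError",
    "default_grid",
    "calibrate",
    "read_spectrum",
    "write_spectrum",
    "read_session",
    "write_session",
    "pool_valid_cycles",
]

#: Default common grid: 1-nm spacing, 500-750 nm.  The band arithmetic used
#: downstream (520-525 normalisation window, index bands at 562/576/593 nm,
#: fit window 560-750 nm) presumes a shared uniform grid; 1 nm resolves the
#: narrowest haemoglobin features (~10 nm dips).
DEFAULT_GRID_NM = (500.0, 750.0, 1.0)


class SpectrumParseError(ValueError):
    """Raised when a spectrum or session file violates the format contract."""


class GridMismatchError(ValueError):
    """Raised when an operation requires spectra on one common grid."""


@dataclass(frozen=True)
class WavelengthGrid:
    """Strictly increasing wavelength axis in nanometres."""

    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1 or vals.size < 2:
            raise ValueError("wavelength grid needs at least two points")
        if not np.all(np.diff(vals) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return int(self.values.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WavelengthGrid):
            return NotImplemented
        return self.values.shape == other.values.shape and bool(
            np.allclose(self.values, other.values, rtol=0, atol=1e-9)
        )

    @property
    def spacing(self) -> float:
        """Grid step in nm; raises if the grid is not uniform."""
        d = np.diff(self.values)
        if not np.allclose(d, d[0], rtol=1e-9, atol=1e-9):
            raise ValueError("grid is not uniform")
        return float(d[0])

    def is_uniform(self) -> bool:
        d = np.diff(self.values)
        return bool(np.allclose(d, d[0], rtol=1e-9, atol=1e-9))

    def band_mask(self, lo_nm: float, hi_nm: float) -> np.ndarray:
        return (self.values >= lo_nm) & (self.values <= hi_nm)


def default_grid() -> WavelengthGrid:
    lo, hi, step = DEFAULT_GRID_NM
    return WavelengthGrid(np.arange(lo, hi + step / 2, step))


@dataclass(frozen=True)
class Spectrum:
    """One emission spectrum with its excitation and integration metadata.

    ``intensity`` is raw detector counts before calibration and counts per ms
    after; ``excitation_nm`` is 407 or 425 for fluorescence spectra and None
    for dark spectra.
    """

    grid: WavelengthGrid
    intensity: np.ndarray
    excitation_nm: int | None
    integration_time_ms: float
    calibrated: bool = False

    def __post_init__(self) -> None:
        inten = np.asarray(self.intensity, dtype=float)
        if inten.shape != (len(self.grid),):
            raise ValueError(
                f"intensity length {inten.size} != grid length {len(self.grid)}"
            )
        if not self.integration_time_ms > 0:
            raise ValueError("integration_time_ms must be positive")
        if self.excitation_nm is not None and self.excitation_nm not in (407, 425):
            raise ValueError("excitation_nm must be 407, 425 or None (dark)")
        object.__setattr__(self, "intensity", inten)

    def band_mean(self, lo_nm: float, hi_nm: float) -> float:
        mask = self.grid.band_mask(lo_nm, hi_nm)
        if not mask.any():
            raise ValueError(f"band [{lo_nm}, {hi_nm}] nm outside grid")
        return float(self.intensity[mask].mean())

    def resample(self, grid: WavelengthGrid) -> "Spectrum":
        """Linear interpolation onto a new grid (no extrapolation)."""
        lo, hi = self.grid.values[0], self.grid.values[-1]
        if grid.values[0] < lo - 1e-9 or grid.values[-1] > hi + 1e-9:
            raise ValueError("target grid extends beyond the source grid")
        inten = np.interp(grid.values, self.grid.values, self.intensity)
        return replace(self, grid=grid, intensity=inten)

    def scaled(self, factor: float) -> "Spectrum":
        return replace(self, intensity=self.intensity * factor)


@dataclass(frozen=True)
class MeasurementCycle:
    """One acquisition cycle: 425-excited, 407-excited and dark spectra."""

    f425: Spectrum
    f407: Spectrum
    dark: Spectrum

    def __post_init__(self) -> None:
        if not (self.f425.grid == self.f407.grid == self.dark.grid):
            raise GridMismatchError("cycle spectra must share one grid")
        if self.f425.excitation_nm != 425 or self.f407.excitation_nm != 407:
            raise ValueError("cycle spectra carry wrong excitation tags")
        if self.dark.excitation_nm is not None:
            raise ValueError("dark spectrum must have excitation_nm=None")

    def calibrated(self) -> "MeasurementCycle":
        """Dark-subtract and time-normalise both fluorescence spectra."""
        if self.f425.calibrated and self.f407.calibrated:
            return self
        return MeasurementCycle(
            f425=calibrate(self.f425, self.dark),
            f407=calibrate(self.f407, self.dark),
            dark=self.dark,
        )


@dataclass
class Site:
    """One tissue site: its cycles, validity flag and starting blood index."""

    cycles: list[MeasurementCycle]
    valid: bool = True
    blood_index_at_start: float | None = None


@dataclass
class Session:
    """All measurements of one subject.

    A complete study session has 10 valid sites x 10 cycles.  Sites with
    other cycle counts or ``valid=False`` are retained but excluded from
    quantitation.  ``remission`` holds opaque photodiode remission samples
    that may be present in session files; they do not enter any calculation.
    """

    subject_id: str
    sites: list[Site] = field(default_factory=list)
    remission: object | None = None

    def n_cycles(self) -> int:
        return sum(len(s.cycles) for s in self.sites)

    def iter_cycles(self) -> Iterator[MeasurementCycle]:
        for site in self.sites:
            yield from site.cycles


def calibrate(raw: Spectrum, dark: Spectrum) -> Spectrum:
    """Dark-subtract and integration-time-normalise a raw spectrum.

    output = (raw - dark) / integration_time_ms, in counts per ms.
    """
    if raw.calibrated:
        raise ValueError("spectrum is already calibrated")
    if not raw.grid == dark.grid:
        raise GridMismatchError("raw and dark spectra are on different grids")
    if abs(raw.integration_time_ms - dark.integration_time_ms) > 1e-9:
        raise ValueError("raw and dark integration times differ")
    inten = (raw.intensity - dark.intensity) / raw.integration_time_ms
    return Spectrum(
        grid=raw.grid,
        intensity=inten,
        excitation_nm=raw.excitation_nm,
        integration_time_ms=raw.integration_time_ms,
        calibrated=True,
    )


# ---------------------------------------------------------------------------
# Spectrum TSV dialect
#
#   # znpp-spectrum/1
#   # excitation_nm=425          (or "none" for dark spectra)
#   # integration_time_ms=200
#   # calibrated=false
#   # rows=251                   (checksummed row count; detects truncation)
#   wavelength_nm<TAB>intensity
#   500.0<TAB>123.4
# ---------------------------------------------------------------------------

_FORMAT_TAG = "znpp-spectrum/1"


def write_spectrum(spectrum: Spectrum, path: str | Path) -> None:
    path = Path(path)
    lines = [
        f"# {_FORMAT_TAG}",
        "# excitation_nm="
        + ("none" if spectrum.excitation_nm is None else str(spectrum.excitation_nm)),
        f"# integration_time_ms={spectrum.integration_time_ms!r}",
        f"# calibrated={'true' if spectrum.calibrated else 'false'}",
        f"# rows={len(spectrum.grid)}",
        "wavelength_nm\tintensity",
    ]
    for wl, v in zip(spectrum.grid.values, spectrum.intensity):
        lines.append(f"{float(wl)!r}\t{float(v)!r}")
    path.write_text("\n".join(lines) + "\n")


def read_spectrum(path: str | Path) -> Spectrum:
    path = Path(path)
    meta: dict[str, str] = {}
    wavelengths: list[float] = []
    intensities: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, _, val = body.partition("=")
                    meta[key.strip()] = val.strip()
                continue
            if line.startswith("wavelength_nm"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise SpectrumParseError(f"{path}:{lineno}: expected two columns")
            try:
                wavelengths.append(float(parts[0]))
                intensities.append(float(parts[1]))
            except ValueError as exc:
                raise SpectrumParseError(f"{path}:{lineno}: {exc}") from None

    for key in ("excitation_nm", "integration_time_ms", "rows"):
        if key not in meta:
            raise SpectrumParseError(f"{path}: missing metadata line '# {key}=...'")
    if int(meta["rows"]) != len(wavelengths):
        raise SpectrumParseError(
            f"{path}: row checksum mismatch (header says {meta['rows']}, "
            f"found {len(wavelengths)}; file may be truncated)"
        )
    wl = np.asarray(wavelengths)
    if not np.all(np.diff(wl) > 0):
        bad = int(np.argmax(np.diff(wl) <= 0)) + 1
        raise SpectrumParseError(
            f"{path}: wavelengths not strictly increasing near data row {bad + 1}"
        )
    exc_raw = meta["excitation_nm"]
    excitation = None if exc_raw == "none" else int(exc_raw)
    return Spectrum(
        grid=WavelengthGrid(wl),
        intensity=np.asarray(intensities),
        excitation_nm=excitation,
        integration_time_ms=float(meta["integration_time_ms"]),
        calibrated=meta.get("calibrated", "false") == "true",
    )


# ---------------------------------------------------------------------------
# Session format: JSON-shaped structured text, schema "znpp-session/1",
# with per-cycle spectra embedded as arrays.
# ---------------------------------------------------------------------------

_SESSION_TAG = "znpp-session/1"


def _spectrum_to_obj(s: Spectrum) -> dict:
    return {
        "wavelength_nm": s.grid.values.tolist(),
        "intensity": s.intensity.tolist(),
        "excitation_nm": s.excitation_nm,
        "integration_time_ms": s.integration_time_ms,
        "calibrated": s.calibrated,
    }


def _spectrum_from_obj(obj: dict) -> Spectrum:
    return Spectrum(
        grid=WavelengthGrid(np.asarray(obj["wavelength_nm"], dtype=float)),
        intensity=np.asarray(obj["intensity"], dtype=float),
        excitation_nm=obj["excitation_nm"],
        integration_time_ms=float(obj["integration_time_ms"]),
        calibrated=bool(obj["calibrated"]),
    )


def write_session(session: Session, path: str | Path) -> None:
    doc = {
        "format": _SESSION_TAG,
        "subject_id": session.subject_id,
        "n_sites": len(session.sites),
        "sites": [
            {
                "valid": site.valid,
                "blood_index_at_start": site.blood_index_at_start,
                "n_cycles": len(site.cycles),
                "cycles": [
                    {
                        "f425": _spectrum_to_obj(c.f425),
                        "f407": _spectrum_to_obj(c.f407),
                        "dark": _spectrum_to_obj(c.dark),
                    }
                    for c in site.cycles
                ],
            }
            for site in session.sites
        ],
        "remission": session.remission,
    }
    Path(path).write_text(json.dumps(doc))


def read_session(path: str | Path) -> Session:
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise SpectrumParseError(f"{path}: not valid session JSON ({exc})") from None
    if doc.get("format") != _SESSION_TAG:
        raise SpectrumParseError(
            f"{path}: unknown session format {doc.get('format')!r}"
        )
    if doc.get("n_sites") != len(doc.get("sites", [])):
        raise SpectrumParseError(f"{path}: site count checksum mismatch")
    sites = []
    for site_obj in doc["sites"]:
        if site_obj.get("n_cycles") != len(site_obj.get("cycles", [])):
            raise SpectrumParseError(f"{path}: cycle count checksum mismatch")
        cycles = [
            MeasurementCycle(
                f425=_spectrum_from_obj(c["f425"]),
                f407=_spectrum_from_obj(c["f407"]),
                dark=_spectrum_from_obj(c["dark"]),
            )
            for c in site_obj["cycles"]
        ]
        sites.append(
            Site(
                cycles=cycles,
                valid=bool(site_obj["valid"]),
                blood_index_at_start=site_obj.get("blood_index_at_start"),
            )
        )
    return Session(
        subject_id=doc["subject_id"], sites=sites, remission=doc.get("remission")
    )


def pool_valid_cycles(session: Session) -> list[MeasurementCycle]:
    """Calibrated cycles from valid sites only; may be empty."""
    pooled: list[MeasurementCycle] = []
    for site in session.sites:
        if not site.valid:
            continue
        pooled.extend(c.calibrated() for c in site.cycles)
    return pooled
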