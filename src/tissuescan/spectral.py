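"""Spectrum container, calibration and table I/O.

A :class:`Spectrum` is one wavelength-indexed intensity record acquired at a
single probe position, in one of three modalities:

* ``DRS`` — broadband diffuse reflectance (dimensionless after normalisation
  against a Spectralon standard of known nominal reflectance),
* ``FLUOR_RAW`` — raw fluorescence counts, distorted by tissue absorption and
  scattering,
* ``IFS`` — intrinsic fluorescence, i.e. raw fluorescence with the
  absorption/scattering distortion divided out.

Calibration follows the usual reflectance-standard protocol: dark background
subtraction followed by normalisation against a diffuse reflectance standard,

    R(lambda) = R_nominal * (sample - dark) / (standard - dark).

All wavelengths are in nm, positions in mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "Modality",
    "WavelengthGrid",
    "Spectrum",
    "CalibrationSet",
    "GridError",
    "CalibrationError",
    "SpectraTableError",
    "subtract_background",
    "normalize_reflectance",
    "resample",
    "read_spectra_table",
    "write_spectra_table",
]

#: Valid spectrum modalities.
MODALITIES = ("DRS", "FLUOR_RAW", "IFS")

Modality = str

#: Default fluorescence excitation wavelength (nm); frequency-tripled Nd:YAG.
DEFAULT_EXCITATION_NM = 355.0


class GridError(ValueError):
    """Wavelength grids are incompatible or a requested grid is out of range."""


class CalibrationError(ValueError):
    """Reflectance calibration is degenerate (non-positive standard signal)."""


class SpectraTableError(ValueError):
    """A spectra table file is malformed."""


@dataclass(frozen=True)
class WavelengthGrid:
    """Uniform wavelength grid, by default the 350-700 nm acquisition band
    sampled at the spectrometer's 2 nm resolution."""

    start_nm: float = 350.0
    stop_nm: float = 700.0
    step_nm: float = 2.0

    def __post_init__(self) -> None:
        if self.step_nm <= 0:
            raise ValueError("step_nm must be positive")
        if self.start_nm >= self.stop_nm:
            raise ValueError("start_nm must be below stop_nm")

    @property
    def wavelengths(self) -> np.ndarray:
        n = int(round((self.stop_nm - self.start_nm) / self.step_nm)) + 1
        return self.start_nm + self.step_nm * np.arange(n)

    def __len__(self) -> int:
        return len(self.wavelengths)


@dataclass
class Spectrum:
    """One spectrum: strictly increasing wavelength axis plus intensities.

    Parameters
    ----------
    wavelengths_nm
        Strictly increasing wavelength grid in nm.
    intensities
        Nonnegative intensities (counts, or reflectance/IFS units).
    modality
        One of ``DRS``, ``FLUOR_RAW``, ``IFS``.
    excitation_nm
        Excitation wavelength; only meaningful for fluorescence modalities.
    integration_time_ms
        Acquisition integration time.
    meta
        Free-form metadata (flags, provenance).
    """

    wavelengths_nm: np.ndarray
    intensities: np.ndarray
    modality: Modality = "DRS"
    excitation_nm: float = DEFAULT_EXCITATION_NM
    integration_time_ms: float = 1.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavelengths_nm.ndim != 1:
            raise ValueError("wavelengths_nm must be 1-D")
        if self.wavelengths_nm.shape != self.intensities.shape:
            raise ValueError("wavelengths and intensities differ in length")
        if len(self.wavelengths_nm) >= 2 and not np.all(
            np.diff(self.wavelengths_nm) > 0
        ):
            raise ValueError("wavelengths must be strictly increasing")
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.integration_time_ms <= 0:
            raise ValueError("integration_time_ms must be positive")

    def copy_with(self, **kw) -> "Spectrum":
        out = replace(self, **kw)
        if "meta" not in kw:
            out.meta = dict(self.meta)
        return out

    def same_grid(self, other: "Spectrum", atol: float = 1e-9) -> bool:
        return self.wavelengths_nm.shape == other.wavelengths_nm.shape and np.allclose(
            self.wavelengths_nm, other.wavelengths_nm, atol=atol, rtol=0.0
        )

    def band(self, lo_nm: float, hi_nm: float) -> "Spectrum":
        """Restrict to a wavelength window [lo_nm, hi_nm] (inclusive)."""
        sel = (self.wavelengths_nm >= lo_nm) & (self.wavelengths_nm <= hi_nm)
        return self.copy_with(
            wavelengths_nm=self.wavelengths_nm[sel], intensities=self.intensities[sel]
        )


@dataclass
class CalibrationSet:
    """Dark background plus Spectralon reference, sharing one grid.

    ``spectralon_nominal_reflectance`` is the standard's certified reflectance
    fraction; the scanner's normaliser is a 20 % panel.
    """

    dark_background: Spectrum
    spectralon_reference: Spectrum
    spectralon_nominal_reflectance: float = 0.20

    def __post_init__(self) -> None:
        if not (0.0 < self.spectralon_nominal_reflectance <= 1.0):
            raise ValueError("nominal reflectance must be in (0, 1]")
        if not self.dark_background.same_grid(self.spectralon_reference):
            raise GridError("dark and Spectralon spectra are on different grids")


def _require_same_grid(a: Spectrum, b: Spectrum, what: str) -> None:
    if not a.same_grid(b):
        raise GridError(f"{what}: spectra are on different wavelength grids; resample first")


def subtract_background(raw: Spectrum, dark: Spectrum) -> Spectrum:
    """Subtract the dark background, clipping negatives to zero.

    Detector noise can dip below the dark level; negative differences are
    floored at 0 and the number of clipped channels is recorded in
    ``meta['n_clipped']`` so downstream nonnegativity invariants hold.
    """
    _require_same_grid(raw, dark, "subtract_background")
    diff = raw.intensities - dark.intensities
    n_clipped = int(np.sum(diff < 0))
    out = raw.copy_with(intensities=np.maximum(diff, 0.0))
    out.meta["background_subtracted"] = True
    out.meta["n_clipped"] = n_clipped
    return out


def normalize_reflectance(sample: Spectrum, cal: CalibrationSet) -> Spectrum:
    """Convert raw counts to reflectance via the Spectralon standard.

    R(lambda) = nominal * (sample - dark) / (spectralon - dark).

    Skips dark subtraction for inputs already flagged
    ``meta['background_subtracted']``. The lamp spectral shape and the
    detector response cancel exactly in the ratio.
    """
    dark = cal.dark_background
    _require_same_grid(sample, dark, "normalize_reflectance")

    if sample.meta.get("background_subtracted"):
        num = sample.intensities
    else:
        num = np.maximum(sample.intensities - dark.intensities, 0.0)
    den = cal.spectralon_reference.intensities - dark.intensities
    if np.any(den <= 0):
        raise CalibrationError(
            "Spectralon reference does not exceed dark background everywhere "
            "in the working band"
        )
    out = sample.copy_with(
        intensities=cal.spectralon_nominal_reflectance * num / den, modality="DRS"
    )
    out.meta["normalized"] = True
    return out


def resample(s: Spectrum, grid: WavelengthGrid | np.ndarray) -> Spectrum:
    """Linearly interpolate a spectrum onto a new grid (no extrapolation).

    Spectra are smooth at the 2 nm instrument resolution, so plain linear
    interpolation is adequate and no smoothing is applied.
    """
    target = grid.wavelengths if isinstance(grid, WavelengthGrid) else np.asarray(grid, float)
    lo, hi = s.wavelengths_nm[0], s.wavelengths_nm[-1]
    if target[0] < lo - 1e-9 or target[-1] > hi + 1e-9:
        raise GridError(
            f"requested grid [{target[0]}, {target[-1]}] nm exceeds source span "
            f"[{lo}, {hi}] nm"
        )
    vals = np.interp(target, s.wavelengths_nm, s.intensities)
    return s.copy_with(wavelengths_nm=target, intensities=vals)


# ---------------------------------------------------------------------------
# Long-format spectra tables
#
# Columns: x_mm, y_mm, modality, wavelength_nm, intensity. One header line,
# UTF-8, comma- or tab-delimited by file extension.
# ---------------------------------------------------------------------------

_TABLE_COLUMNS = ["x_mm", "y_mm", "modality", "wavelength_nm", "intensity"]


def write_spectra_table(
    path: str | Path, pixels: Iterable[tuple[float, float, Spectrum]]
) -> None:
    """Write (x, y, Spectrum) records to a long-format delimited table."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    frames = []
    for x, y, s in pixels:
        frames.append(
            pd.DataFrame(
                {
                    "x_mm": x,
                    "y_mm": y,
                    "modality": s.modality,
                    "wavelength_nm": s.wavelengths_nm,
                    "intensity": s.intensities,
                }
            )
        )
    df = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=_TABLE_COLUMNS)
    )
    df.to_csv(path, sep=sep, index=False, float_format="%.10g")


def read_spectra_table(path: str | Path) -> list[tuple[float, float, Spectrum]]:
    """Read a long-format spectra table back into (x, y, Spectrum) records.

    Rejects malformed headers, non-monotone wavelength runs and duplicate
    (x, y, modality) pixels. Round-trips with :func:`write_spectra_table`
    to ~1e-9 relative precision.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    try:
        df = pd.read_csv(path, sep=sep)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise SpectraTableError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in _TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise SpectraTableError(f"{path}: missing column(s) {missing}")

    out: list[tuple[float, float, Spectrum]] = []
    seen: set[tuple[float, float, str]] = set()
    n_expected: dict[str, int] = {}
    for (x, y, mod), grp in df.groupby(["x_mm", "y_mm", "modality"], sort=False):
        key = (float(x), float(y), str(mod))
        if key in seen:
            raise SpectraTableError(f"duplicate pixel {key}")
        seen.add(key)
        wl = grp["wavelength_nm"].to_numpy(float)
        if len(wl) >= 2 and not np.all(np.diff(wl) > 0):
            raise SpectraTableError(
                f"pixel ({float(x)}, {float(y)}, {mod}): wavelengths not strictly increasing"
            )
        if mod in n_expected and len(wl) != n_expected[mod]:
            raise SpectraTableError(
                f"pixel ({float(x)}, {float(y)}, {mod}): {len(wl)} wavelength rows, "
                f"expected {n_expected[mod]}"
            )
        n_expected.setdefault(str(mod), len(wl))
        out.append(
            (
                float(x),
                float(y),
                Spectrum(wl, grp["intensity"].to_numpy(float), modality=str(mod)),
            )
        )
    return out
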