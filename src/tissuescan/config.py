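"""Validated run configuration for the command-line pipeline.

A single :class:`RunConfig` carries everything a stage needs — wavelength
grid, fit band and bounds, probe geometry, scan pitch and probe offset,
tissue-mask threshold, library path and the one seed from which all
randomness flows. Configs load from YAML or TOML and a serialized copy is
written into every output directory so artifacts are reproducible from their
own metadata.
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml
from pydantic import BaseModel, Field, field_validator

from .drsfit import FitOptions
from .models import ProbeGeometry
from .spectral import WavelengthGrid

__all__ = ["RunConfig", "load_config"]

SUMMARY_SCHEMA_VERSION = 1


class RunConfig(BaseModel):
    """All stage parameters; validated before any stage runs."""

    grid_start_nm: float = 350.0
    grid_stop_nm: float = 700.0
    grid_step_nm: float = 2.0
    fit_band_nm: tuple[float, float] = (370.0, 700.0)
    fit_lower: tuple[float, float, float, float, float] = (0, 0, 0, 0, 0)
    fit_upper: tuple[float, float, float, float, float] = (10, 4, 10, 10, 10)
    collection_radius_mm: float = 0.5
    probe_separation_mm: float = 7.5
    pixel_pitch_mm: float = 0.5
    probe_offset_mm: tuple[float, float] = (7.5, 0.0)
    mask_threshold_fraction: float = 0.05
    library_path: str | None = None
    seed: int = 0
    output_dir: str = "tissuescan_out"

    @field_validator("grid_step_nm", "pixel_pitch_mm", "collection_radius_mm")
    @classmethod
    def _positive(cls, v, info):
        if v <= 0:
            raise ValueError(f"{info.field_name} must be positive")
        return v

    @field_validator("mask_threshold_fraction")
    @classmethod
    def _fraction(cls, v):
        if not (0.0 <= v < 1.0):
            raise ValueError("mask_threshold_fraction must be in [0, 1)")
        return v

    def wavelength_grid(self) -> WavelengthGrid:
        return WavelengthGrid(self.grid_start_nm, self.grid_stop_nm, self.grid_step_nm)

    def probe_geometry(self) -> ProbeGeometry:
        return ProbeGeometry(
            collection_radius_mm=self.collection_radius_mm,
            probe_separation_mm=self.probe_separation_mm,
        )

    def fit_options(self) -> FitOptions:
        return FitOptions(
            band_nm=self.fit_band_nm, lower=self.fit_lower, upper=self.fit_upper
        )

    def library(self):
        from .models import ChromophoreLibrary, default_library

        if self.library_path:
            return ChromophoreLibrary.from_directory(self.library_path)
        return default_library()

    def write_copy(self, out_dir: str | Path) -> Path:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        path = out_dir / "run_config.yaml"
        path.write_text(yaml.safe_dump(json.loads(self.model_dump_json()), sort_keys=True))
        return path


def load_config(path: str | Path | None) -> RunConfig:
    """Load YAML (.yaml/.yml) or TOML (.toml) config; defaults if None."""
    if path is None:
        return RunConfig()
    path = Path(path)
    if path.suffix == ".toml":
        import tomllib

        data = tomllib.loads(path.read_text())
    else:
        data = yaml.safe_load(path.read_text()) or {}
    return RunConfig(**data)
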