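"""Synthetic scans with known ground truth.

Three study designs are emulated, all built on the same forward models used
by the fitter so that round-trip recovery is a meaningful end-to-end test:

* **Liquid phantom plates** — droplets of an intralipid/hemoglobin mixture
  held in 1 cm O-rings on the glass plate, alongside 10 % and 20 %
  Spectralon standards. Intralipid scatters in the Mie regime, so the
  phantom recipe maps the volume fraction linearly to the Mie amplitude
  (A = 1.0 mm^-1 per % at 500 nm, B = 1 fixed) with a small Rayleigh term
  (C = 0.05 mm^-1 per %) from the droplet-size tail; hemoglobin (or a
  drop of blood, modelled as its Hb content) sets absorption, and furan
  (strong 400-450 nm emitter) provides fluorescence in IFS phantoms.
* **Resolution targets** — a dot lattice and a step edge blurred by a
  Gaussian optical point-spread function, for edge-response estimates.
* **Two-tissue scans** — a normal and a cancerous region side by side with
  small cancer foci embedded in the normal region. Per-pixel parameters are
  drawn from class-conditional Gaussians whose means honour the observed
  contrast directions (higher A, C, beta-carotene, NADH in normal tissue;
  higher B, Hb, collagen in cancer).

Every generator is deterministic under its seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.stats import norm

from .models import (
    AbsorberConcentrations,
    ChromophoreLibrary,
    OpticalProperties,
    ProbeGeometry,
    ScatteringParams,
    default_library,
    diffuse_reflectance,
    fluorescence_forward,
    optical_properties,
)
from .spectral import Spectrum, WavelengthGrid

__all__ = [
    "NoiseModel",
    "PhantomSpec",
    "TissueScanSpec",
    "PlateScan",
    "ResolutionTarget",
    "TissueScan",
    "intralipid_scattering",
    "phantom_optical_properties",
    "simulate_phantom_spectrum",
    "simulate_phantom_plate",
    "simulate_resolution_target",
    "simulate_tissue_scan",
    "DEFAULT_CLASS_DISTRIBUTIONS",
]

#: Mie amplitude per percent intralipid (mm^-1 at 500 nm); see module docstring.
INTRALIPID_A_PER_PCT = 1.0
#: Fixed Mie exponent for lipid-droplet scatterers.
INTRALIPID_B = 1.0
#: Small Rayleigh amplitude per percent intralipid (mm^-1 at 500 nm), from the
#: sub-wavelength tail of the droplet size distribution; keeps all three
#: scattering parameters identifiable in phantom series.
INTRALIPID_C_PER_PCT = 0.05
#: Intrinsic furan fluorescence weight per ug/mL.
FURAN_WEIGHT_PER_UGML = 1.0
#: Background (bare glass plate) reflectance.
PLATE_BACKGROUND_REFLECTANCE = 0.02


@dataclass(frozen=True)
class NoiseModel:
    """Measurement noise: fractional multiplicative Gaussian, additive
    floor, optional wavelength jitter. Defaults: 1 % multiplicative, a small
    additive floor, no jitter."""

    multiplicative_sd: float = 0.01
    additive_sd: float = 1e-4
    wavelength_jitter_sd_nm: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.multiplicative_sd, self.additive_sd, self.wavelength_jitter_sd_nm) < 0:
            raise ValueError("noise magnitudes must be nonnegative")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def apply(self, s: Spectrum, rng: np.random.Generator) -> Spectrum:
        y = s.intensities
        if self.wavelength_jitter_sd_nm > 0:
            shift = rng.normal(0.0, self.wavelength_jitter_sd_nm)
            y = np.interp(s.wavelengths_nm, s.wavelengths_nm + shift, y)
        y = y * (1.0 + self.multiplicative_sd * rng.standard_normal(y.shape))
        y = y + self.additive_sd * rng.standard_normal(y.shape)
        return s.copy_with(intensities=np.maximum(y, 0.0))


NO_NOISE = NoiseModel(0.0, 0.0, 0.0)


@dataclass(frozen=True)
class PhantomSpec:
    """One liquid phantom: intralipid scatterer, Hb absorber, furan emitter."""

    intralipid_pct: float
    c_hb: float = 0.0            # mg/mL
    c_furan: float = 0.0         # ug/mL
    droplet_id: int = 0

    def __post_init__(self) -> None:
        if min(self.intralipid_pct, self.c_hb, self.c_furan) < 0:
            raise ValueError("phantom composition must be nonnegative")


def intralipid_scattering(intralipid_pct: float) -> ScatteringParams:
    """Map intralipid volume fraction to Mie scattering parameters."""
    return ScatteringParams(
        A=INTRALIPID_A_PER_PCT * intralipid_pct,
        B=INTRALIPID_B,
        C=INTRALIPID_C_PER_PCT * intralipid_pct,
    )


def phantom_optical_properties(
    spec: PhantomSpec, lib: ChromophoreLibrary, wavelengths_nm: np.ndarray
) -> OpticalProperties:
    return optical_properties(
        wavelengths_nm,
        intralipid_scattering(spec.intralipid_pct),
        AbsorberConcentrations(c_hb=spec.c_hb, c_bcar=0.0),
        lib,
    )


def simulate_phantom_spectrum(
    spec: PhantomSpec,
    noise: NoiseModel = NO_NOISE,
    geom: ProbeGeometry | None = None,
    lib: ChromophoreLibrary | None = None,
    grid: WavelengthGrid | None = None,
) -> tuple[Spectrum, Spectrum]:
    """Simulate one phantom's (DRS, raw fluorescence) spectrum pair."""
    geom = geom or ProbeGeometry()
    lib = lib or default_library()
    grid = grid or WavelengthGrid()
    rng = noise.rng()
    wl = grid.wavelengths
    props = phantom_optical_properties(spec, lib, wl)
    drs = diffuse_reflectance(props, geom)
    fluor = fluorescence_forward(
        {"furan": FURAN_WEIGHT_PER_UGML * spec.c_furan}, props, geom, lib=lib
    )
    return noise.apply(drs, rng), noise.apply(fluor, rng)


@dataclass
class PlateScan:
    """A simulated phantom plate: per-pixel spectra plus ground truth."""

    pixels: list[tuple[float, float, Spectrum]]
    droplet_specs: list[PhantomSpec]
    droplet_centers_mm: list[tuple[float, float]]
    droplet_radius_mm: float
    pitch_mm: float
    shape: tuple[int, int]
    spectralon_regions: dict[float, tuple[float, float, float, float]]  # refl -> (x0, y0, x1, y1)

    def droplet_mask(self, i: int) -> np.ndarray:
        rows, cols = self.shape
        cx, cy = self.droplet_centers_mm[i]
        x = (np.arange(cols) + 0.5) * self.pitch_mm
        y = (np.arange(rows) + 0.5) * self.pitch_mm
        xx, yy = np.meshgrid(x, y)
        return (xx - cx) ** 2 + (yy - cy) ** 2 <= self.droplet_radius_mm**2

    def droplet_mean_spectrum(self, i: int) -> Spectrum:
        """Average the pixel spectra inside droplet ``i`` (the per-droplet
        averaging applied before fitting)."""
        mask = self.droplet_mask(i)
        rows, cols = self.shape
        acc = None
        count = 0
        for x, y, s in self.pixels:
            c = int(x / self.pitch_mm)
            r = int(y / self.pitch_mm)
            if r < rows and c < cols and mask[r, c]:
                acc = s.intensities if acc is None else acc + s.intensities
                count += 1
        if count == 0:
            raise ValueError(f"droplet {i} has no pixels")
        ref = self.pixels[0][2]
        return Spectrum(ref.wavelengths_nm.copy(), acc / count, modality="DRS")


def simulate_phantom_plate(
    hb_series: list[float],
    intralipid_pct: float = 2.0,
    noise: NoiseModel = NoiseModel(),
    geom: ProbeGeometry | None = None,
    lib: ChromophoreLibrary | None = None,
    grid: WavelengthGrid | None = None,
    pitch_mm: float = 0.5,
    droplet_diameter_mm: float = 10.0,
    droplet_spacing_mm: float = 12.0,
    n_cols: int = 5,
) -> PlateScan:
    """Simulate a droplet plate: one droplet per Hb value, plus in-scene
    10 % and 20 % Spectralon standards, on a dark glass background.
    An empty series gives a background-plus-standards-only scan."""
    geom = geom or ProbeGeometry()
    lib = lib or default_library()
    grid = grid or WavelengthGrid()
    rng = noise.rng()
    wl = grid.wavelengths

    r = droplet_diameter_mm / 2.0
    if droplet_spacing_mm < droplet_diameter_mm:
        raise ValueError("droplets overlap at the requested layout")
    n = len(hb_series)
    n_rows_drop = int(np.ceil(n / n_cols))
    specs = [
        PhantomSpec(intralipid_pct=intralipid_pct, c_hb=hb, droplet_id=i)
        for i, hb in enumerate(hb_series)
    ]
    centers = [
        (
            droplet_spacing_mm * (i % n_cols) + droplet_spacing_mm / 2.0,
            droplet_spacing_mm * (i // n_cols) + droplet_spacing_mm / 2.0,
        )
        for i in range(n)
    ]
    width = droplet_spacing_mm * n_cols
    spectralon_h = 12.0
    height = droplet_spacing_mm * n_rows_drop + spectralon_h
    y_sp = droplet_spacing_mm * n_rows_drop
    spectralon = {
        0.10: (2.0, y_sp + 1.0, 2.0 + 10.0, y_sp + 11.0),
        0.20: (width - 12.0, y_sp + 1.0, width - 2.0, y_sp + 11.0),
    }

    cols = int(round(width / pitch_mm))
    rows = int(round(height / pitch_mm))
    x = (np.arange(cols) + 0.5) * pitch_mm
    y = (np.arange(rows) + 0.5) * pitch_mm
    xx, yy = np.meshgrid(x, y)

    base = np.full((rows, cols), -1, dtype=int)  # -1 background
    for i, (cx, cy) in enumerate(centers):
        base[(xx - cx) ** 2 + (yy - cy) ** 2 <= r**2] = i
    sp_code = {0.10: -2, 0.20: -3}
    for refl, (x0, y0, x1, y1) in spectralon.items():
        base[(xx >= x0) & (xx <= x1) & (yy >= y0) & (yy <= y1)] = sp_code[refl]

    base_spectra: dict[int, np.ndarray] = {
        -1: np.full_like(wl, PLATE_BACKGROUND_REFLECTANCE),
        -2: np.full_like(wl, 0.10),
        -3: np.full_like(wl, 0.20),
    }
    for i, spec in enumerate(specs):
        props = phantom_optical_properties(spec, lib, wl)
        base_spectra[i] = diffuse_reflectance(props, geom).intensities

    pixels: list[tuple[float, float, Spectrum]] = []
    for rr in range(rows):
        for cc in range(cols):
            s = Spectrum(wl.copy(), base_spectra[base[rr, cc]].copy(), modality="DRS")
            pixels.append((float(x[cc]), float(y[rr]), noise.apply(s, rng)))

    return PlateScan(
        pixels=pixels,
        droplet_specs=specs,
        droplet_centers_mm=centers,
        droplet_radius_mm=r,
        pitch_mm=pitch_mm,
        shape=(rows, cols),
        spectralon_regions=spectralon,
    )


@dataclass
class ResolutionTarget:
    """Blurred dot-lattice image plus a single step-edge line profile."""

    image: np.ndarray                       # (rows, cols) reflectance
    pitch_mm: float
    edge_positions_mm: np.ndarray
    edge_profile: np.ndarray


def simulate_resolution_target(
    dot_diameter_mm: float = 0.25,
    grid_pitch_mm: float = 1.0,
    psf_sigma_mm: float = 0.0975,
    scan_pitch_mm: float = 0.05,
    noise: NoiseModel = NO_NOISE,
    extent_mm: float = 5.0,
    contrast: tuple[float, float] = (0.9, 0.1),
) -> ResolutionTarget:
    """Dot lattice convolved with a Gaussian PSF, plus an ideal blurred edge.

    ``contrast`` is (background, dot) reflectance — dark dots on a bright
    field. The edge profile is a step at the field midpoint blurred by the
    same PSF, evaluated through the exact Gaussian-smoothed step (the normal
    CDF) and sampled at the scan pitch.
    """
    if psf_sigma_mm < 0 or scan_pitch_mm <= 0:
        raise ValueError("psf and pitch must be positive")
    if dot_diameter_mm < scan_pitch_mm:
        warnings.warn("dot diameter below scan pitch: sub-resolution features")
    rng = noise.rng()

    # supersampled lattice, blurred, then decimated to the scan pitch
    sup = max(1, int(round(scan_pitch_mm / 0.01)))
    fine = scan_pitch_mm / sup
    n_fine = int(round(extent_mm / fine))
    ax = (np.arange(n_fine) + 0.5) * fine
    xx, yy = np.meshgrid(ax, ax)
    bg, dot = contrast
    img = np.full((n_fine, n_fine), bg)
    half = grid_pitch_mm / 2.0
    for cx in np.arange(half, extent_mm, grid_pitch_mm):
        for cy in np.arange(half, extent_mm, grid_pitch_mm):
            img[(xx - cx) ** 2 + (yy - cy) ** 2 <= (dot_diameter_mm / 2) ** 2] = dot
    if psf_sigma_mm > 0:
        img = gaussian_filter(img, sigma=psf_sigma_mm / fine, mode="nearest")
    image = img.reshape(n_fine // sup, sup, n_fine // sup, sup).mean(axis=(1, 3))
    if noise.multiplicative_sd > 0 or noise.additive_sd > 0:
        image = np.maximum(
            image * (1 + noise.multiplicative_sd * rng.standard_normal(image.shape))
            + noise.additive_sd * rng.standard_normal(image.shape),
            0.0,
        )

    # single low->high edge at the midpoint of a 4*extent line
    pos = (np.arange(int(round(extent_mm / scan_pitch_mm))) + 0.5) * scan_pitch_mm
    x0 = extent_mm / 2.0
    lo, hi = dot, bg
    if psf_sigma_mm > 0:
        prof = lo + (hi - lo) * norm.cdf((pos - x0) / psf_sigma_mm)
    else:
        prof = np.where(pos >= x0, hi, lo).astype(float)
    if noise.multiplicative_sd > 0:
        prof = prof * (1 + noise.multiplicative_sd * rng.standard_normal(prof.shape))
    return ResolutionTarget(
        image=image, pitch_mm=scan_pitch_mm, edge_positions_mm=pos, edge_profile=prof
    )


# ---------------------------------------------------------------------------
# Two-tissue scans
# ---------------------------------------------------------------------------

#: Class-conditional parameter distributions (mean, sd). Means honour the
#: contrast directions: normal tissue richer in Mie/Rayleigh scatterers,
#: beta-carotene (fat) and NADH; cancer richer in B (larger scatterers/nuclei),
#: Hb (angiogenesis) and collagen (stromal fibrosis). Effect sizes ~1.5-2.5
#: pooled SD. Versioned: bump _CLASS_DIST_VERSION on any change.
_CLASS_DIST_VERSION = 1
DEFAULT_CLASS_DISTRIBUTIONS: dict[str, dict[str, tuple[float, float]]] = {
    "normal": {
        "A": (1.20, 0.12),
        "B": (0.80, 0.12),
        "C": (0.35, 0.05),
        "c_hb": (0.60, 0.12),
        "c_bcar": (0.25, 0.04),
        "collagen": (0.80, 0.15),
        "nadh": (0.90, 0.15),
    },
    "cancer": {
        "A": (0.90, 0.12),
        "B": (1.35, 0.15),
        "C": (0.20, 0.04),
        "c_hb": (1.60, 0.25),
        "c_bcar": (0.10, 0.03),
        "collagen": (2.00, 0.30),
        "nadh": (0.55, 0.12),
    },
}

_PARAM_ORDER = ("A", "B", "C", "c_hb", "c_bcar", "collagen", "nadh")


@dataclass(frozen=True)
class TissueScanSpec:
    """Geometry and statistics of a synthetic two-tissue scan.

    The left half is normal tissue with embedded circular cancer foci; the
    right half is bulk cancer. Default 20 x 20 mm at 0.5 mm pitch keeps
    pixel-wise fitting of full scans affordable while leaving the 1 and 3 mm
    foci at 2 and 6 pixels across.
    """

    width_mm: float = 20.0
    height_mm: float = 20.0
    pitch_mm: float = 0.5
    probe_offset_mm: tuple[float, float] = (7.5, 0.0)
    foci_mm: tuple[tuple[float, float, float], ...] = (
        (5.0, 5.0, 1.0),     # (x, y, diameter)
        (4.0, 14.0, 3.0),
    )
    class_distributions: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: DEFAULT_CLASS_DISTRIBUTIONS
    )
    noise: NoiseModel = NoiseModel()
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("normal", "cancer"):
            dists = self.class_distributions[name]
            for p in _PARAM_ORDER:
                if dists[p][0] < 0:
                    raise ValueError(f"{name}/{p}: negative mean")
        nd, cd = (self.class_distributions[k] for k in ("normal", "cancer"))
        for p in ("A", "C", "c_bcar", "nadh"):
            if not nd[p][0] > cd[p][0]:
                raise ValueError(f"contrast direction violated for {p} (normal should exceed cancer)")
        for p in ("B", "c_hb", "collagen"):
            if not cd[p][0] > nd[p][0]:
                raise ValueError(f"contrast direction violated for {p} (cancer should exceed normal)")
        for _, _, d in self.foci_mm:
            if not (0.0 < d <= 10.0):
                raise ValueError("focus diameters must lie in (0, 10] mm")


@dataclass
class TissueScan:
    """Simulated two-tissue scan with per-pixel ground truth."""

    drs_pixels: list[tuple[float, float, Spectrum]]
    ifs_pixels: list[tuple[float, float, Spectrum]]
    truth_labels: np.ndarray        # (rows, cols), 0 normal / 1 cancer
    truth_params: dict[str, np.ndarray]
    spec: TissueScanSpec

    @property
    def focus_masks(self) -> list[np.ndarray]:
        rows, cols = self.truth_labels.shape
        p = self.spec.pitch_mm
        x = (np.arange(cols) + 0.5) * p
        y = (np.arange(rows) + 0.5) * p
        xx, yy = np.meshgrid(x, y)
        return [
            (xx - fx) ** 2 + (yy - fy) ** 2 <= (d / 2.0) ** 2
            for fx, fy, d in self.spec.foci_mm
        ]


def simulate_tissue_scan(
    spec: TissueScanSpec = TissueScanSpec(),
    lib: ChromophoreLibrary | None = None,
    geom: ProbeGeometry | None = None,
    grid: WavelengthGrid | None = None,
) -> TissueScan:
    """Simulate side-by-side normal/cancer tissue with embedded foci.

    Per-pixel parameters are drawn from the class distributions (clipped at
    a small positive floor), pushed through the same DRS and fluorescence
    forward models the fitter inverts, and degraded by the seeded noise
    model. Fluorescence pixels carry the probe-offset shift in their
    recorded stage coordinates; :func:`tissuescan.assembly.coregister`
    removes it.
    """
    lib = lib or default_library()
    geom = geom or ProbeGeometry()
    grid = grid or WavelengthGrid()
    rng = np.random.default_rng(spec.seed)
    noise_rng = spec.noise.rng()
    wl = grid.wavelengths

    p = spec.pitch_mm
    cols = int(round(spec.width_mm / p))
    rows = int(round(spec.height_mm / p))
    x = (np.arange(cols) + 0.5) * p
    y = (np.arange(rows) + 0.5) * p
    xx, yy = np.meshgrid(x, y)

    labels = (xx >= spec.width_mm / 2.0).astype(np.int8)  # right half cancer
    for fx, fy, d in spec.foci_mm:
        labels[(xx - fx) ** 2 + (yy - fy) ** 2 <= (d / 2.0) ** 2] = 1

    params = {}
    for name in _PARAM_ORDER:
        vals = np.empty((rows, cols))
        for code, cls in ((0, "normal"), (1, "cancer")):
            mu, sd = spec.class_distributions[cls][name]
            m = labels == code
            vals[m] = rng.normal(mu, sd, size=int(m.sum()))
        params[name] = np.clip(vals, 1e-3, None)
    params["B"] = np.clip(params["B"], None, 4.0)

    drs_pixels: list[tuple[float, float, Spectrum]] = []
    ifs_pixels: list[tuple[float, float, Spectrum]] = []
    dx, dy = spec.probe_offset_mm
    for rr in range(rows):
        for cc in range(cols):
            props = optical_properties(
                wl,
                ScatteringParams(
                    A=params["A"][rr, cc], B=params["B"][rr, cc], C=params["C"][rr, cc]
                ),
                AbsorberConcentrations(
                    c_hb=params["c_hb"][rr, cc], c_bcar=params["c_bcar"][rr, cc]
                ),
                lib,
            )
            drs = diffuse_reflectance(props, geom)
            fluor = fluorescence_forward(
                {
                    "collagen": params["collagen"][rr, cc],
                    "nadh": params["nadh"][rr, cc],
                },
                props,
                geom,
                lib=lib,
            )
            drs_pixels.append((float(x[cc]), float(y[rr]), spec.noise.apply(drs, noise_rng)))
            ifs_pixels.append(
                (float(x[cc] + dx), float(y[rr] + dy), spec.noise.apply(fluor, noise_rng))
            )

    return TissueScan(
        drs_pixels=drs_pixels,
        ifs_pixels=ifs_pixels,
        truth_labels=labels,
        truth_params=params,
        spec=spec,
    )
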