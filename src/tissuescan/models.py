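"""Physical forward models shared by the fitter and the simulator.

The scanner's spectral model has three layers:

1. **Optical properties.** Absorption is a linear mix of chromophore
   extinction spectra (hemoglobin in mg/mL, beta-carotene in arbitrary
   concentration units):

       mu_a(lambda) = c_hb * eps_hb(lambda) + c_bcar * eps_bcar(lambda)

   Reduced scattering combines a Mie power law and a Rayleigh term,
   referenced to lambda0 = 500 nm:

       mu_s'(lambda) = A (lambda/lambda0)^-B + C (lambda/lambda0)^-4

   ``A`` tracks the amount of Mie-sized scatterers, ``B`` their size and
   ``C`` the amount of Rayleigh (sub-wavelength) scatterers.

2. **Diffuse reflectance.** The probe collects light over an effective disc
   of radius ``r_c`` around the delivery fiber. The diffusion-approximation
   dipole solution, integrated in closed form over that disc, gives

       R = (mu_s'/mu_t') * 1/2 * [ exp(-mu_eff z0) + exp(-mu_eff zb')
             - z0 exp(-mu_eff r1)/r1 - zb' exp(-mu_eff r2)/r2 ]

   with mu_t' = mu_a + mu_s', mu_eff = sqrt(3 mu_a mu_s'), source depth
   z0 = 1/mu_s', image depth zb' = z0 + 4AD (A the internal-reflection
   parameter for the tissue/glass interface), r1 = sqrt(z0^2 + r_c^2),
   r2 = sqrt(zb'^2 + r_c^2). The absorption-independent diffusion
   convention D = 1/(3 mu_s') is used, so mu_a enters only through the
   albedo prefactor and mu_eff and the reflectance is strictly decreasing
   in absorption everywhere — the behaviour physical probes show.
   R is dimensionless.

3. **Fluorescence distortion.** Measured fluorescence is the intrinsic
   emission line shape multiplied by photon-migration attenuation factors at
   the excitation and emission wavelengths. The same factor is used by the
   simulator (forward) and the extraction (inverse) so the pair is exact by
   construction; see :func:`fluorescence_distortion`.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from .spectral import Spectrum, WavelengthGrid, DEFAULT_EXCITATION_NM

__all__ = [
    "ScatteringParams",
    "AbsorberConcentrations",
    "OpticalProperties",
    "ProbeGeometry",
    "ChromophoreLibrary",
    "default_library",
    "reduced_scattering",
    "absorption",
    "diffuse_reflectance",
    "fluorescence_distortion",
    "fluorescence_forward",
]

#: Internal-reflection parameter for a refractive-index-mismatched boundary
#: (n_rel ~ 1.4, tissue against the scanner glass plate); Groenhuis/Egan fit.
_N_REL = 1.4
_R_D = -1.440 * _N_REL**-2 + 0.710 / _N_REL + 0.668 + 0.0636 * _N_REL
BOUNDARY_A = (1.0 + _R_D) / (1.0 - _R_D)


@dataclass(frozen=True)
class ScatteringParams:
    """Mie/Rayleigh reduced-scattering parameters (amplitudes in mm^-1 at the
    reference wavelength)."""

    A: float
    B: float
    C: float = 0.0
    lambda0_nm: float = 500.0

    def __post_init__(self) -> None:
        if self.A < 0 or self.C < 0:
            raise ValueError("scattering amplitudes must be nonnegative")
        if not (0.0 <= self.B <= 4.0):
            raise ValueError("Mie exponent B must lie in [0, 4]")


@dataclass(frozen=True)
class AbsorberConcentrations:
    """Hemoglobin (mg/mL) and beta-carotene (arbitrary units) concentrations."""

    c_hb: float = 0.0
    c_bcar: float = 0.0

    def __post_init__(self) -> None:
        if self.c_hb < 0 or self.c_bcar < 0:
            raise ValueError("concentrations must be nonnegative")


@dataclass(frozen=True)
class OpticalProperties:
    """Absorption and reduced scattering sampled on a wavelength grid."""

    wavelengths_nm: np.ndarray
    mu_a: np.ndarray
    mu_s_prime: np.ndarray

    def __post_init__(self) -> None:
        for name in ("wavelengths_nm", "mu_a", "mu_s_prime"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), float))
        if np.any(self.mu_a < 0) or np.any(self.mu_s_prime < 0):
            raise ValueError("optical properties must be nonnegative")


@dataclass(frozen=True)
class ProbeGeometry:
    """Closed-form constants of the probe reflectance expression.

    ``collection_radius_mm`` is the single effective geometry parameter of
    the diffusion closed form; it is set once per instrument by
    :func:`tissuescan.drsfit.calibrate_probe` on phantoms of known optical
    properties. ``probe_separation_mm`` is the DRS-to-fluorescence probe
    spacing used for scan co-registration, not for reflectance.
    """

    collection_radius_mm: float = 0.5
    probe_separation_mm: float = 7.5
    spot_diameter_mm: float = 1.0

    def __post_init__(self) -> None:
        if self.collection_radius_mm <= 0 or self.probe_separation_mm <= 0:
            raise ValueError("probe geometry lengths must be positive")


class ChromophoreLibrary:
    """Named extinction spectra and unit-area fluorescence emission bases.

    Spectra are stored as wavelength tables and evaluated by linear
    interpolation; files are two-column (wavelength_nm, value) delimited
    text, one per species, overridable by pointing ``from_directory`` at a
    user library.
    """

    def __init__(
        self,
        absorbers: dict[str, tuple[np.ndarray, np.ndarray]],
        emitters: dict[str, tuple[np.ndarray, np.ndarray]],
    ) -> None:
        self._absorbers = {k: (np.asarray(w, float), np.asarray(v, float)) for k, (w, v) in absorbers.items()}
        self._emitters = {}
        for k, (w, v) in emitters.items():
            w = np.asarray(w, float)
            v = np.asarray(v, float)
            if np.any(v < 0):
                raise ValueError(f"emission basis {k!r} has negative values")
            self._emitters[k] = (w, v)

    @property
    def absorber_names(self) -> list[str]:
        return sorted(self._absorbers)

    @property
    def emitter_names(self) -> list[str]:
        return sorted(self._emitters)

    def extinction(self, name: str, wavelengths_nm: np.ndarray) -> np.ndarray:
        """Extinction spectrum of one absorber (mm^-1 per concentration unit)."""
        if name not in self._absorbers:
            raise KeyError(f"unknown absorber {name!r}; have {self.absorber_names}")
        w, v = self._absorbers[name]
        return np.interp(np.asarray(wavelengths_nm, float), w, v)

    def emission(self, name: str, wavelengths_nm: np.ndarray) -> np.ndarray:
        """Unit-area emission shape of one fluorophore (nm^-1)."""
        if name not in self._emitters:
            raise KeyError(f"unknown fluorophore {name!r}; have {self.emitter_names}")
        w, v = self._emitters[name]
        wl = np.asarray(wavelengths_nm, float)
        out = np.interp(wl, w, v)
        # renormalise to unit area on the evaluation grid
        area = np.trapezoid(out, wl)
        return out / area if area > 0 else out

    def with_emitters(self, shapes: dict[str, tuple[np.ndarray, np.ndarray]]) -> "ChromophoreLibrary":
        emitters = dict(self._emitters)
        emitters.update(shapes)
        return ChromophoreLibrary(self._absorbers, emitters)

    @classmethod
    def from_directory(cls, directory: str | Path) -> "ChromophoreLibrary":
        """Load a library from ``*_extinction*.tsv`` / ``*_emission*.tsv`` files."""
        directory = Path(directory)
        absorbers, emitters = {}, {}
        for f in sorted(directory.glob("*.tsv")):
            data = np.loadtxt(f, comments="#")
            name = f.stem.split("_")[0]
            if "_extinction" in f.stem:
                absorbers[name] = (data[:, 0], data[:, 1])
            elif "_emission" in f.stem:
                emitters[name] = (data[:, 0], data[:, 1])
        if not absorbers and not emitters:
            raise FileNotFoundError(f"no *_extinction/*_emission .tsv files in {directory}")
        return cls(absorbers, emitters)


_DEFAULT_LIB: ChromophoreLibrary | None = None


def default_library() -> ChromophoreLibrary:
    """The packaged library: hb / bcarotene absorbers, collagen / nadh / furan
    emission bases (synthetic parametric shapes; see the data file headers)."""
    global _DEFAULT_LIB
    if _DEFAULT_LIB is None:
        with resources.as_file(resources.files("tissuescan") / "data") as d:
            _DEFAULT_LIB = ChromophoreLibrary.from_directory(d)
    return _DEFAULT_LIB


def reduced_scattering(wavelengths_nm: np.ndarray, p: ScatteringParams) -> np.ndarray:
    """mu_s'(lambda) = A (lambda/lambda0)^-B + C (lambda/lambda0)^-4, in mm^-1."""
    lam = np.asarray(wavelengths_nm, float) / p.lambda0_nm
    return p.A * lam**-p.B + p.C * lam**-4.0


def absorption(
    wavelengths_nm: np.ndarray,
    c: AbsorberConcentrations,
    lib: ChromophoreLibrary,
) -> np.ndarray:
    """mu_a(lambda) = c_hb eps_hb + c_bcar eps_bcar, in mm^-1."""
    wl = np.asarray(wavelengths_nm, float)
    return c.c_hb * lib.extinction("hb", wl) + c.c_bcar * lib.extinction("bcarotene", wl)


def optical_properties(
    wavelengths_nm: np.ndarray,
    scattering: ScatteringParams,
    concentrations: AbsorberConcentrations,
    lib: ChromophoreLibrary,
) -> OpticalProperties:
    """Bundle mu_a and mu_s' for one parameter set on a grid."""
    wl = np.asarray(wavelengths_nm, float)
    return OpticalProperties(
        wl, absorption(wl, concentrations, lib), reduced_scattering(wl, scattering)
    )


def _reflectance_arrays(
    mu_a: np.ndarray, mu_s_prime: np.ndarray, r_c: float
) -> np.ndarray:
    mu_a = np.asarray(mu_a, float)
    mu_sp = np.asarray(mu_s_prime, float)
    if not (np.all(np.isfinite(mu_a)) and np.all(np.isfinite(mu_sp))):
        raise ValueError("optical properties must be finite")
    mu_t = mu_a + mu_sp
    with np.errstate(divide="ignore", invalid="ignore"):
        z0 = 1.0 / mu_sp
        mu_eff = np.sqrt(3.0 * mu_a * mu_sp)
        zb = z0 * (1.0 + 4.0 * BOUNDARY_A / 3.0)  # z0 + 4*A*D, D = 1/(3 mu_s')
        r1 = np.hypot(z0, r_c)
        r2 = np.hypot(zb, r_c)
        R = (
            0.5
            * (mu_sp / mu_t)
            * (
                np.exp(-mu_eff * z0)
                + np.exp(-mu_eff * zb)
                - z0 * np.exp(-mu_eff * r1) / r1
                - zb * np.exp(-mu_eff * r2) / r2
            )
        )
    return np.where(mu_sp > 0, R, 0.0)


def diffuse_reflectance(
    props: OpticalProperties,
    geom: ProbeGeometry,
    grid: WavelengthGrid | np.ndarray | None = None,
) -> Spectrum:
    """Diffusion-approximation probe reflectance, per wavelength.

    Evaluates the disc-integrated dipole closed form (module docstring) at
    the properties' grid, or resampled onto ``grid`` if given.
    """
    wl = props.wavelengths_nm
    mu_a, mu_sp = props.mu_a, props.mu_s_prime
    if grid is not None:
        target = grid.wavelengths if isinstance(grid, WavelengthGrid) else np.asarray(grid, float)
        mu_a = np.interp(target, wl, mu_a)
        mu_sp = np.interp(target, wl, mu_sp)
        wl = target
    R = _reflectance_arrays(mu_a, mu_sp, geom.collection_radius_mm)
    return Spectrum(wl, R, modality="DRS")


def fluorescence_distortion(
    props: OpticalProperties,
    geom: ProbeGeometry,
    excitation_nm: float = DEFAULT_EXCITATION_NM,
    mu_a_excitation: float | None = None,
    mu_s_excitation: float | None = None,
) -> np.ndarray:
    """Photon-migration distortion factor of measured fluorescence.

    Fluorescence photons travel roughly half an excitation path and half an
    emission path, so the practical single-probe correction uses the
    geometric mean of the diffuse attenuation ratios at the excitation and
    emission wavelengths,

        T(lambda_m) = sqrt( [R(mu_a_x, mu_s_x') / R(0, mu_s_x')]
                          * [R(mu_a(lambda_m), mu_s'(lambda_m)) / R(0, mu_s'(lambda_m))] )

    where R(mu_a, mu_s')/R(0, mu_s') is the fraction of the zero-absorption
    diffuse signal surviving absorption. With zero absorption the factor is
    exactly 1 at every wavelength, so the intrinsic line shape is untouched.
    Excitation-wavelength properties default to the properties model
    evaluated (extrapolated) at 355 nm.
    """
    wl = props.wavelengths_nm
    if mu_a_excitation is None:
        mu_a_excitation = float(np.interp(excitation_nm, wl, props.mu_a))
    if mu_s_excitation is None:
        mu_s_excitation = float(np.interp(excitation_nm, wl, props.mu_s_prime))
    r_c = geom.collection_radius_mm

    def atten(mu_a, mu_sp):
        return _reflectance_arrays(mu_a, mu_sp, r_c) / _reflectance_arrays(
            np.zeros_like(np.asarray(mu_sp, float)), mu_sp, r_c
        )

    t_x = atten(np.array([mu_a_excitation]), np.array([mu_s_excitation]))[0]
    t_m = atten(props.mu_a, props.mu_s_prime)
    return np.sqrt(t_x * t_m)


def fluorescence_forward(
    coeffs: dict[str, float],
    props: OpticalProperties,
    geom: ProbeGeometry,
    grid: WavelengthGrid | np.ndarray | None = None,
    lib: ChromophoreLibrary | None = None,
    excitation_nm: float = DEFAULT_EXCITATION_NM,
) -> Spectrum:
    """Raw (distorted) fluorescence for intrinsic fluorophore weights.

    Builds the intrinsic spectrum as ``sum_k w_k * basis_k(lambda)`` and
    multiplies by :func:`fluorescence_distortion`; the extraction in
    :mod:`tissuescan.ifs` divides the same factor back out, so the pair is an
    exact round trip by construction.
    """
    lib = lib or default_library()
    if grid is None:
        wl = props.wavelengths_nm
    else:
        wl = grid.wavelengths if isinstance(grid, WavelengthGrid) else np.asarray(grid, float)
    for name, w in coeffs.items():
        if w < 0:
            raise ValueError(f"fluorophore weight for {name!r} must be nonnegative")
    intrinsic = np.zeros_like(wl)
    for name, w in coeffs.items():
        intrinsic = intrinsic + w * lib.emission(name, wl)
    if grid is not None and not np.array_equal(wl, props.wavelengths_nm):
        props = OpticalProperties(
            wl,
            np.interp(wl, props.wavelengths_nm, props.mu_a),
            np.interp(wl, props.wavelengths_nm, props.mu_s_prime),
        )
    T = fluorescence_distortion(props, geom, excitation_nm=excitation_nm)
    return Spectrum(wl, intrinsic * T, modality="FLUOR_RAW", excitation_nm=excitation_nm)
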