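"""Inverse DRS problem: recover scattering and absorber parameters.

A normalised reflectance spectrum is fitted with the diffusion closed form
of :mod:`tissuescan.models` by bounded nonlinear least squares over the five
parameters (A, B, C, c_hb, c_bcar). The residual surface has local minima in
the Mie exponent B, so the fit is restarted from a small deterministic grid
of B values (amplitudes seeded from the data) and the lowest-residual
solution is returned. There is no randomness anywhere in the fitter:
identical inputs and options give bitwise-identical results.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares, minimize_scalar

from .models import (
    AbsorberConcentrations,
    ChromophoreLibrary,
    ProbeGeometry,
    ScatteringParams,
    _reflectance_arrays,
    default_library,
)
from .spectral import Spectrum

__all__ = ["FitOptions", "DRSFitResult", "fit_drs", "fit_drs_series", "calibrate_probe"]

_PARAM_NAMES = ("A", "B", "C", "c_hb", "c_bcar")


@dataclass(frozen=True)
class FitOptions:
    """Fit configuration.

    The fit band drops 350-370 nm, where lamp output and the filter edge
    leave little usable reflectance signal; the data keep the full
    acquisition band. Bounds are a generous physiological envelope.
    """

    band_nm: tuple[float, float] = (370.0, 700.0)
    lower: tuple[float, ...] = (0.0, 0.0, 0.0, 0.0, 0.0)
    upper: tuple[float, ...] = (10.0, 4.0, 10.0, 10.0, 10.0)
    b_starts: tuple[float, ...] = (0.5, 1.5, 3.0)
    xtol: float = 1e-10
    ftol: float = 1e-10
    gtol: float = 1e-12
    max_nfev: int = 500
    #: accept a start early when its residual RMS falls below this fraction
    #: of the mean reflectance (later starts cannot materially improve a fit
    #: already at the noise floor); keeps pixel-wise maps fast. Deterministic:
    #: starts are tried in a fixed order.
    early_stop_rel_rms: float = 0.02


@dataclass
class DRSFitResult:
    """Fitted DRS parameters with diagnostics."""

    scattering: ScatteringParams
    concentrations: AbsorberConcentrations
    residual_rms: float
    fit_ok: bool
    n_iter: int
    fitted_model: Spectrum

    def as_dict(self) -> dict[str, float]:
        return {
            "A": self.scattering.A,
            "B": self.scattering.B,
            "C": self.scattering.C,
            "c_hb": self.concentrations.c_hb,
            "c_bcar": self.concentrations.c_bcar,
        }


def _model(
    wl: np.ndarray,
    theta: np.ndarray,
    eps_hb: np.ndarray,
    eps_bcar: np.ndarray,
    r_c: float,
) -> np.ndarray:
    A, B, C, c_hb, c_bcar = theta
    lam = wl / 500.0
    mu_sp = A * lam**-B + C * lam**-4.0
    mu_a = c_hb * eps_hb + c_bcar * eps_bcar
    return _reflectance_arrays(mu_a, mu_sp, r_c)


def _failed_result(spectrum: Spectrum, rms: float) -> DRSFitResult:
    return DRSFitResult(
        scattering=ScatteringParams(0.0, 0.0, 0.0),
        concentrations=AbsorberConcentrations(0.0, 0.0),
        residual_rms=rms,
        fit_ok=False,
        n_iter=0,
        fitted_model=spectrum.copy_with(intensities=np.zeros_like(spectrum.intensities)),
    )


def fit_drs(
    spectrum: Spectrum,
    lib: ChromophoreLibrary | None = None,
    geom: ProbeGeometry | None = None,
    opts: FitOptions | None = None,
) -> DRSFitResult:
    """Fit one reflectance spectrum; never raises on non-convergence.

    Multi-start bounded least squares (see module docstring). A degenerate
    input (non-positive or flat) or failure of every start returns
    ``fit_ok=False`` with the residual reported.
    """
    lib = lib or default_library()
    geom = geom or ProbeGeometry()
    opts = opts or FitOptions()

    fit = spectrum.band(*opts.band_nm)
    wl, y = fit.wavelengths_nm, fit.intensities
    if len(wl) < 100:
        raise ValueError(f"fit band holds {len(wl)} channels; need >= 100")
    if np.max(y) <= 0:
        return _failed_result(spectrum, float(np.sqrt(np.mean(y**2))))

    eps_hb = lib.extinction("hb", wl)
    eps_bcar = lib.extinction("bcarotene", wl)
    r_c = geom.collection_radius_mm
    lower, upper = np.array(opts.lower), np.array(opts.upper)

    # seed amplitudes from the red end, where absorption is weakest:
    # invert R(mu_a=0, mu_s') at the mean red reflectance for mu_s'(650)
    red = y[wl >= 630.0]
    r_red = float(np.clip(np.mean(red), 1e-4, None))
    mu_grid = np.linspace(0.05, 20.0, 400)
    R_grid = _reflectance_arrays(np.zeros_like(mu_grid), mu_grid, r_c)
    mu_sp_red = float(np.interp(r_red, R_grid, mu_grid))

    best = None
    total_iter = 0
    for b0 in opts.b_starts:
        A0 = np.clip(mu_sp_red * (650.0 / 500.0) ** b0, lower[0] + 1e-3, upper[0] - 1e-3)
        x0 = np.clip(
            np.array([A0, b0, 0.05, 0.3, 0.05]), lower + 1e-6, upper - 1e-6
        )
        try:
            sol = least_squares(
                lambda th: _model(wl, th, eps_hb, eps_bcar, r_c) - y,
                x0,
                bounds=(lower, upper),
                method="trf",
                xtol=opts.xtol,
                ftol=opts.ftol,
                gtol=opts.gtol,
                max_nfev=opts.max_nfev,
            )
        except Exception:
            continue
        total_iter += sol.nfev
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol
        if (
            best is not None
            and np.sqrt(2.0 * best.cost / len(y)) <= opts.early_stop_rel_rms * np.mean(y)
        ):
            break

    if best is None:
        return _failed_result(spectrum, float(np.sqrt(np.mean(y**2))))

    theta = best.x
    model_full = _model(
        spectrum.wavelengths_nm,
        theta,
        lib.extinction("hb", spectrum.wavelengths_nm),
        lib.extinction("bcarotene", spectrum.wavelengths_nm),
        r_c,
    )
    return DRSFitResult(
        scattering=ScatteringParams(A=theta[0], B=theta[1], C=theta[2]),
        concentrations=AbsorberConcentrations(c_hb=theta[3], c_bcar=theta[4]),
        residual_rms=float(np.sqrt(np.mean(best.fun**2))),
        fit_ok=True,
        n_iter=total_iter,
        fitted_model=Spectrum(spectrum.wavelengths_nm.copy(), model_full, modality="DRS"),
    )


def fit_drs_series(
    spectra: list[Spectrum],
    lib: ChromophoreLibrary | None = None,
    geom: ProbeGeometry | None = None,
    opts: FitOptions | None = None,
) -> tuple[list[DRSFitResult], dict[str, float]]:
    """Fit a series independently; also report per-parameter coefficient of
    variation (std/mean over fits with ``fit_ok``)."""
    if not spectra:
        raise ValueError("empty spectrum series")
    results = [fit_drs(s, lib, geom, opts) for s in spectra]
    ok = [r for r in results if r.fit_ok]
    cv: dict[str, float] = {}
    for name in _PARAM_NAMES:
        vals = np.array([r.as_dict()[name] for r in ok])
        if len(vals) == 0:
            cv[name] = float("nan")
        else:
            m = vals.mean()
            cv[name] = float(vals.std() / m) if m != 0 else 0.0
    return results, cv


def calibrate_probe(
    known_phantoms: list,
    lib: ChromophoreLibrary | None = None,
    radius_bounds_mm: tuple[float, float] = (0.05, 3.0),
) -> ProbeGeometry:
    """Estimate the effective collection radius from known phantoms.

    ``known_phantoms`` pairs each measured reflectance :class:`Spectrum`
    with its known optical properties, given either directly as
    :class:`~tissuescan.models.OpticalProperties` or as a
    :class:`~tissuescan.simulate.PhantomSpec` (converted via the phantom
    recipe). A 1-D least squares over the radius minimises the pooled
    model-data misfit; the returned geometry is reused for every fit of the
    scan.
    """
    if not known_phantoms:
        raise ValueError("need at least one phantom")
    lib = lib or default_library()

    pairs = []
    for spec, spectrum in known_phantoms:
        if hasattr(spec, "mu_a"):
            props = spec
        else:
            from .simulate import phantom_optical_properties

            props = phantom_optical_properties(spec, lib, spectrum.wavelengths_nm)
        if np.max(spectrum.intensities) <= 0:
            raise ValueError("degenerate (all-zero) phantom spectrum")
        mu_a = np.interp(spectrum.wavelengths_nm, props.wavelengths_nm, props.mu_a)
        mu_sp = np.interp(
            spectrum.wavelengths_nm, props.wavelengths_nm, props.mu_s_prime
        )
        pairs.append((mu_a, mu_sp, spectrum.intensities))

    def cost(r_c: float) -> float:
        return sum(
            float(np.sum((_reflectance_arrays(mu_a, mu_sp, r_c) - y) ** 2))
            for mu_a, mu_sp, y in pairs
        )

    res = minimize_scalar(
        cost, bounds=radius_bounds_mm, method="bounded", options={"xatol": 1e-8}
    )
    return ProbeGeometry(collection_radius_mm=float(res.x))
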