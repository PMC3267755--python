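"""Intrinsic fluorescence extraction and linear decomposition.

Raw fluorescence measured through turbid tissue is the intrinsic emission
line shape multiplied by a photon-migration distortion that depends on the
tissue's absorption and scattering at the excitation (355 nm) and emission
wavelengths. The co-located DRS fit supplies those optical properties, and
:func:`extract_intrinsic` divides the distortion out — the exact inverse of
:func:`tissuescan.models.fluorescence_forward`, which shares the same
distortion function. The corrected (IFS) spectrum is then decomposed into
named fluorophore contributions by nonnegative least squares, or a basis can
be learned from data by multivariate curve resolution (MCR-ALS).

Optical properties at the 355 nm excitation come from the fitted DRS model
evaluated there (analytic extrapolation), not from the raw DRS data, whose
350 nm edge carries little signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls

from .drsfit import DRSFitResult, FitOptions, fit_drs
from .models import (
    ChromophoreLibrary,
    OpticalProperties,
    ProbeGeometry,
    default_library,
    fluorescence_distortion,
    optical_properties,
)
from .spectral import Spectrum

__all__ = [
    "ExtractionError",
    "IFSFitResult",
    "MCRResult",
    "extract_intrinsic",
    "nnls_decompose",
    "derive_basis_mcr",
]


class ExtractionError(ValueError):
    """The DRS information cannot support extraction at this pixel."""


@dataclass
class IFSFitResult:
    coefficients: dict[str, float]
    residual_rms: float
    fitted_model: Spectrum
    rank_deficient: bool = False


@dataclass
class MCRResult:
    """MCR-ALS output: unit-area component shapes, per-sample weights and the
    convergence log (squared-Frobenius objective per iteration)."""

    library: ChromophoreLibrary
    shapes: np.ndarray          # (n_components, n_wavelengths)
    weights: np.ndarray         # (n_samples, n_components)
    wavelengths_nm: np.ndarray
    objective_history: list[float] = field(default_factory=list)
    converged: bool = True


def extract_intrinsic(
    fluor_raw: Spectrum,
    drs: Spectrum | DRSFitResult,
    geom: ProbeGeometry | None = None,
    lib: ChromophoreLibrary | None = None,
    fit_opts: FitOptions | None = None,
) -> Spectrum:
    """Correct raw fluorescence to the intrinsic spectrum.

    ``drs`` may be an already-fitted :class:`DRSFitResult` (preferred inside
    the pixel-wise pipeline) or a normalised DRS spectrum, which is fitted
    here first. Raises :class:`ExtractionError` when the DRS information is
    degenerate at the required wavelengths; callers treat that as a flagged
    pixel, not a fatal error.
    """
    geom = geom or ProbeGeometry()
    lib = lib or default_library()

    if isinstance(drs, DRSFitResult):
        fit = drs
    else:
        fit = fit_drs(drs, lib, geom, fit_opts)
    if not fit.fit_ok:
        raise ExtractionError("DRS fit failed; no optical properties for correction")

    wl = fluor_raw.wavelengths_nm
    # the fitted model's mu_a / mu_s' on the fluorescence grid; excitation
    # values come from the same grid by interpolation, exactly mirroring the
    # forward distortion so forward/extract is an identity pair
    props = optical_properties(wl, fit.scattering, fit.concentrations, lib)

    model_R = np.interp(
        wl, fit.fitted_model.wavelengths_nm, fit.fitted_model.intensities
    )
    if np.any(model_R <= 0):
        raise ExtractionError("non-positive DRS reflectance in the emission band")

    T = fluorescence_distortion(props, geom, excitation_nm=fluor_raw.excitation_nm)
    if np.any(T <= 0) or not np.all(np.isfinite(T)):
        raise ExtractionError("degenerate photon-migration factor")
    out = fluor_raw.copy_with(intensities=fluor_raw.intensities / T, modality="IFS")
    out.meta["ifs_corrected"] = True
    return out


def nnls_decompose(
    ifs: Spectrum,
    basis: ChromophoreLibrary | None = None,
    names: list[str] | None = None,
) -> IFSFitResult:
    """Nonnegative least squares of an IFS spectrum onto named basis shapes.

    Deterministic; a rank-deficient basis is flagged (``rank_deficient``)
    and the NNLS solution — minimum-norm within the active set — is still
    returned so maps stay renderable.
    """
    basis = basis or default_library()
    names = names or ["collagen", "nadh"]
    if not names:
        raise ValueError("need at least one basis shape")
    wl = ifs.wavelengths_nm
    M = np.column_stack([basis.emission(n, wl) for n in names])
    rank = np.linalg.matrix_rank(M, tol=1e-10 * np.abs(M).max() * max(M.shape))
    coeffs, rnorm = nnls(M, ifs.intensities)
    fitted = M @ coeffs
    return IFSFitResult(
        coefficients={n: float(c) for n, c in zip(names, coeffs)},
        residual_rms=float(np.sqrt(np.mean((fitted - ifs.intensities) ** 2))),
        fitted_model=ifs.copy_with(intensities=fitted, modality="IFS"),
        rank_deficient=rank < len(names),
    )


def _pick_initial_shapes(X: np.ndarray, k: int) -> np.ndarray:
    """Dissimilarity-based spectrum picking: start from the largest-norm
    spectrum, then greedily add the spectrum with the largest residual after
    projection onto the span of those already chosen. Deterministic."""
    idx = [int(np.argmax(np.linalg.norm(X, axis=1)))]
    for _ in range(1, k):
        basis = X[idx].T  # (m, chosen)
        proj, *_ = np.linalg.lstsq(basis, X.T, rcond=None)
        resid = np.linalg.norm(X.T - basis @ proj, axis=0)
        resid[idx] = -np.inf
        idx.append(int(np.argmax(resid)))
    return np.maximum(X[idx], 0.0)


def derive_basis_mcr(
    training: list[Spectrum],
    n_components: int,
    max_iter: int = 500,
    tol: float = 1e-10,
) -> MCRResult:
    """Learn nonnegative component shapes from mixed IFS spectra (MCR-ALS).

    Alternating NNLS on weights and shapes, with shapes renormalised to unit
    area each sweep (a pure rescaling, absorbed by the weights). The
    objective ||X - W S||_F^2 is non-increasing across iterations.
    Non-convergence within ``max_iter`` returns the last iterate with
    ``converged=False``.
    """
    if len(training) < n_components:
        raise ValueError("need at least n_components training spectra")
    wl = training[0].wavelengths_nm
    X = np.vstack([s.intensities for s in training])  # (n, m)
    n, m = X.shape

    S = _pick_initial_shapes(X, n_components)  # (k, m)
    S = _normalize_shapes(S, wl)
    W = np.zeros((n, n_components))
    history: list[float] = []
    total = float(np.sum(X**2))
    prev = np.inf
    converged = False
    for _ in range(max_iter):
        for i in range(n):
            W[i], _ = nnls(S.T, X[i])
        for j in range(m):
            S[:, j], _ = nnls(W, X[:, j])
        obj = float(np.sum((X - W @ S) ** 2))
        history.append(obj)
        # stop on a vanishing residual or a stalled objective
        if obj <= 1e-12 * total or (np.isfinite(prev) and prev - obj <= tol * max(prev, 1e-30)):
            converged = True
            break
        prev = obj
    areas = np.trapezoid(S, wl, axis=1)
    scale = np.where(areas > 0, areas, 1.0)
    S = S / scale[:, None]
    W = W * scale[None, :]

    emitters = {f"component_{i}": (wl, S[i]) for i in range(n_components)}
    return MCRResult(
        library=ChromophoreLibrary({}, emitters),
        shapes=S,
        weights=W,
        wavelengths_nm=wl,
        objective_history=history,
        converged=converged,
    )


def _normalize_shapes(S: np.ndarray, wl: np.ndarray) -> np.ndarray:
    areas = np.trapezoid(S, wl, axis=1)
    return S / np.where(areas > 0, areas, 1.0)[:, None]
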