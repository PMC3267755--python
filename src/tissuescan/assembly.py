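"""Hyperspectral cube assembly, registration, maps and diagnosis.

Per-pixel spectra from a raster scan become a :class:`HyperCube`
(rows x cols x wavelength). The DRS and fluorescence probes are mounted a
fixed distance apart, so the two cubes record the same tissue under stage
coordinates shifted by that separation; :func:`coregister` removes the shift
by integer-pixel re-registration only — spectra are never interpolated
during registration. Pixel-wise model fitting then produces the seven
quantitative parameter maps (A, B, C, Hb, beta-carotene, collagen, NADH),
and a two-parameter linear decision model over (DRS beta-carotene,
IFS collagen) labels each pixel normal or cancer for the diagnostic map.

Image convention: row-major, 0-based; pixel centers at origin + (i+0.5)*pitch;
x increases with columns, y with rows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import matplotlib
import numpy as np
from scipy.optimize import minimize

from .drsfit import DRSFitResult, FitOptions, fit_drs
from .ifs import ExtractionError, extract_intrinsic, nnls_decompose
from .models import ChromophoreLibrary, ProbeGeometry, default_library
from .spectral import Spectrum

logger = logging.getLogger("tissuescan")

__all__ = [
    "HyperCube",
    "ParameterMap",
    "DiagnosticMap",
    "DecisionModel",
    "PlacementError",
    "RegistrationError",
    "EdgeAmbiguityError",
    "assemble_cube",
    "coregister",
    "spectral_slice",
    "parameter_maps",
    "edge_response",
    "train_decision_model",
    "classify_pixels",
    "tissue_mask_from_cube",
    "render_maps",
    "write_cubes_h5",
    "read_cubes_h5",
]

LABEL_NORMAL, LABEL_CANCER, LABEL_NON_TISSUE = 0, 1, 2
LABEL_NAMES = {LABEL_NORMAL: "normal", LABEL_CANCER: "cancer", LABEL_NON_TISSUE: "non_tissue"}


class PlacementError(ValueError):
    """A pixel position does not sit on the scan grid."""


class RegistrationError(ValueError):
    """Probe offset is not an integer number of pixels."""


class EdgeAmbiguityError(ValueError):
    """An edge profile has zero or multiple candidate edges."""


@dataclass
class HyperCube:
    """One modality's (rows, cols, lambda) cube with registration metadata."""

    data: np.ndarray
    wavelengths_nm: np.ndarray
    pixel_pitch_mm: float
    modality: str = "DRS"
    origin_mm: tuple[float, float] = (0.0, 0.0)
    probe_offset_mm: tuple[float, float] = (0.0, 0.0)
    valid: np.ndarray | None = None  # (rows, cols) bool; None = all valid

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, float)
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, float)
        if self.pixel_pitch_mm <= 0:
            raise ValueError("pixel pitch must be positive")
        if self.data.ndim != 3 or self.data.shape[2] != len(self.wavelengths_nm):
            raise ValueError("data must be (rows, cols, n_wavelengths)")
        if self.valid is None:
            self.valid = np.ones(self.data.shape[:2], dtype=bool)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[:2]

    def pixel_spectrum(self, row: int, col: int) -> Spectrum:
        return Spectrum(
            self.wavelengths_nm.copy(), self.data[row, col], modality=self.modality
        )


@dataclass
class ParameterMap:
    """One per-pixel quantitative parameter image with a validity mask."""

    name: str
    values: np.ndarray
    mask: np.ndarray  # True = valid

    def masked(self) -> np.ma.MaskedArray:
        return np.ma.MaskedArray(self.values, mask=~self.mask)


@dataclass
class DecisionModel:
    """Linear two-class boundary in the (beta-carotene, collagen) plane.

    Logistic maximum likelihood on standardized features with a tiny ridge
    (per-sample mean objective, so duplicating the dataset changes nothing
    and perfectly separable data yield capped coefficients rather than a
    divergent fit).
    """

    feature_names: tuple[str, ...]
    coef: np.ndarray
    intercept: float
    feature_means: np.ndarray
    feature_scales: np.ndarray
    separable: bool = False
    trained_on: dict = field(default_factory=dict)

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        Z = (np.asarray(X, float) - self.feature_means) / self.feature_scales
        return Z @ self.coef + self.intercept

    def predict(self, X: np.ndarray) -> np.ndarray:
        """1 = cancer, 0 = normal (probability-0.5 cut)."""
        return (self.decision_function(X) > 0).astype(np.int8)


def assemble_cube(
    pixels: list[tuple[float, float, Spectrum]],
    pitch_mm: float,
    probe_offset_mm: tuple[float, float] = (0.0, 0.0),
    tol: float = 0.25,
) -> HyperCube:
    """Place (x, y, Spectrum) records onto the inferred regular grid.

    Grid indices come from rounding (pos - origin)/pitch; positions further
    than ``tol`` (in pixels, default a quarter pitch) from a lattice point
    are placement errors, duplicates are rejected, and missing lattice cells
    are masked invalid.
    """
    if not pixels:
        raise ValueError("no pixels to assemble")
    xs = np.array([p[0] for p in pixels])
    ys = np.array([p[1] for p in pixels])
    x0, y0 = xs.min(), ys.min()
    ci = (xs - x0) / pitch_mm
    ri = (ys - y0) / pitch_mm
    cr, rr = np.round(ci), np.round(ri)
    off = np.hypot(ci - cr, ri - rr)
    if np.any(off > tol):
        i = int(np.argmax(off))
        raise PlacementError(
            f"pixel at ({xs[i]}, {ys[i]}) mm is {off[i]:.2f} px off the "
            f"{pitch_mm} mm grid"
        )
    cr = cr.astype(int)
    rr = rr.astype(int)
    rows, cols = rr.max() + 1, cr.max() + 1
    wl = pixels[0][2].wavelengths_nm
    data = np.zeros((rows, cols, len(wl)))
    valid = np.zeros((rows, cols), dtype=bool)
    for (x, y, s), r, c in zip(pixels, rr, cr):
        if valid[r, c]:
            raise PlacementError(f"duplicate pixel at ({x}, {y}) mm")
        if not np.array_equal(s.wavelengths_nm, wl):
            raise ValueError("pixels carry mismatched wavelength grids")
        data[r, c] = s.intensities
        valid[r, c] = True
    return HyperCube(
        data=data,
        wavelengths_nm=wl.copy(),
        pixel_pitch_mm=pitch_mm,
        modality=pixels[0][2].modality,
        origin_mm=(float(x0 - pitch_mm / 2), float(y0 - pitch_mm / 2)),
        probe_offset_mm=probe_offset_mm,
        valid=valid,
    )


def registration_shift_pixels(offset_mm: float, pitch_mm: float) -> int:
    """Integer-pixel shift implied by a probe offset at a given pitch
    (e.g. a 7.5 mm separation at 0.25 mm pitch is a 30-pixel shift)."""
    return _integer_shift(offset_mm, pitch_mm)


def _integer_shift(offset_mm: float, pitch_mm: float, tol_px: float = 0.1) -> int:
    s = offset_mm / pitch_mm
    k = int(round(s))
    if abs(s - k) > tol_px:
        raise RegistrationError(
            f"offset {offset_mm} mm is {s:.3f} pixels at pitch {pitch_mm} mm — "
            "not an integer shift; resample the scan"
        )
    return k


def coregister(drs: HyperCube, ifs: HyperCube) -> tuple[HyperCube, HyperCube]:
    """Shift the fluorescence cube into the DRS frame and crop to overlap.

    The per-axis shift is round(probe_offset/pitch) pixels (an error beyond
    0.1 px); registration is pure integer re-indexing and cropping, never
    interpolation. Applying coregister to already-registered cubes (zero
    offset, same origin) is the identity.
    """
    if drs.pixel_pitch_mm != ifs.pixel_pitch_mm:
        raise RegistrationError("cubes must share a pixel pitch")
    p = drs.pixel_pitch_mm
    dx, dy = ifs.probe_offset_mm
    kx = _integer_shift(dx - drs.probe_offset_mm[0], p)
    ky = _integer_shift(dy - drs.probe_offset_mm[1], p)
    # tissue-frame origin of the fluorescence cube
    ox = ifs.origin_mm[0] - kx * p
    oy = ifs.origin_mm[1] - ky * p
    # integer index offset of ifs grid relative to drs grid
    jx = _integer_shift(ox - drs.origin_mm[0], p)
    jy = _integer_shift(oy - drs.origin_mm[1], p)

    r0 = max(0, jy)
    c0 = max(0, jx)
    r1 = min(drs.shape[0], jy + ifs.shape[0])
    c1 = min(drs.shape[1], jx + ifs.shape[1])
    if r1 <= r0 or c1 <= c0:
        raise RegistrationError("cubes do not overlap after registration")

    def crop(cube: HyperCube, ra, rb, ca, cb, origin) -> HyperCube:
        return HyperCube(
            data=cube.data[ra:rb, ca:cb],
            wavelengths_nm=cube.wavelengths_nm,
            pixel_pitch_mm=cube.pixel_pitch_mm,
            modality=cube.modality,
            origin_mm=origin,
            probe_offset_mm=(0.0, 0.0),
            valid=cube.valid[ra:rb, ca:cb],
        )

    origin = (drs.origin_mm[0] + c0 * p, drs.origin_mm[1] + r0 * p)
    drs_out = crop(drs, r0, r1, c0, c1, origin)
    ifs_out = crop(ifs, r0 - jy, r1 - jy, c0 - jx, c1 - jx, origin)
    return drs_out, ifs_out


def spectral_slice(cube: HyperCube, wavelength_nm: float) -> ParameterMap:
    """Nearest-channel intensity image at one wavelength."""
    wl = cube.wavelengths_nm
    if not (wl[0] <= wavelength_nm <= wl[-1]):
        raise ValueError(f"{wavelength_nm} nm outside the cube's axis [{wl[0]}, {wl[-1]}]")
    k = int(np.argmin(np.abs(wl - wavelength_nm)))
    return ParameterMap(
        name=f"I({wl[k]:g} nm)", values=cube.data[:, :, k].copy(), mask=cube.valid.copy()
    )


_MAP_NAMES = ("A", "B", "C", "c_hb", "c_bcar", "collagen", "nadh")


def parameter_maps(
    drs: HyperCube,
    ifs: HyperCube,
    lib: ChromophoreLibrary | None = None,
    geom: ProbeGeometry | None = None,
    fit_opts: FitOptions | None = None,
    fluor_names: tuple[str, str] = ("collagen", "nadh"),
) -> dict[str, ParameterMap]:
    """Pixel-wise DRS fit + IFS extraction + NNLS decomposition.

    Returns the seven quantitative maps; pixels where either cube is masked
    or any stage fails are masked in all maps (failure counts logged). The
    pipeline is embarrassingly parallel over pixels and processed in raster
    order for determinism.
    """
    if drs.shape != ifs.shape:
        raise ValueError("cubes must be co-registered to the same shape")
    lib = lib or default_library()
    geom = geom or ProbeGeometry()
    rows, cols = drs.shape
    values = {n: np.zeros((rows, cols)) for n in _MAP_NAMES}
    mask = np.zeros((rows, cols), dtype=bool)
    n_fail = 0
    for r in range(rows):
        for c in range(cols):
            if not (drs.valid[r, c] and ifs.valid[r, c]):
                continue
            fit = fit_drs(drs.pixel_spectrum(r, c), lib, geom, fit_opts)
            if not fit.fit_ok:
                n_fail += 1
                continue
            try:
                intrinsic = extract_intrinsic(
                    ifs.pixel_spectrum(r, c).copy_with(modality="FLUOR_RAW"),
                    fit,
                    geom,
                    lib,
                )
            except ExtractionError:
                n_fail += 1
                continue
            dec = nnls_decompose(intrinsic, lib, list(fluor_names))
            d = fit.as_dict()
            for n in ("A", "B", "C", "c_hb", "c_bcar"):
                values[n][r, c] = d[n]
            values["collagen"][r, c] = dec.coefficients[fluor_names[0]]
            values["nadh"][r, c] = dec.coefficients[fluor_names[1]]
            mask[r, c] = True
        logger.debug("parameter_maps: row %d/%d done", r + 1, rows)
    if n_fail:
        logger.info("parameter_maps: %d pixel(s) failed and were masked", n_fail)
    return {n: ParameterMap(name=n, values=values[n], mask=mask.copy()) for n in _MAP_NAMES}


def edge_response(
    positions_mm: np.ndarray, intensities: np.ndarray
) -> float:
    """10-90 % rise distance of a single step-edge profile, in mm.

    The profile is normalized to [0, 1] (so any positive intensity scaling
    cancels), anchored at its unique 50 % crossing, and the 10 % and 90 %
    crossings located by linear interpolation between samples. Profiles with
    no or multiple 50 % crossings are ambiguous and rejected.
    """
    x = np.asarray(positions_mm, float)
    y = np.asarray(intensities, float)
    if len(x) < 4:
        raise ValueError("profile too short")
    if y[0] > y[-1]:  # accept high->low by mirroring
        x, y = -x[::-1], y[::-1]
    f = (y - y.min()) / (y.max() - y.min())
    s = np.sign(f - 0.5)
    crossings = np.nonzero(np.diff(s > 0))[0]
    if len(crossings) != 1:
        cand = [float(x[i]) for i in crossings]
        raise EdgeAmbiguityError(
            f"expected one 50% crossing, found {len(crossings)} near {cand}"
        )

    def crossing(level: float, lo_idx: int, direction: int) -> float:
        i = lo_idx
        while 0 <= i < len(f) - 1:
            a, b = f[i], f[i + 1]
            if (a - level) * (b - level) <= 0 and a != b:
                return float(x[i] + (level - a) / (b - a) * (x[i + 1] - x[i]))
            i += direction
        raise EdgeAmbiguityError(f"no {level:.0%} crossing found")

    anchor = int(crossings[0])
    x10 = crossing(0.10, anchor, -1)
    x90 = crossing(0.90, anchor, +1)
    return abs(x90 - x10)


def train_decision_model(
    features: np.ndarray,
    labels: np.ndarray,
    feature_names: tuple[str, ...] = ("c_bcar", "collagen"),
    ridge: float = 1e-6,
) -> DecisionModel:
    """Fit the linear diagnostic boundary by logistic maximum likelihood.

    Features are standardized; the objective is the per-sample mean negative
    log-likelihood plus a tiny ridge, minimized with L-BFGS from zero — a
    deterministic convex problem. Requires both classes; perfect separation
    is flagged (``separable``), with the ridge keeping coefficients finite.
    """
    X = np.asarray(features, float)
    yv = np.asarray(labels).astype(float)
    if X.ndim != 2 or X.shape[1] != len(feature_names):
        raise ValueError("features must be (n_samples, n_features)")
    classes = np.unique(yv)
    if len(classes) < 2:
        raise ValueError("need both classes to train a boundary")
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    Z = (X - mu) / sd
    t = 2.0 * yv - 1.0  # +-1

    def objective(w):
        margins = t * (Z @ w[:-1] + w[-1])
        nll = np.mean(np.logaddexp(0.0, -margins))
        return nll + 0.5 * ridge * np.dot(w[:-1], w[:-1])

    def grad(w):
        margins = t * (Z @ w[:-1] + w[-1])
        sig = 1.0 / (1.0 + np.exp(np.clip(margins, -500, 500)))
        gw = -(Z * (t * sig)[:, None]).mean(axis=0) + ridge * w[:-1]
        gb = -(t * sig).mean()
        return np.append(gw, gb)

    res = minimize(
        objective,
        np.zeros(Z.shape[1] + 1),
        jac=grad,
        method="L-BFGS-B",
        options={"maxiter": 1000, "ftol": 1e-14, "gtol": 1e-12},
    )
    coef, intercept = res.x[:-1], float(res.x[-1])
    pred = ((Z @ coef + intercept) > 0).astype(float)
    separable = bool(np.all(pred == yv))
    return DecisionModel(
        feature_names=tuple(feature_names),
        coef=coef,
        intercept=intercept,
        feature_means=mu,
        feature_scales=sd,
        separable=separable,
        trained_on={"n_samples": len(yv), "class_counts": {int(k): int((yv == k).sum()) for k in classes}},
    )


@dataclass
class DiagnosticMap:
    """Per-pixel diagnosis: 0 normal, 1 cancer, 2 non-tissue."""

    labels: np.ndarray
    model: DecisionModel

    def label_names(self) -> np.ndarray:
        out = np.empty(self.labels.shape, dtype=object)
        for code, name in LABEL_NAMES.items():
            out[self.labels == code] = name
        return out


def tissue_mask_from_cube(
    drs: HyperCube, spectralon_level: float = 0.20, fraction: float = 0.05
) -> np.ndarray:
    """Pixels whose broadband DRS intensity falls below ``fraction`` of the
    in-scan Spectralon level are non-tissue (gaps, plate background)."""
    broadband = drs.data.mean(axis=2)
    return broadband >= fraction * spectralon_level


def classify_pixels(
    maps: dict[str, ParameterMap],
    model: DecisionModel,
    tissue_mask: np.ndarray | None = None,
) -> DiagnosticMap:
    """Apply the decision model per pixel to build the diagnostic map."""
    missing = [n for n in model.feature_names if n not in maps]
    if missing:
        raise KeyError(f"missing feature map(s) {missing}")
    ref = maps[model.feature_names[0]]
    shape = ref.values.shape
    X = np.column_stack([maps[n].values.ravel() for n in model.feature_names])
    labels = model.predict(X).reshape(shape).astype(np.int8)
    invalid = ~np.logical_and.reduce([maps[n].mask for n in model.feature_names])
    labels[invalid] = LABEL_NON_TISSUE
    if tissue_mask is not None:
        labels[~tissue_mask] = LABEL_NON_TISSUE
    return DiagnosticMap(labels=labels, model=model)


def render_maps(
    maps: dict[str, ParameterMap] | DiagnosticMap,
    out_dir: str | Path,
    pixel_pitch_mm: float = 0.5,
    fmt: str = "png",
) -> list[Path]:
    """Render parameter maps (viridis + colorbar) or a diagnostic map
    (exactly three fixed colors) as deterministic image files with a scale
    bar derived from the pixel pitch."""
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def scale_bar(ax, shape):
        bar_mm = max(1.0, round(shape[1] * pixel_pitch_mm / 5.0))
        ax.plot(
            [shape[1] * 0.05, shape[1] * 0.05 + bar_mm / pixel_pitch_mm],
            [shape[0] * 0.95] * 2,
            "w-",
            lw=3,
        )
        ax.text(shape[1] * 0.05, shape[0] * 0.92, f"{bar_mm:g} mm", color="w", fontsize=8)

    if isinstance(maps, DiagnosticMap):
        fig, ax = plt.subplots(figsize=(4, 4), dpi=150)
        cmap = ListedColormap(["#2e7d32", "#c62828", "#212121"])  # normal/cancer/non-tissue
        ax.imshow(maps.labels, cmap=cmap, vmin=0, vmax=2, interpolation="nearest")
        scale_bar(ax, maps.labels.shape)
        ax.set_axis_off()
        path = out_dir / f"diagnostic_map.{fmt}"
        fig.savefig(path, metadata={"Software": "tissuescan"} if fmt == "png" else None)
        plt.close(fig)
        written.append(path)
        return written

    for name, pm in maps.items():
        fig, ax = plt.subplots(figsize=(4.4, 4), dpi=150)
        im = ax.imshow(pm.masked(), cmap="viridis", interpolation="nearest")
        fig.colorbar(im, ax=ax, shrink=0.85)
        scale_bar(ax, pm.values.shape)
        ax.set_title(name)
        ax.set_axis_off()
        path = out_dir / f"map_{name}.{fmt}"
        fig.savefig(path, metadata={"Software": "tissuescan"} if fmt == "png" else None)
        plt.close(fig)
        written.append(path)
    return written


def write_cubes_h5(path: str | Path, drs: HyperCube, ifs: HyperCube | None = None) -> None:
    """Write cubes to the HDF5 container (/drs, /ifs, /wavelengths_nm)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("drs", data=drs.data)
        f.create_dataset("drs_valid", data=drs.valid)
        if ifs is not None:
            f.create_dataset("ifs", data=ifs.data)
            f.create_dataset("ifs_valid", data=ifs.valid)
            f.attrs["probe_offset_mm"] = ifs.probe_offset_mm
        f.create_dataset("wavelengths_nm", data=drs.wavelengths_nm)
        f.attrs["pixel_pitch_mm"] = drs.pixel_pitch_mm
        f.attrs["origin_mm"] = drs.origin_mm


def read_cubes_h5(path: str | Path) -> tuple[HyperCube, HyperCube | None]:
    with h5py.File(path, "r") as f:
        wl = f["wavelengths_nm"][...]
        pitch = float(f.attrs["pixel_pitch_mm"])
        origin = tuple(f.attrs["origin_mm"])
        drs = HyperCube(
            data=f["drs"][...],
            wavelengths_nm=wl,
            pixel_pitch_mm=pitch,
            modality="DRS",
            origin_mm=origin,
            valid=f["drs_valid"][...].astype(bool),
        )
        ifs = None
        if "ifs" in f:
            ifs = HyperCube(
                data=f["ifs"][...],
                wavelengths_nm=wl,
                pixel_pitch_mm=pitch,
                modality="FLUOR_RAW",
                origin_mm=origin,
                probe_offset_mm=tuple(f.attrs.get("probe_offset_mm", (0.0, 0.0))),
                valid=f["ifs_valid"][...].astype(bool),
            )
    return drs, ifs
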