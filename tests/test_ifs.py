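"""Intrinsic fluorescence extraction, NNLS decomposition and MCR-ALS."""

import itertools

import numpy as np
import pytest

import tissuescan as ts
from tissuescan.ifs import ExtractionError, derive_basis_mcr
from tissuescan.simulate import NoiseModel, PhantomSpec, simulate_phantom_spectrum
from tissuescan.spectral import Spectrum


def _extract_phantom(spec, seed, lib, geom, noise=NoiseModel(0.002, 1e-5, seed=0)):
    noise = NoiseModel(noise.multiplicative_sd, noise.additive_sd, seed=seed)
    drs, raw = simulate_phantom_spectrum(spec, noise, geom, lib)
    fit = ts.fit_drs(drs, lib, geom)
    return raw, ts.extract_intrinsic(raw.copy_with(modality="FLUOR_RAW"), fit, geom, lib)


def relrms(a, b):
    return np.linalg.norm(a - b) / np.linalg.norm((a + b) / 2.0)


class TestExtractIntrinsic:
    def test_zero_absorption_preserves_shape(self, wl, lib, geom):
        props = ts.OpticalProperties(wl, np.zeros_like(wl), np.full_like(wl, 1.5))
        raw = ts.fluorescence_forward({"furan": 1.0}, props, geom, lib=lib)
        fit = ts.fit_drs(ts.diffuse_reflectance(props, geom), lib, geom)
        out = ts.extract_intrinsic(raw, fit, geom, lib)
        shape = lib.emission("furan", wl)
        ratio = out.intensities[shape > shape.max() * 0.01] / shape[shape > shape.max() * 0.01]
        assert np.allclose(ratio, ratio[0], rtol=1e-3)

    def test_replicate_phantom_pairs_agree_after_extraction(self, lib, geom):
        """Same furan, slightly different blood: IFS replicates agree <=5% RMS."""
        p1 = PhantomSpec(1.0, 3.80, 0.8)
        p2 = PhantomSpec(1.0, 3.40, 0.8)
        _, ifs1 = _extract_phantom(p1, 1, lib, geom)
        _, ifs2 = _extract_phantom(p2, 2, lib, geom)
        assert relrms(ifs1.intensities, ifs2.intensities) <= 0.05

    def test_absorption_invariance_across_hb_range(self, lib, geom):
        """Fixed fluorophore content: extracted IFS varies <5% RMS over
        Hb 0.3-3.8 mg/mL while raw fluorescence varies substantially."""
        raws, ifss = [], []
        for i, hb in enumerate((0.3, 1.0, 2.0, 3.8)):
            raw, ifs = _extract_phantom(PhantomSpec(1.0, hb, 0.5), 10 + i, lib, geom)
            raws.append(raw.intensities)
            ifss.append(ifs.intensities)
        raw_spread = max(relrms(raws[0], r) for r in raws[1:])
        ifs_spread = max(relrms(ifss[0], x) for x in ifss[1:])
        assert raw_spread > 0.20
        assert ifs_spread < 0.05

    def test_round_trip_through_fitted_drs(self, wl, lib, geom):
        """Noiseless forward -> DRS fit -> extraction recovers the intrinsic
        combination through the full estimation path."""
        rng = np.random.default_rng(17)
        for _ in range(20):
            from conftest import draw_params, make_props

            p = draw_params(rng)
            props = make_props(wl, lib, **p)
            w = {"collagen": rng.uniform(0.1, 3), "nadh": rng.uniform(0.1, 3)}
            raw = ts.fluorescence_forward(w, props, geom, lib=lib)
            fit = ts.fit_drs(ts.diffuse_reflectance(props, geom), lib, geom)
            out = ts.extract_intrinsic(raw, fit, geom, lib)
            truth = w["collagen"] * lib.emission("collagen", wl) + w["nadh"] * lib.emission("nadh", wl)
            assert relrms(out.intensities, truth) < 1e-4

    def test_failed_drs_fit_raises_extraction_error(self, wl, lib, geom):
        raw = Spectrum(wl, np.ones_like(wl), modality="FLUOR_RAW")
        bad = ts.fit_drs(Spectrum(wl, np.zeros_like(wl)), lib, geom)
        with pytest.raises(ExtractionError):
            ts.extract_intrinsic(raw, bad, geom, lib)


class TestNNLSDecompose:
    def test_exact_combination_recovered(self, wl, lib):
        y = 2.0 * lib.emission("collagen", wl) + 0.0 * lib.emission("nadh", wl)
        res = ts.nnls_decompose(Spectrum(wl, y, modality="IFS"), lib, ["collagen", "nadh"])
        assert res.coefficients["collagen"] == pytest.approx(2.0, abs=1e-10)
        assert res.coefficients["nadh"] == pytest.approx(0.0, abs=1e-10)
        assert res.residual_rms <= 1e-10

    def test_unphysical_negative_input_clamped(self, wl, lib):
        y = -1.0 * lib.emission("collagen", wl)
        res = ts.nnls_decompose(Spectrum(wl, y, modality="IFS"), lib, ["collagen"])
        assert res.coefficients["collagen"] == 0.0
        assert res.residual_rms > 0.001

    def test_noisy_random_combos_coefficient_rmse_under_2_percent(self, wl, lib):
        rng = np.random.default_rng(7)
        errs = []
        scale = 1.0
        for _ in range(100):
            w = rng.uniform(0.0, 2.0 * scale, size=2)
            y = w[0] * lib.emission("collagen", wl) + w[1] * lib.emission("nadh", wl)
            y = y * (1.0 + 0.005 * rng.standard_normal(y.shape))
            res = ts.nnls_decompose(Spectrum(wl, np.maximum(y, 0), modality="IFS"), lib, ["collagen", "nadh"])
            errs.extend([res.coefficients["collagen"] - w[0], res.coefficients["nadh"] - w[1]])
        rmse = np.sqrt(np.mean(np.square(errs)))
        assert rmse < 0.02 * (2.0 * scale)

    def test_rank_deficient_basis_flagged(self, wl, lib):
        dup = lib.with_emitters({"collagen2": (wl, lib.emission("collagen", wl))})
        y = lib.emission("collagen", wl)
        res = ts.nnls_decompose(Spectrum(wl, y, modality="IFS"), dup, ["collagen", "collagen2"])
        assert res.rank_deficient
        assert res.residual_rms <= 1e-10


def _unit(y, wl):
    return y / np.trapezoid(y, wl)


class TestMCR:
    def _separated_shapes(self, wl):
        return np.vstack(
            [
                _unit(np.exp(-0.5 * ((wl - 410) / 15.0) ** 2), wl),
                _unit(np.exp(-0.5 * ((wl - 560) / 25.0) ** 2), wl),
            ]
        )

    def test_recovers_known_shapes_with_ample_mixing(self, wl):
        S = self._separated_shapes(wl)
        rng = np.random.default_rng(0)
        W = rng.uniform(0.1, 2.0, size=(30, 2))
        W[0], W[1] = [2.0, 0.0], [0.0, 2.0]  # pure samples
        X = W @ S
        res = derive_basis_mcr([Spectrum(wl, x, modality="IFS") for x in X], 2)
        err = min(
            max(
                np.linalg.norm(res.shapes[list(p)][i] - S[i]) / np.linalg.norm(S[i])
                for i in range(2)
            )
            for p in itertools.permutations(range(2))
        )
        assert err < 0.02

    def test_single_component_proportional_spectra_exact(self, wl):
        S = self._separated_shapes(wl)[0]
        train = [Spectrum(wl, a * S, modality="IFS") for a in (0.5, 1.0, 2.0)]
        res = derive_basis_mcr(train, 1)
        assert np.allclose(res.shapes[0], S, atol=1e-12)

    def test_overcomplete_basis_converges_with_tiny_residual(self, wl):
        S = self._separated_shapes(wl)
        rng = np.random.default_rng(1)
        X = rng.uniform(0.1, 2.0, size=(20, 2)) @ S
        res = derive_basis_mcr([Spectrum(wl, x, modality="IFS") for x in X], 3)
        assert res.objective_history[-1] <= 1e-10 * np.sum(X**2)

    def test_objective_non_increasing(self, wl):
        S = self._separated_shapes(wl)
        rng = np.random.default_rng(2)
        X = rng.uniform(0.1, 2.0, size=(25, 2)) @ S
        X = X * (1.0 + 0.01 * rng.standard_normal(X.shape))
        res = derive_basis_mcr([Spectrum(wl, np.maximum(x, 0), modality="IFS") for x in X], 2)
        assert np.all(np.diff(res.objective_history) <= 1e-12)

    def test_too_few_training_spectra_rejected(self, wl):
        with pytest.raises(ValueError):
            derive_basis_mcr([Spectrum(wl, np.ones_like(wl), modality="IFS")], 2)
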