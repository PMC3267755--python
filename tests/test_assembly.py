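"""Cube assembly, co-registration, maps, edge response and diagnosis."""

import numpy as np
import pytest

import tissuescan as ts
from tissuescan.assembly import (
    EdgeAmbiguityError,
    PlacementError,
    RegistrationError,
    HyperCube,
    read_cubes_h5,
    registration_shift_pixels,
    tissue_mask_from_cube,
    write_cubes_h5,
)
from tissuescan.spectral import Spectrum

WL3 = np.array([400.0, 500.0, 600.0])


def px(x, y, vals, modality="DRS"):
    return (x, y, Spectrum(WL3, np.asarray(vals, float), modality=modality))


def grid_pixels(rows, cols, pitch=0.5, fn=None, x0=0.0, y0=0.0):
    out = []
    for r in range(rows):
        for c in range(cols):
            v = fn(r, c) if fn else [1.0, 2.0, 3.0]
            out.append(px(x0 + (c + 0.5) * pitch, y0 + (r + 0.5) * pitch, v))
    return out


class TestAssembleCube:
    def test_complete_grid(self):
        cube = ts.assemble_cube(grid_pixels(2, 2), 0.5)
        assert cube.shape == (2, 2)
        assert cube.valid.all()

    def test_missing_pixel_masked(self):
        pixels = grid_pixels(2, 2)[:-1]
        cube = ts.assemble_cube(pixels, 0.5)
        assert cube.shape == (2, 2)
        assert not cube.valid[1, 1]
        assert cube.valid.sum() == 3

    def test_serpentine_equals_raster_order(self):
        pixels = grid_pixels(3, 4, fn=lambda r, c: [r, c, r * c])
        serp = []
        for r in range(3):
            row = [p for p in pixels if round(p[1] / 0.5 - 0.5) == r]
            serp.extend(row if r % 2 == 0 else row[::-1])
        a = ts.assemble_cube(pixels, 0.5)
        b = ts.assemble_cube(serp, 0.5)
        assert np.array_equal(a.data, b.data)
        assert np.array_equal(a.valid, b.valid)

    def test_off_grid_position_rejected(self):
        pixels = grid_pixels(2, 2) + [px(1.9, 0.25, [0, 0, 0])]
        with pytest.raises(PlacementError, match="off the"):
            ts.assemble_cube(pixels, 0.5)

    def test_duplicate_position_rejected(self):
        pixels = grid_pixels(2, 2) + [px(0.25, 0.25, [9, 9, 9])]
        with pytest.raises(PlacementError, match="duplicate"):
            ts.assemble_cube(pixels, 0.5)


class TestCoregister:
    def test_shift_arithmetic(self):
        assert registration_shift_pixels(7.5, 0.25) == 30
        assert registration_shift_pixels(7.5, 0.5) == 15
        assert registration_shift_pixels(0.0, 0.25) == 0

    def test_non_integer_shift_rejected(self):
        with pytest.raises(RegistrationError, match="resample"):
            registration_shift_pixels(7.5, 1.0)

    def test_zero_offset_identity(self):
        drs = ts.assemble_cube(grid_pixels(3, 3, fn=lambda r, c: [r, c, 0]), 0.5)
        ifs = ts.assemble_cube(grid_pixels(3, 3, fn=lambda r, c: [c, r, 1]), 0.5)
        a, b = ts.coregister(drs, ifs)
        assert np.array_equal(a.data, drs.data)
        assert np.array_equal(b.data, ifs.data)

    def test_offset_cubes_align_exactly(self):
        """Fluorescence recorded 7.5 mm downstream of DRS realigns onto the
        same tissue pixels, spectra untouched (no interpolation)."""
        fn = lambda r, c: [r + 10 * c, r, c]
        drs = ts.assemble_cube(grid_pixels(4, 4, fn=fn), 0.5)
        ifs = ts.assemble_cube(
            grid_pixels(4, 4, fn=fn, x0=7.5), 0.5, probe_offset_mm=(7.5, 0.0)
        )
        a, b = ts.coregister(drs, ifs)
        assert a.shape == b.shape == (4, 4)
        assert np.array_equal(a.data, b.data)  # same tissue values
        assert b.probe_offset_mm == (0.0, 0.0)

    def test_involution_recovers_overlap(self):
        fn = lambda r, c: [r, c, r + c]
        drs = ts.assemble_cube(grid_pixels(4, 4, fn=fn), 0.5)
        ifs = ts.assemble_cube(grid_pixels(4, 4, fn=fn, x0=1.0), 0.5, probe_offset_mm=(1.0, 0.0))
        a, b = ts.coregister(drs, ifs)
        assert np.array_equal(a.data, b.data)
        # registering the already-registered pair changes nothing
        a2, b2 = ts.coregister(a, b)
        assert np.array_equal(a2.data, a.data) and np.array_equal(b2.data, b.data)

    def test_mismatched_pitch_rejected(self):
        drs = ts.assemble_cube(grid_pixels(2, 2), 0.5)
        ifs = ts.assemble_cube(grid_pixels(2, 2, pitch=0.25), 0.25)
        with pytest.raises(RegistrationError):
            ts.coregister(drs, ifs)


class TestSpectralSlice:
    def test_constant_cube_constant_image(self):
        cube = ts.assemble_cube(grid_pixels(3, 3), 0.5)
        img = ts.spectral_slice(cube, 500.0)
        assert np.all(img.values == 2.0)

    def test_nearest_channel_selection(self):
        cube = ts.assemble_cube(grid_pixels(2, 2, fn=lambda r, c: [1, 5, 9]), 0.5)
        img = ts.spectral_slice(cube, 489.3)  # nearest channel is 500 here
        assert np.all(img.values == 5.0)
        assert "500" in img.name

    def test_out_of_band_rejected(self):
        cube = ts.assemble_cube(grid_pixels(2, 2), 0.5)
        with pytest.raises(ValueError):
            ts.spectral_slice(cube, 900.0)


class TestEdgeResponse:
    def test_ideal_step_bounded_by_sampling_pitch(self):
        x = np.arange(0, 10, 0.05)
        y = np.where(x >= 5.0, 1.0, 0.0)
        assert ts.edge_response(x, y) <= 0.05 + 1e-12

    def test_gaussian_blurred_step_matches_2p563_sigma(self):
        from scipy.stats import norm

        sigma = 0.0975
        x = np.arange(0, 10, 0.005)
        y = norm.cdf((x - 5.0) / sigma)
        assert ts.edge_response(x, y) == pytest.approx(2.5631 * sigma, rel=0.02)

    def test_scale_invariance(self):
        from scipy.stats import norm

        x = np.arange(0, 10, 0.01)
        y = norm.cdf((x - 5.0) / 0.2)
        assert ts.edge_response(x, 7.3 * y) == pytest.approx(ts.edge_response(x, y), rel=1e-12)

    def test_multi_edge_profile_rejected(self):
        x = np.arange(0, 10, 0.01)
        y = np.where((x > 3) & (x < 6), 1.0, 0.0)  # up then down
        with pytest.raises(EdgeAmbiguityError):
            ts.edge_response(x, y)


class TestDecisionModel:
    def _clouds(self, n=300, seed=0):
        rng = np.random.default_rng(seed)
        normal = rng.normal([0.25, 0.8], [0.04, 0.15], size=(n, 2))
        cancer = rng.normal([0.10, 2.0], [0.03, 0.30], size=(n, 2))
        X = np.vstack([normal, cancer])
        y = np.r_[np.zeros(n), np.ones(n)]
        return X, y

    def test_separated_clouds_high_accuracy(self):
        X, y = self._clouds()
        m = ts.train_decision_model(X, y)
        assert np.mean(m.predict(X) == y) >= 0.99

    def test_label_flip_flips_signs_only(self):
        X, y = self._clouds()
        m1 = ts.train_decision_model(X, y)
        m2 = ts.train_decision_model(X, 1 - y)
        assert np.allclose(m1.coef, -m2.coef, atol=1e-5)
        assert m1.intercept == pytest.approx(-m2.intercept, abs=1e-5)

    def test_duplicated_dataset_identical_model(self):
        X, y = self._clouds()
        m1 = ts.train_decision_model(X, y)
        m2 = ts.train_decision_model(np.vstack([X, X]), np.r_[y, y])
        assert np.allclose(m1.coef, m2.coef, atol=1e-8)
        assert m1.intercept == pytest.approx(m2.intercept, abs=1e-8)

    def test_single_class_rejected(self):
        X, y = self._clouds()
        with pytest.raises(ValueError):
            ts.train_decision_model(X, np.zeros_like(y))

    def test_perfect_separation_flagged_and_finite(self):
        X = np.array([[0.0, 0.0], [0.1, 0.1], [1.0, 1.0], [1.1, 1.1]])
        y = np.array([0, 0, 1, 1])
        m = ts.train_decision_model(X, y)
        assert m.separable
        assert np.all(np.isfinite(m.coef))


class TestClassifyPixels:
    def _maps_from(self, bcar, coll, mask=None):
        bcar, coll = np.asarray(bcar, float), np.asarray(coll, float)
        m = np.ones(bcar.shape, bool) if mask is None else mask
        return {
            "c_bcar": ts.ParameterMap("c_bcar", bcar, m),
            "collagen": ts.ParameterMap("collagen", coll, m),
        }

    def _model(self):
        rng = np.random.default_rng(3)
        X = np.vstack(
            [rng.normal([0.25, 0.8], 0.03, (200, 2)), rng.normal([0.10, 2.0], 0.05, (200, 2))]
        )
        y = np.r_[np.zeros(200), np.ones(200)]
        return ts.train_decision_model(X, y)

    def test_class_means_labeled_accordingly(self):
        model = self._model()
        maps = self._maps_from([[0.25, 0.10]], [[0.8, 2.0]])
        diag = ts.classify_pixels(maps, model)
        assert diag.labels[0, 0] == 0  # normal
        assert diag.labels[0, 1] == 1  # cancer

    def test_empty_tissue_mask_all_non_tissue(self):
        model = self._model()
        maps = self._maps_from(np.full((3, 3), 0.25), np.full((3, 3), 0.8))
        diag = ts.classify_pixels(maps, model, tissue_mask=np.zeros((3, 3), bool))
        assert np.all(diag.labels == 2)

    def test_missing_feature_map_rejected(self):
        model = self._model()
        with pytest.raises(KeyError):
            ts.classify_pixels({"c_bcar": ts.ParameterMap("c_bcar", np.ones((2, 2)), np.ones((2, 2), bool))}, model)

    def test_masked_pixels_survive_as_non_tissue(self):
        model = self._model()
        mask = np.array([[True, False]])
        maps = self._maps_from([[0.25, 0.25]], [[0.8, 0.8]], mask)
        diag = ts.classify_pixels(maps, model)
        assert diag.labels[0, 0] == 0 and diag.labels[0, 1] == 2


class TestParameterMaps:
    def test_uniform_scan_gives_spatially_constant_maps(self, lib, geom):
        from tissuescan.simulate import TissueScanSpec, NoiseModel, simulate_tissue_scan

        dists = {
            cls: {k: (v[0], 0.0) for k, v in d.items()}
            for cls, d in ts.simulate.DEFAULT_CLASS_DISTRIBUTIONS.items()
        }
        spec = TissueScanSpec(
            width_mm=4.0, height_mm=2.0, pitch_mm=0.5, probe_offset_mm=(2.0, 0.0),
            foci_mm=(), class_distributions=dists, noise=NoiseModel(0, 0, 0), seed=0,
        )
        scan = simulate_tissue_scan(spec, lib, geom)
        drs = ts.assemble_cube(scan.drs_pixels, 0.5)
        ifs = ts.assemble_cube(scan.ifs_pixels, 0.5, probe_offset_mm=(2.0, 0.0))
        drs, ifs = ts.coregister(drs, ifs)
        maps = ts.parameter_maps(drs, ifs, lib, geom)
        lab = scan.truth_labels
        for name, pm in maps.items():
            for code, cls in ((0, "normal"), (1, "cancer")):
                vals = pm.values[(lab == code) & pm.mask]
                assert vals.std() / vals.mean() < 0.01
                assert vals.mean() == pytest.approx(dists[cls][name][0], rel=0.02)

    def test_masked_input_pixels_masked_in_all_maps(self, lib, geom):
        from conftest import make_props

        wl = ts.WavelengthGrid().wavelengths
        props = make_props(wl, lib)
        drs_s = ts.diffuse_reflectance(props, geom)
        fl_s = ts.fluorescence_forward({"collagen": 1.0, "nadh": 0.5}, props, geom, lib=lib)
        pix_d, pix_f = [], []
        for r in range(2):
            for c in range(2):
                if (r, c) == (1, 1):
                    continue
                pix_d.append((0.25 + 0.5 * c, 0.25 + 0.5 * r, drs_s))
                pix_f.append((0.25 + 0.5 * c, 0.25 + 0.5 * r, fl_s))
        drs = ts.assemble_cube(pix_d, 0.5)
        ifs = ts.assemble_cube(pix_f, 0.5)
        maps = ts.parameter_maps(drs, ifs, lib, geom)
        for pm in maps.values():
            assert not pm.mask[1, 1]
            assert pm.mask.sum() == 3


class TestRendering:
    def _maps(self):
        v = np.linspace(0, 1, 12).reshape(3, 4)
        return {"A": ts.ParameterMap("A", v, np.ones((3, 4), bool))}

    def test_rendered_dimensions_and_determinism(self, tmp_path):
        import imageio.v3 as iio

        p1 = ts.render_maps(self._maps(), tmp_path / "a")[0]
        p2 = ts.render_maps(self._maps(), tmp_path / "b")[0]
        img = iio.imread(p1)
        assert img.ndim == 3 and img.shape[0] > 0
        assert p1.read_bytes() == p2.read_bytes()

    def test_diagnostic_map_has_three_label_codes(self, tmp_path):
        labels = np.array([[0, 1], [2, 1]], dtype=np.int8)
        model = TestClassifyPixels()._model()
        diag = ts.DiagnosticMap(labels=labels, model=model)
        paths = ts.render_maps(diag, tmp_path)
        assert paths[0].exists()
        assert set(np.unique(labels)) == {0, 1, 2}
        assert set(diag.label_names().ravel()) == {"normal", "cancer", "non_tissue"}


class TestCubeIO:
    def test_h5_round_trip(self, tmp_path):
        drs = ts.assemble_cube(grid_pixels(3, 4, fn=lambda r, c: [r, c, r + c]), 0.5)
        ifs = ts.assemble_cube(
            grid_pixels(3, 4, fn=lambda r, c: [c, r, r * c], x0=7.5), 0.5, probe_offset_mm=(7.5, 0.0)
        )
        path = tmp_path / "cubes.h5"
        write_cubes_h5(path, drs, ifs)
        d2, i2 = read_cubes_h5(path)
        assert np.array_equal(d2.data, drs.data)
        assert np.array_equal(i2.data, ifs.data)
        assert d2.pixel_pitch_mm == 0.5
        assert tuple(i2.probe_offset_mm) == (7.5, 0.0)


def test_tissue_mask_threshold():
    data = np.zeros((2, 2, 3))
    data[0, 0] = 0.15   # bright tissue
    data[0, 1] = 0.002  # below 5% of the 0.2 standard
    data[1] = 0.05
    cube = HyperCube(data=data, wavelengths_nm=WL3, pixel_pitch_mm=0.5)
    mask = tissue_mask_from_cube(cube)
    assert mask[0, 0] and not mask[0, 1]
    assert mask[1].all()
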