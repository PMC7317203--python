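"""Preprocessing chain: calibration, subsetting, NDVI masking, averaging,
binning, derivative."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import nightscan as ns
from nightscan import preprocess as pp
from nightscan import synth_scene as sc


def make_cube(values, centers=None, white=None, mask=None, calibrated=False):
    values = np.asarray(values, dtype=float)
    n_bands = values.shape[2]
    if centers is None:
        centers = np.linspace(619.5, 983.0, n_bands)
    if white is None:
        white = np.ones(n_bands)
    if mask is None:
        mask = np.ones(values.shape[:2], dtype=int)
    return sc.SpectralCube(
        values=values,
        grid=sc.WavelengthGrid(np.asarray(centers, dtype=float)),
        white_reference=np.asarray(white, dtype=float),
        truth_mask=np.asarray(mask),
        calibrated=calibrated,
    )


def profile_frame(spectra, centers):
    rows = {f"b{c:.2f}": np.asarray(spectra, dtype=float)[:, i]
            for i, c in enumerate(centers)}
    frame = pd.DataFrame(rows)
    frame.insert(0, "plant_id", np.arange(1, len(frame) + 1))
    return frame


class TestCalibrate:
    def test_ratio(self):
        cube = make_cube(np.full((1, 1, 3), 0.5), white=[1.0, 1.0, 1.0])
        assert np.allclose(pp.calibrate(cube).values, 0.5)

    def test_raw_equal_to_white_gives_flat_unity(self):
        white = np.array([3.0, 7.0, 11.0])
        cube = make_cube(np.broadcast_to(white, (2, 2, 3)).copy(), white=white)
        assert np.allclose(pp.calibrate(cube).values, 1.0)

    def test_nonpositive_white_reference_names_band(self):
        with pytest.raises(ValueError, match="band 1"):
            make_cube(np.ones((1, 1, 3)), white=[1.0, 0.0, 1.0])

    def test_out_of_range_values_clipped_with_warning(self):
        cube = make_cube(np.full((1, 1, 3), 4.0), white=[2.0, 1.0, 2.0])
        with pytest.warns(UserWarning, match="clipped"):
            refl = pp.calibrate(cube)
        assert refl.values.max() == pp.CALIBRATION_CLIP[1]

    def test_double_calibration_rejected(self):
        cube = make_cube(np.ones((1, 1, 3)))
        with pytest.raises(ValueError, match="already"):
            pp.calibrate(pp.calibrate(cube))


class TestSubsetBands:
    def test_default_window_keeps_93_of_116_bands(self):
        cube = make_cube(np.ones((1, 1, 116)), centers=sc.default_grid().centers)
        assert pp.subset_bands(cube).values.shape[2] == 93

    def test_full_window_is_identity(self):
        frame = profile_frame(np.arange(12.0).reshape(2, 6), np.linspace(500, 900, 6))
        out = pp.subset_bands(frame, 400, 1000)
        pd.testing.assert_frame_equal(out, frame)

    def test_degenerate_window_keeps_single_band(self):
        cube = make_cube(np.ones((1, 1, 116)), centers=sc.default_grid().centers)
        assert pp.subset_bands(cube, 983.0, 983.0).values.shape[2] == 1

    def test_empty_subset_is_error(self):
        frame = profile_frame(np.ones((1, 4)), [700, 710, 720, 730])
        with pytest.raises(ValueError, match="empty"):
            pp.subset_bands(frame, 100, 200)


class TestNdvi:
    def test_closed_form(self):
        assert pp.ndvi(np.array([[0.05, 0.45]]), 0, 1) == pytest.approx(0.8)

    def test_equal_bands_give_zero(self):
        assert pp.ndvi(np.array([[0.3, 0.3]]), 0, 1) == pytest.approx(0.0)

    def test_zero_denominator_is_nan(self):
        assert np.isnan(pp.ndvi(np.array([[0.0, 0.0]]), 0, 1))

    def test_soil_preset_falls_below_spinach_threshold(self):
        cfg = ns.SceneConfig(crop="spinach")
        soil = sc.soil_spectrum(cfg)
        red_i, nir_i = pp.ndvi_band_indices(sc.default_grid())
        assert pp.ndvi(soil, red_i, nir_i) < 0.54


class TestMaskPixels:
    def _cube_with_ndvi(self, ndvi_values, crop_centers=True):
        """One plant; each pixel engineered to a requested NDVI value."""
        centers = sc.default_grid().centers
        red_i, nir_i = pp.ndvi_band_indices(sc.WavelengthGrid(centers))
        pixels = []
        for v in ndvi_values:
            spec = np.full(len(centers), 0.2)
            red = 0.2
            spec[nir_i] = red * (1 + v) / (1 - v)
            pixels.append(spec)
        values = np.asarray(pixels)[None, :, :]
        mask = np.ones((1, len(ndvi_values)), dtype=int)
        return make_cube(values, centers=centers, mask=mask, calibrated=True)

    def test_spinach_boundary_value_excluded_strictly(self):
        cube = self._cube_with_ndvi([0.54, 0.60])
        retained = pp.mask_pixels(cube, "spinach")
        assert len(retained[1][0]) == 1   # only the interior pixel

    def test_bok_choy_interior_point_retained(self):
        cube = self._cube_with_ndvi([0.60])
        assert len(pp.mask_pixels(cube, "bok_choy")[1][0]) == 1

    def test_plant_with_no_valid_pixels_dropped_with_warning(self):
        cube = self._cube_with_ndvi([0.1, 0.2])
        with pytest.warns(UserWarning, match="no pixels"):
            retained = pp.mask_pixels(cube, "bok_choy")
        assert retained == {}

    def test_unknown_crop_rejected(self):
        cube = self._cube_with_ndvi([0.6])
        with pytest.raises(ValueError, match="crop"):
            pp.mask_pixels(cube, "lettuce")

    def test_default_scene_retains_exactly_the_true_plants(self, tiny_config):
        cubes, labels = ns.simulate_dataset(tiny_config, emit="cubes")
        refl = pp.calibrate(cubes[1])
        retained = pp.mask_pixels(refl, "bok_choy")
        truth = {l.plant_id for l in labels if l.series == 1}
        assert set(retained) == truth
        for pid, idx in retained.items():
            assert np.all(refl.truth_mask[idx] == pid)
            assert len(idx[0]) <= tiny_config.pixels_per_plant


class TestAverageProfiles:
    def test_identical_pixels_average_to_that_spectrum(self):
        spec = np.linspace(0.1, 0.5, 5)
        cube = make_cube(np.broadcast_to(spec, (1, 3, 5)).copy(), calibrated=True)
        out = pp.average_profiles(cube, {1: (np.zeros(3, int), np.arange(3))})
        band_cols = [c for c in out.columns if c.startswith("b")]
        assert np.allclose(out[band_cols].to_numpy()[0], spec)
        assert out.n_pixels.iloc[0] == 3

    def test_two_pixels_average_to_midpoint(self):
        values = np.array([[[0.2, 0.4], [0.4, 0.8]]])
        cube = make_cube(values, centers=[700.0, 710.0], calibrated=True)
        out = pp.average_profiles(cube, {1: (np.zeros(2, int), np.arange(2))})
        assert np.allclose(out[["b700.00", "b710.00"]].to_numpy()[0], [0.3, 0.6])


class TestBinSpectra:
    def test_93_bands_bin_to_31(self):
        centers = np.linspace(619.5, 983.0, 93)
        frame = profile_frame(np.random.default_rng(0).random((2, 93)), centers)
        out = pp.bin_spectra(frame)
        assert len([c for c in out.columns if c.startswith("b")]) == 31

    def test_simple_arithmetic(self):
        frame = profile_frame([[1, 2, 3, 4, 5, 6]], [1, 2, 3, 4, 5, 6])
        out = pp.bin_spectra(frame, factor=3)
        cols = [c for c in out.columns if c.startswith("b")]
        assert np.allclose(out[cols].to_numpy()[0], [2.0, 5.0])
        assert cols == ["b2.00", "b5.00"]

    def test_constant_spectrum_unchanged(self):
        frame = profile_frame(np.full((1, 6), 0.7), np.arange(6) + 700.0)
        out = pp.bin_spectra(frame, factor=3)
        cols = [c for c in out.columns if c.startswith("b")]
        assert np.allclose(out[cols], 0.7)

    def test_partial_bins_rejected(self):
        frame = profile_frame(np.ones((1, 7)), np.arange(7) + 700.0)
        with pytest.raises(ValueError, match="divisible"):
            pp.bin_spectra(frame, factor=3)

    @settings(derandomize=True, max_examples=25)
    @given(st.integers(1, 10), st.integers(1, 4))
    def test_equal_bins_conserve_the_global_mean(self, n_bins, factor):
        rng = np.random.default_rng(n_bins * 7 + factor)
        spectra = rng.random((3, n_bins * factor))
        frame = profile_frame(spectra, np.arange(n_bins * factor) + 500.0)
        out = pp.bin_spectra(frame, factor=factor)
        cols = [c for c in out.columns if c.startswith("b")]
        assert np.allclose(out[cols].mean(axis=1), spectra.mean(axis=1))


class TestFirstDerivative:
    def test_constant_profile_gives_zero(self):
        frame = profile_frame(np.full((2, 5), 0.3), np.arange(5) * 10.0 + 700)
        out = pp.first_derivative(frame)
        cols = [c for c in out.columns if c.startswith("d")]
        assert np.allclose(out[cols], 0.0)

    def test_linear_profile_gives_constant_slope(self):
        centers = np.array([700.0, 705.0, 712.0, 720.0])   # uneven spacing
        slope = 0.004
        frame = profile_frame([10 + slope * centers], centers)
        out = pp.first_derivative(frame)
        cols = [c for c in out.columns if c.startswith("d")]
        assert np.allclose(out[cols], slope)

    def test_keep_length_repeats_last_difference(self):
        frame = profile_frame([[0.0, 1.0, 3.0]], [100.0, 101.0, 102.0])
        out = pp.first_derivative(frame)
        cols = [c for c in out.columns if c.startswith("d")]
        assert len(cols) == 3
        assert np.allclose(out[cols].to_numpy()[0], [1.0, 2.0, 2.0])
        short = pp.first_derivative(frame, keep_length=False)
        assert len([c for c in short.columns if c.startswith("d")]) == 2

    def test_matches_independent_difference_quotient(self, bok_profiles):
        binned = pp.bin_spectra(pp.subset_bands(bok_profiles.head(5)))
        out = pp.first_derivative(binned, keep_length=False)
        cols = [c for c in binned.columns if c.startswith("b")]
        centers = pp.frame_grid(binned)
        # brute-force oracle: explicit loops over profiles and bands
        for i in range(len(binned)):
            for j in range(len(cols) - 1):
                expect = (
                    binned[cols[j + 1]].iloc[i] - binned[cols[j]].iloc[i]
                ) / (centers[j + 1] - centers[j])
                got = out[f"d{centers[j]:.2f}"].iloc[i]
                assert got == pytest.approx(expect, rel=1e-12)

    def test_duplicate_wavelengths_rejected(self):
        # duplicate band columns can arise from careless concatenation
        frame = pd.DataFrame(
            np.array([[1.0, 2.0, 3.0]]),
            columns=["b700.00", "b700.00", "b710.00"],
        )
        with pytest.raises(ValueError, match="duplicate"):
            pp.first_derivative(frame)

    def test_single_band_rejected(self):
        frame = profile_frame([[1.0]], [700.0])
        with pytest.raises(ValueError):
            pp.first_derivative(frame)


class TestFullChain:
    def test_cube_and_profile_paths_agree_without_noise(self):
        cfg = ns.SceneConfig(
            plants_per_cell={("late", "low", True): 2, ("late", "low", False): 2},
            pixels_per_plant=10,
            pixel_noise_sd=0.0,
            plant_sd=0.0,
            plant_edge_sd_nm=0.0,
            infestation_escape_rate=0.0,
            seed=9,
        )
        profiles, labels = ns.simulate_dataset(cfg)
        direct = pp.profiles_to_derivatives(profiles)
        cubes, _ = ns.simulate_dataset(cfg, emit="cubes")
        via_cube = pd.concat(
            [
                pp.cube_to_derivatives(cubes[s], "bok_choy",
                                       [l for l in labels if l.series == s])
                for s in (1, 2)
            ],
            ignore_index=True,
        )
        d_cols = [c for c in direct.columns if c.startswith("d")]
        a = direct.sort_values("plant_id")[d_cols].to_numpy()
        b = via_cube.sort_values("plant_id")[d_cols].to_numpy()
        assert np.allclose(a, b, atol=1e-9)
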