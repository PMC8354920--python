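import numpy as np
import pytest

from inkdose import errors
from inkdose.spectra_core import (
    ABSORBANCE,
    HyperspectralCube,
    ReferencePair,
    RegionOfInterest,
    compute_absorbance,
    extract_roi,
    invert_absorbance,
    peak_intensity_image,
    restrict_wavelengths,
)


class TestComputeAbsorbance:
    def test_white_sample_gives_zero_absorbance(self, small_grid, small_refs):
        cube = HyperspectralCube(
            np.tile(small_refs.white[0], (3, 5, 1)), small_grid
        )
        out = compute_absorbance(cube, small_refs)
        assert out.mode == ABSORBANCE
        np.testing.assert_allclose(out.data, 0.0, atol=1e-12)

    def test_decade_ratio_gives_unit_absorbance(self, small_grid, small_refs):
        white, black = small_refs.white[0], small_refs.black[0]
        counts = black + 0.1 * (white - black)
        cube = HyperspectralCube(np.tile(counts, (2, 3, 1)), small_grid)
        out = compute_absorbance(cube, small_refs)
        np.testing.assert_allclose(out.data, 1.0, rtol=1e-12)

    def test_matches_scalar_loop_oracle(self, raw_cube, small_refs):
        out = compute_absorbance(raw_cube, small_refs)
        white, black = small_refs.white[0], small_refs.black[0]
        for f in range(raw_cube.n_frames):
            for s in range(raw_cube.n_spatial):
                for w in range(raw_cube.n_wavelengths):
                    expected = -np.log10(
                        (raw_cube.data[f, s, w] - black[w])
                        / (white[w] - black[w])
                    )
                    assert out.data[f, s, w] == pytest.approx(expected, rel=1e-12)

    def test_inverse_transform_recovers_counts(self, raw_cube, small_refs):
        out = compute_absorbance(raw_cube, small_refs)
        back = invert_absorbance(out, small_refs)
        np.testing.assert_allclose(back.data, raw_cube.data, rtol=1e-10)

    def test_invalid_reference_rejected(self, raw_cube, small_grid):
        bad = ReferencePair(
            white=np.full(small_grid.size, 100.0),
            black=np.full(small_grid.size, 100.0),
        )
        with pytest.raises(errors.InvalidReferenceError):
            compute_absorbance(raw_cube, bad)

    def test_axis_mismatch_rejected(self, raw_cube):
        refs = ReferencePair(white=np.full(7, 2.0), black=np.full(7, 1.0))
        with pytest.raises(errors.DimensionError):
            compute_absorbance(raw_cube, refs)

    def test_ratio_floor_clips_and_logs(self, small_grid, small_refs):
        counts = np.tile(small_refs.black[0], (2, 2, 1))  # ratio 0 everywhere
        cube = HyperspectralCube(counts, small_grid)
        out = compute_absorbance(cube, small_refs)
        assert np.all(np.isfinite(out.data))
        assert out.meta["n_clipped"] == counts.size


class TestWavelengthSelection:
    def test_boundary_inclusion(self):
        grid = np.array([1000.0, 1200.0, 1400.0, 1600.0, 1700.0])
        cube = HyperspectralCube(np.zeros((2, 2, 5)), grid)
        out = restrict_wavelengths(cube, (1200, 1600))
        np.testing.assert_array_equal(out.wavelengths, [1200, 1400, 1600])

    def test_full_window_is_identity(self, raw_cube):
        out = restrict_wavelengths(raw_cube, (0, 1e4))
        np.testing.assert_array_equal(out.data, raw_cube.data)

    def test_disjoint_window_raises(self, raw_cube):
        with pytest.raises(errors.EmptySelectionError):
            restrict_wavelengths(raw_cube, (1710, 1720))


class TestExtractRoi:
    def test_full_extent_identity(self, raw_cube):
        roi = RegionOfInterest((0, raw_cube.n_frames), (0, raw_cube.n_spatial))
        out = extract_roi(raw_cube, roi)
        np.testing.assert_array_equal(out.data, raw_cube.data)

    def test_shape_arithmetic(self, raw_cube):
        out = extract_roi(raw_cube, RegionOfInterest((2, 4), (0, 3)))
        assert out.data.shape == (2, 3, raw_cube.n_wavelengths)

    def test_element_copy_oracle(self, raw_cube):
        out = extract_roi(raw_cube, RegionOfInterest((1, 3), (2, 5)))
        for f in range(2):
            for s in range(3):
                np.testing.assert_array_equal(
                    out.data[f, s], raw_cube.data[1 + f, 2 + s]
                )

    def test_out_of_bounds_raises(self, raw_cube):
        with pytest.raises(errors.BoundsError):
            extract_roi(raw_cube, RegionOfInterest((0, 99), (0, 2)))

    def test_commutes_with_restrict(self, raw_cube):
        roi = RegionOfInterest((1, 3), (1, 4))
        window = (1100, 1500)
        a = restrict_wavelengths(extract_roi(raw_cube, roi), window)
        b = extract_roi(restrict_wavelengths(raw_cube, window), roi)
        np.testing.assert_array_equal(a.data, b.data)
        np.testing.assert_array_equal(a.wavelengths, b.wavelengths)


class TestPeakIntensityImage:
    def test_exact_grid_wavelength(self, raw_cube, small_grid):
        img = peak_intensity_image(raw_cube, small_grid[3])
        np.testing.assert_array_equal(img, raw_cube.data[:, :, 3])

    def test_tie_breaks_toward_lower_wavelength(self, raw_cube, small_grid):
        mid = 0.5 * (small_grid[3] + small_grid[4])
        img = peak_intensity_image(raw_cube, mid)
        np.testing.assert_array_equal(img, raw_cube.data[:, :, 3])

    def test_outside_grid_raises(self, raw_cube):
        with pytest.raises(errors.RangeError):
            peak_intensity_image(raw_cube, 3000.0)

    def test_bright_spot_location(self, small_grid):
        data = np.zeros((6, 6, small_grid.size))
        data[4, 2, :] = 1.0
        cube = HyperspectralCube(data, small_grid, mode=ABSORBANCE)
        img = peak_intensity_image(cube, 1300.0)
        assert np.unravel_index(np.argmax(img), img.shape) == (4, 2)
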