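import numpy as np
import pytest

from inkdose import errors
from inkdose.calibration import band_integral_image
from inkdose.spectra_core import compute_absorbance
from inkdose.synthetic import (
    DepositionModel,
    OpticsConfig,
    PrintPattern,
    SpectralModel,
    blur_field,
    deposit_mass_field,
    reference_doses,
    render_cube,
    render_raman_map,
    resample_to_pixels,
)

SINGLE_DROP_MG = 415e-9 * 250.0  # 415 pl x 250 mg/ml


def _single_spot_pattern(n_drops=1):
    return PrintPattern(kind="calibration_strip", spots=(n_drops,))


class TestDepositMassField:
    def test_single_drop_mass_closure(self):
        dep = DepositionModel(drop_volume_sd_pl=0.0)
        field = deposit_mass_field(_single_spot_pattern(), dep, seed=0)
        assert field.total_mg == pytest.approx(SINGLE_DROP_MG, rel=1e-12)

    def test_two_layers_double_one_layer_without_volume_jitter(self):
        dep = DepositionModel(drop_volume_sd_pl=0.0)
        one = deposit_mass_field(
            PrintPattern(kind="multilayer_square", n_layers=1), dep, seed=3
        )
        two = deposit_mass_field(
            PrintPattern(kind="multilayer_square", n_layers=2), dep, seed=3
        )
        np.testing.assert_allclose(two.values, 2.0 * one.values, rtol=1e-12)

    def test_field_integral_equals_ground_truth_total(self):
        field = deposit_mass_field(
            PrintPattern(kind="calibration_strip"), DepositionModel(), seed=11
        )
        assert field.total_mg == pytest.approx(
            field.ground_truth["total_mg"], rel=1e-12
        )
        spot_sum = sum(s["mass_mg"] for s in field.ground_truth["spots"])
        assert field.total_mg == pytest.approx(spot_sum, rel=1e-12)

    def test_deterministic_given_seed(self):
        a = deposit_mass_field(_single_spot_pattern(50), seed=5)
        b = deposit_mass_field(_single_spot_pattern(50), seed=5)
        np.testing.assert_array_equal(a.values, b.values)

    def test_coffee_ring_moves_mass_off_centre_but_conserves_it(self):
        dep0 = DepositionModel(drop_volume_sd_pl=0.0, coffee_ring_fraction=0.0)
        dep1 = DepositionModel(drop_volume_sd_pl=0.0, coffee_ring_fraction=0.5)
        f0 = deposit_mass_field(_single_spot_pattern(), dep0, seed=0)
        f1 = deposit_mass_field(_single_spot_pattern(), dep1, seed=0)
        assert f1.total_mg == pytest.approx(f0.total_mg, rel=1e-12)
        assert f1.values.max() < f0.values.max()


class TestBlurAndResample:
    def test_mass_conserved_through_blur_and_pixel_binning(self):
        field = deposit_mass_field(
            PrintPattern(kind="multilayer_square", n_layers=2),
            DepositionModel(), seed=2,
        )
        blurred = blur_field(field, 154.0)
        assert blurred.sum() == pytest.approx(field.total_mg, rel=1e-9)
        pix = resample_to_pixels(blurred, field.cell_um, 50.0, 114.0)
        assert pix.sum() == pytest.approx(field.total_mg, rel=1e-9)

    def test_raster_coarser_than_pixels_rejected(self, rng):
        with pytest.raises(errors.DomainError):
            resample_to_pixels(rng.random((10, 10)), 100.0, 50.0, 114.0)


def _fast_smodel(**kw):
    """Spectral model on a short grid to keep render tests light."""
    return SpectralModel(wavelengths=np.arange(1200.0, 1601.0, 20.0), **kw)


class TestRenderCube:
    optics = OpticsConfig(frame_binning=28)

    def test_blank_field_recovers_substrate_endmember(self):
        field = deposit_mass_field(_single_spot_pattern(), seed=0)
        field.values[:] = 0.0
        smodel = _fast_smodel(noise_sd=0.0, scatter_range=(1.0, 1.0))
        raw, refs, _ = render_cube(field, self.optics, smodel, seed=0)
        acube = compute_absorbance(raw, refs)
        expected = np.broadcast_to(
            smodel.substrate_endmember, acube.data.shape
        )
        np.testing.assert_allclose(acube.data, expected, atol=1e-9)

    def test_api_absorbance_doubles_with_mass(self):
        from dataclasses import replace as dc_replace

        dep = DepositionModel(drop_volume_sd_pl=0.0)
        f1 = deposit_mass_field(_single_spot_pattern(200), dep, seed=0)
        f2 = dc_replace(f1, values=2.0 * f1.values)
        smodel = _fast_smodel(noise_sd=0.0, scatter_range=(1.0, 1.0))
        out = []
        for f in (f1, f2):
            raw, refs, _ = render_cube(f, self.optics, smodel, seed=0)
            acube = compute_absorbance(raw, refs)
            api = acube.data - smodel.substrate_endmember[None, None, :]
            out.append(api)
        np.testing.assert_allclose(out[1], 2.0 * out[0], atol=1e-9)

    def test_bit_identical_on_repeated_seed(self):
        field = deposit_mass_field(_single_spot_pattern(100), seed=1)
        smodel = _fast_smodel()
        a, _, _ = render_cube(field, self.optics, smodel, seed=42)
        b, _, _ = render_cube(field, self.optics, smodel, seed=42)
        np.testing.assert_array_equal(a.data, b.data)

    def test_pixel_truth_total_matches_deposit(self):
        field = deposit_mass_field(_single_spot_pattern(300), seed=4)
        raw, refs, truth = render_cube(field, self.optics, _fast_smodel(),
                                       seed=4)
        assert truth["total_mg"] == pytest.approx(field.total_mg, rel=1e-9)

    def test_frame_binning_reduces_noise_at_equal_pitch(self):
        field = deposit_mass_field(_single_spot_pattern(), seed=0)
        field.values[:] = 0.0
        smodel = _fast_smodel(noise_sd=0.01, scatter_range=(1.0, 1.0))
        sds = []
        # same 50.45 um working pitch: fast stage unbinned vs slow stage binned
        for optics in (
            OpticsConfig(stage_speed_um_s=200.0 * 28, frame_binning=1),
            OpticsConfig(stage_speed_um_s=200.0, frame_binning=28),
        ):
            raw, refs, _ = render_cube(field, optics, smodel, seed=3)
            acube = compute_absorbance(raw, refs)
            resid = acube.data - smodel.substrate_endmember[None, None, :]
            sds.append(resid.std())
        assert sds[1] == pytest.approx(sds[0] / np.sqrt(28.0), rel=0.15)


class TestRenderRamanMap:
    def test_zero_field_band_integrals_are_zero_mean(self):
        field = deposit_mass_field(_single_spot_pattern(), seed=0)
        field.values[:] = 0.0
        rmap = render_raman_map(field, seed=1, noise_sd=1.0)
        integrals = band_integral_image(rmap)
        assert abs(integrals.mean()) < 5.0 * integrals.std() / np.sqrt(
            integrals.size
        )

    def test_band_integral_proportional_to_local_mass(self):
        field = deposit_mass_field(_single_spot_pattern(100), seed=0)
        rmap = render_raman_map(field, seed=0, noise_sd=0.0,
                                sampling_sigma_um=0.0)
        integrals = band_integral_image(rmap)
        assert integrals.max() > 0
        # noiseless band integrals scale linearly with binned local mass:
        # ratios of integrals equal ratios of masses
        cell = field.cell_um

        def local_mass(idx):
            x, y = rmap.x_um[idx], rmap.y_um[idx]
            i0, i1 = int((x - 50) / cell), int((x + 50) / cell)
            j0, j1 = int((y - 50) / cell), int((y + 50) / cell)
            return field.values[i0:i1, j0:j1].sum()

        order = np.argsort(integrals)
        a, b = order[-1], order[-4]
        assert local_mass(b) > 0
        assert integrals[a] / integrals[b] == pytest.approx(
            local_mass(a) / local_mass(b), rel=0.02
        )

    def test_deterministic_given_seed(self):
        field = deposit_mass_field(_single_spot_pattern(100), seed=0)
        a = render_raman_map(field, seed=9)
        b = render_raman_map(field, seed=9)
        np.testing.assert_array_equal(a.intensities, b.intensities)


class TestReferenceDoses:
    truth = np.array([1e-3, 3e-3, 6e-3, 2e-2])

    def test_zero_error_returns_truth(self):
        values, _ = reference_doses(self.truth, 0.0, seed=0)
        np.testing.assert_array_equal(values, self.truth)

    def test_quantification_limit_flags_small_spots(self):
        _, quantifiable = reference_doses(self.truth, 0.0, seed=0,
                                          loq_mg=5e-3)
        np.testing.assert_array_equal(quantifiable, [False, False, True, True])

    def test_mean_of_many_draws_near_truth(self):
        draws = np.array([
            reference_doses(self.truth[-1:], 0.05, seed=s)[0][0]
            for s in range(1000)
        ])
        assert draws.mean() == pytest.approx(self.truth[-1], rel=0.01)
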