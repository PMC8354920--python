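import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from inkdose import errors
from inkdose.calibration import (
    RamanMap,
    cross_validate,
    assemble_training,
    fit_simpls,
    raman_band_integral,
    stratify_response,
)
from inkdose.spectra_core import ABSORBANCE, HyperspectralCube


def nipals_pls1(X, y, n_components):
    """Independent NIPALS PLS1 oracle (classic deflation form)."""
    Xd = X - X.mean(axis=0)
    yd = y - y.mean()
    W, P, Q = [], [], []
    for _ in range(n_components):
        w = Xd.T @ yd
        w = w / np.linalg.norm(w)
        t = Xd @ w
        tt = float(t @ t)
        p = Xd.T @ t / tt
        q = float(yd @ t) / tt
        Xd = Xd - np.outer(t, p)
        yd = yd - q * t
        W.append(w)
        P.append(p)
        Q.append(q)
    Wm, Pm, Qv = np.column_stack(W), np.column_stack(P), np.array(Q)
    return Wm @ np.linalg.solve(Pm.T @ Wm, Qv)


def _map_from_integrand(shift, spectra):
    spectra = np.asarray(spectra, dtype=float)
    return RamanMap(
        shift_axis=shift,
        intensities=spectra[None, :, :],
        x_um=np.zeros(spectra.shape[0]),
        y_um=np.zeros(spectra.shape[0]),
    )


class TestRamanBandIntegral:
    shift = np.arange(700.0, 771.0, 1.0)

    def test_zero_spectrum(self):
        assert raman_band_integral(self.shift, np.zeros_like(self.shift)) == 0.0

    def test_triangular_peak_area(self):
        # height 6 triangle spanning exactly the 730-740 band: area h*w/2
        y = np.clip(6.0 * (1.0 - np.abs(self.shift - 735.0) / 5.0), 0.0, None)
        area = raman_band_integral(self.shift, y, band=(730.0, 740.0))
        assert area == pytest.approx(6.0 * 10.0 / 2.0, rel=1e-12)

    def test_lorentzian_plus_baseline_vs_quadrature(self):
        # band wide relative to the linewidth so the edge chord removes
        # little of the true in-band area
        shift = np.arange(700.0, 770.0, 0.02)
        gamma = 0.3
        lorentz = (gamma / np.pi) / ((shift - 735.0) ** 2 + gamma**2)
        baseline = 3.0 + 0.05 * shift
        area = raman_band_integral(shift, lorentz + baseline,
                                   band=(725.0, 745.0))
        inband = (shift >= 725) & (shift <= 745)
        oracle = np.trapezoid(lorentz[inband], shift[inband])
        assert area == pytest.approx(oracle, rel=0.02)

    def test_band_outside_axis_rejected(self):
        with pytest.raises(errors.RangeError):
            raman_band_integral(self.shift, self.shift * 0.0, band=(100, 110))


def _impulse_map(integrals):
    """Raman map whose band integrals equal the requested values."""
    shift = np.arange(700.0, 771.0, 1.0)
    peak = np.clip(1.0 - np.abs(shift - 735.0) / 5.0, 0.0, None)
    peak = peak / np.trapezoid(peak, shift)
    spectra = np.outer(np.asarray(integrals, float), peak)
    return _map_from_integrand(shift, spectra)


class TestStratifyResponse:
    def test_single_stratum_uniform_allocation(self):
        resp = stratify_response(_impulse_map([5.0, 1.0, 3.0, 2.0]), 8.0, 1)
        np.testing.assert_allclose(resp.concentration, 2.0)

    def test_two_pixel_proportional_allocation(self):
        resp = stratify_response(_impulse_map([1.0, 3.0]), 4.0, 2)
        np.testing.assert_allclose(sorted(resp.concentration), [1.0, 3.0])

    def test_fine_limit_is_proportional(self):
        resp = stratify_response(_impulse_map([1.0, 2.0, 5.0]), 16.0, None)
        np.testing.assert_allclose(sorted(resp.concentration), [2.0, 4.0, 10.0])

    @settings(deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(0.0, 100.0), min_size=3, max_size=40).filter(
            lambda xs: sum(xs) > 1.0
        ),
        st.integers(1, 6),
        st.floats(0.1, 50.0),
    )
    def test_mass_closure_exact(self, integrals, n_strata, mass):
        resp = stratify_response(_impulse_map(integrals), mass, n_strata)
        assert resp.concentration.sum() == pytest.approx(mass, rel=1e-12)
        assert np.all(resp.concentration >= 0)

    def test_strata_partition_pixels(self):
        resp = stratify_response(_impulse_map(np.arange(1.0, 13.0)), 6.0, 3)
        assert set(resp.stratum_label) == {0, 1, 2}

    def test_all_zero_map_rejected(self):
        with pytest.raises(errors.NoSignalError):
            stratify_response(_impulse_map([0.0, 0.0]), 1.0, 2)


def _pcube(data, grid):
    return HyperspectralCube(data, grid, mode=ABSORBANCE)


class TestAssembleTraining:
    grid = np.linspace(1200, 1600, 9)

    def _spot(self, rng, n_pixels):
        cube = _pcube(rng.normal(size=(6, 6, self.grid.size)), self.grid)
        resp = stratify_response(
            _impulse_map(rng.uniform(1, 2, n_pixels)), 1.0, None,
            pixel_index=np.column_stack(
                [rng.integers(0, 6, n_pixels), rng.integers(0, 6, n_pixels)]
            ),
        )
        return cube, resp

    def test_shapes(self, rng):
        cube, resp = self._spot(rng, 4)
        X, y, excluded = assemble_training([cube], [resp])
        assert X.shape == (4, self.grid.size)
        assert y.shape == (4,)
        assert excluded == []

    def test_small_spots_excluded_by_drop_count(self, rng):
        pairs = [self._spot(rng, 3) for _ in range(4)]
        cubes = [p[0] for p in pairs]
        resps = [p[1] for p in pairs]
        X, y, excluded = assemble_training(cubes, resps, [10, 20, 30, 100])
        assert X.shape[0] == 3  # only the 100-drop spot contributes
        assert [e["n_drops"] for e in excluded] == [10, 20, 30]

    def test_row_permutation_equivariance(self, rng):
        cube, resp = self._spot(rng, 8)
        X1, y1, _ = assemble_training([cube], [resp])
        perm = rng.permutation(8)
        resp2 = type(resp)(
            pixel_index=resp.pixel_index[perm],
            concentration=resp.concentration[perm],
            stratum_label=resp.stratum_label[perm],
            spot_mass=resp.spot_mass,
        )
        X2, y2, _ = assemble_training([cube], [resp2])
        np.testing.assert_array_equal(X2, X1[perm])
        np.testing.assert_array_equal(y2, y1[perm])

    def test_bad_coordinates_rejected(self, rng):
        cube, resp = self._spot(rng, 4)
        resp.pixel_index[0] = (99, 0)
        with pytest.raises(errors.AlignmentError):
            assemble_training([cube], [resp])


class TestSimpls:
    def test_exact_linear_fit_at_full_rank(self, rng):
        X = rng.normal(size=(30, 6))
        y = X @ rng.normal(size=6) + 3.0
        model = fit_simpls(X, y, 6)
        np.testing.assert_allclose(model.predict(X), y, atol=1e-9)

    def test_univariate_reduces_to_least_squares_slope(self, rng):
        x = rng.normal(size=(25, 1))
        y = 2.0 + 0.7 * x[:, 0] + 0.05 * rng.normal(size=25)
        model = fit_simpls(x, y, 1)
        slope = np.polyfit(x[:, 0], y, 1)[0]
        assert model.beta_slope[0] == pytest.approx(slope, rel=1e-10)

    def test_first_component_matches_nipals_direction(self, rng):
        X = rng.normal(size=(40, 12))
        y = rng.normal(size=40)
        model = fit_simpls(X, y, 1)
        oracle = nipals_pls1(X, y, 1)
        a = model.beta_slope / np.linalg.norm(model.beta_slope)
        b = oracle / np.linalg.norm(oracle)
        np.testing.assert_allclose(a, np.sign(a @ b) * b, atol=1e-10)

    def test_beta_matches_nipals_at_any_depth(self, rng):
        X = rng.normal(size=(40, 10))
        y = rng.normal(size=40)
        for a in (2, 4, 7):
            model = fit_simpls(X, y, a)
            np.testing.assert_allclose(
                model.beta_slope, nipals_pls1(X, y, a), atol=1e-9
            )

    def test_beta_matches_sklearn_reference(self, rng):
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        X = rng.normal(size=(50, 15))
        y = X @ rng.normal(size=15) + rng.normal(size=50)
        for a in (1, 3, 5):
            model = fit_simpls(X, y, a)
            ref = sklearn.PLSRegression(n_components=a, scale=False).fit(
                X, y[:, None]
            )
            np.testing.assert_allclose(
                model.beta_slope, ref.coef_.ravel(), atol=1e-8
            )

    def test_scores_orthonormal(self, rng):
        X = rng.normal(size=(35, 9))
        y = rng.normal(size=35)
        model = fit_simpls(X, y, 5)
        gram = model.scores.T @ model.scores
        np.testing.assert_allclose(gram, np.eye(5), atol=1e-10)

    def test_training_residual_non_increasing_in_components(self, rng):
        X = rng.normal(size=(40, 8))
        y = X @ rng.normal(size=8) + rng.normal(size=40)
        resid = [
            np.linalg.norm(y - fit_simpls(X, y, a).predict(X))
            for a in range(1, 8)
        ]
        assert np.all(np.diff(resid) <= 1e-10)

    def test_row_permutation_invariance(self, rng):
        X = rng.normal(size=(30, 7))
        y = rng.normal(size=30)
        perm = rng.permutation(30)
        m1 = fit_simpls(X, y, 3)
        m2 = fit_simpls(X[perm], y[perm], 3)
        np.testing.assert_allclose(m1.beta_slope, m2.beta_slope, atol=1e-10)

    def test_wavelength_permutation_equivariance(self, rng):
        X = rng.normal(size=(30, 7))
        y = rng.normal(size=30)
        perm = rng.permutation(7)
        m1 = fit_simpls(X, y, 3)
        m2 = fit_simpls(X[:, perm], y, 3)
        np.testing.assert_allclose(m2.beta_slope, m1.beta_slope[perm], atol=1e-10)

    def test_rank_error_reports_achievable_rank(self, rng):
        base = rng.normal(size=(20, 2))
        X = base @ rng.normal(size=(2, 10))  # rank 2
        y = X @ rng.normal(size=10)
        with pytest.raises(errors.RankError) as err:
            fit_simpls(X, y, 6)
        assert err.value.achievable_rank == 2

    def test_too_few_rows_rejected(self, rng):
        with pytest.raises(errors.RankError):
            fit_simpls(rng.normal(size=(3, 5)), rng.normal(size=3), 4)


class TestCrossValidate:
    def test_deterministic_given_seed(self, rng):
        X = rng.normal(size=(40, 6))
        y = rng.normal(size=40)
        t1 = cross_validate(X, y, [1, 2, 3], seed=9)
        t2 = cross_validate(X, y, [1, 2, 3], seed=9)
        assert t1.equals(t2)

    def test_noiseless_linear_data_has_tiny_rmsecv_at_true_rank(self, rng):
        X = rng.normal(size=(60, 5))
        y = X @ rng.normal(size=5)
        table = cross_validate(X, y, [5], n_folds=5, seed=0)
        assert table["rmsecv"].iloc[0] < 1e-8

    def test_true_factor_count_beats_single_component(self, rng):
        # three-factor synthetic mixing: RMSECV(3) <= RMSECV(1)
        scores = rng.normal(size=(80, 3))
        X = scores @ rng.normal(size=(3, 12)) + 0.01 * rng.normal(size=(80, 12))
        y = scores @ np.array([1.0, -2.0, 0.5])
        table = cross_validate(X, y, [1, 3], n_folds=4, seed=1).set_index(
            "n_components"
        )
        assert table.loc[3, "rmsecv"] <= table.loc[1, "rmsecv"]

    def test_fold_count_validation(self, rng):
        X = rng.normal(size=(10, 3))
        y = rng.normal(size=10)
        with pytest.raises(errors.ConfigError):
            cross_validate(X, y, [1], n_folds=11)
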