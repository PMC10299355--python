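"""Semivariogram estimation and model fitting against independent oracles."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from soyscout.geostats import (
    Semivariogram,
    degree_of_spatial_dependence,
    empirical_semivariogram,
    fit_all_models,
    fit_variogram_model,
    select_best_model,
)
from soyscout.models import variogram


def brute_force_semivariogram(xy, z, n_bins, max_lag):
    """All-pairs Matheron estimator by explicit enumeration (oracle)."""
    edges = np.linspace(0.0, max_lag, n_bins + 1)
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=int)
    n = len(z)
    for i in range(n):
        for j in range(i + 1, n):
            d = float(np.hypot(*(xy[i] - xy[j])))
            if d <= 0 or d > max_lag:
                continue
            for k in range(n_bins):
                if edges[k] < d <= edges[k + 1]:
                    sums[k] += (z[i] - z[j]) ** 2
                    counts[k] += 1
                    break
    keep = counts > 0
    return ((edges[:-1] + edges[1:]) / 2)[keep], sums[keep] / (2 * counts[keep]), counts[keep]


class TestEmpiricalSemivariogram:
    def test_constant_field_is_zero(self, unit_grid_xy):
        sv = empirical_semivariogram(unit_grid_xy, np.full(25, 3.0), n_bins=5)
        np.testing.assert_allclose(sv.gamma, 0.0)

    def test_two_point_hand_value(self):
        xy = np.array([[0.0, 0.0], [3.0, 4.0]])
        sv = empirical_semivariogram(xy, np.array([0.0, 2.0]), n_bins=1, max_lag=5.0)
        assert sv.n_bins == 1
        assert sv.gamma[0] == pytest.approx(2.0)  # (0 - 2)^2 / 2
        assert sv.n_pairs[0] == 1

    def test_matches_brute_force_on_grid(self, unit_grid_xy, rng):
        z = rng.integers(0, 50, 25).astype(float)
        sv = empirical_semivariogram(unit_grid_xy, z, n_bins=6)
        lags, gamma, counts = brute_force_semivariogram(unit_grid_xy, z, 6, sv.max_lag)
        np.testing.assert_allclose(sv.gamma, gamma, rtol=1e-12)
        np.testing.assert_array_equal(sv.n_pairs, counts)
        np.testing.assert_allclose(sv.lags, lags)

    def test_coincident_points_rejected(self):
        xy = np.zeros((4, 2))
        with pytest.raises(ValueError):
            empirical_semivariogram(xy, np.arange(4.0))

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            empirical_semivariogram(np.zeros((1, 2)), np.array([1.0]))


def _noiseless_sv(model, nugget, psill, rng_eff, lags=None):
    lags = np.linspace(10, 400, 12) if lags is None else lags
    gamma = variogram(model, lags, nugget, psill, rng_eff)
    return Semivariogram(
        lags=lags, gamma=gamma, n_pairs=np.full(lags.size, 50),
        max_lag=float(lags.max()), bin_width=float(lags[1] - lags[0]),
    )


class TestFitVariogramModel:
    @pytest.mark.parametrize("model", ["exponential", "spherical", "gaussian"])
    def test_noiseless_recovery(self, model):
        """Fits on exact model curves recover (C0, C, a) to <= 1% relative."""
        sv = _noiseless_sv(model, 100.0, 900.0, 200.0)
        fit = fit_variogram_model(sv, model)
        assert fit.converged
        assert fit.nugget == pytest.approx(100.0, rel=0.01)
        assert fit.sill_total == pytest.approx(1000.0, rel=0.01)
        assert fit.range_eff == pytest.approx(200.0, rel=0.01)

    def test_pure_nugget_gives_zero_dd(self):
        sv = _noiseless_sv("exponential", 500.0, 0.0, 100.0)
        fit = fit_variogram_model(sv, "exponential")
        assert fit.partial_sill == pytest.approx(0.0, abs=1e-6 * 500)
        assert fit.dd == pytest.approx(0.0, abs=0.01)

    def test_too_few_bins_rejected(self):
        sv = _noiseless_sv("exponential", 1.0, 1.0, 50.0, lags=np.array([10.0, 20, 30.0]))
        with pytest.raises(ValueError):
            fit_variogram_model(sv, "exponential")

    def test_dd_scale_invariance(self):
        """Scaling the data by k scales nugget and sill by k^2 and leaves DD
        unchanged."""
        sv1 = _noiseless_sv("spherical", 50.0, 150.0, 120.0)
        k = 7.0
        sv2 = Semivariogram(
            lags=sv1.lags, gamma=sv1.gamma * k**2, n_pairs=sv1.n_pairs,
            max_lag=sv1.max_lag, bin_width=sv1.bin_width,
        )
        f1 = fit_variogram_model(sv1, "spherical")
        f2 = fit_variogram_model(sv2, "spherical")
        assert f2.nugget == pytest.approx(k**2 * f1.nugget, rel=1e-3)
        assert f2.sill_total == pytest.approx(k**2 * f1.sill_total, rel=1e-3)
        assert f2.dd == pytest.approx(f1.dd, abs=0.01)


class TestSelectBestModel:
    def test_single_fit_returned(self):
        sv = _noiseless_sv("exponential", 10.0, 90.0, 150.0)
        fit = fit_variogram_model(sv, "exponential")
        assert select_best_model([fit]) is fit

    def test_true_model_selected(self):
        sv = _noiseless_sv("spherical", 100.0, 900.0, 200.0)
        best = select_best_model(fit_all_models(sv))
        assert best.model == "spherical"

    def test_tie_broken_by_model_order(self):
        sv = _noiseless_sv("exponential", 10.0, 90.0, 150.0)
        a = fit_variogram_model(sv, "exponential")
        b = fit_variogram_model(sv, "exponential")
        b.model = "gaussian"  # duplicate RSS/r2 under a different label
        assert select_best_model([b, a]).model == "exponential"

    def test_no_converged_fits_rejected(self):
        with pytest.raises(ValueError):
            select_best_model([])


class TestDegreeOfSpatialDependence:
    def test_extremes(self):
        assert degree_of_spatial_dependence(0.0, 100.0) == (100.0, "strong")
        dd, cls = degree_of_spatial_dependence(100.0, 100.0)
        assert dd == 0.0 and cls == "weak"

    @pytest.mark.parametrize(
        "nugget,sill,dd,cls",
        [
            (14400, 212600, 93.2, "strong"),
            (15930, 38320, 58.4, "moderate"),
        ],
    )
    def test_worked_examples(self, nugget, sill, dd, cls):
        got, got_cls = degree_of_spatial_dependence(nugget, sill)
        assert got == pytest.approx(dd, abs=0.05)
        assert got_cls == cls

    def test_class_boundaries(self):
        assert degree_of_spatial_dependence(75.0, 100.0)[1] == "weak"    # DD = 25
        assert degree_of_spatial_dependence(74.9, 100.0)[1] == "moderate"
        assert degree_of_spatial_dependence(24.5, 100.0)[1] == "moderate"  # DD = 75.5
        assert degree_of_spatial_dependence(24.0, 100.0)[1] == "strong"  # DD = 76

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            degree_of_spatial_dependence(1.0, 0.0)
        with pytest.raises(ValueError):
            degree_of_spatial_dependence(10.0, 5.0)

    @given(
        nugget=st.floats(0.0, 1e6),
        extra=st.floats(1e-6, 1e6),
        k=st.floats(0.1, 100.0),
    )
    def test_scale_invariance_property(self, nugget, extra, k):
        dd1, _ = degree_of_spatial_dependence(nugget, nugget + extra)
        dd2, _ = degree_of_spatial_dependence(k * nugget, k * (nugget + extra))
        assert dd1 == pytest.approx(dd2, abs=1e-9)
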