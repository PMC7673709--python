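"""Fitting, window selection, F-test chain and map assembly tests."""

import numpy as np
import pytest

from dlsi import (
    DLSIParams,
    FitBounds,
    G2Curve,
    ModelSpec,
    Regime,
    fit_curve,
    fit_image,
    fit_window,
    g2_forward,
    rcbf_dlsi,
    select_model,
    tau_c_initial,
)
from dlsi.fitting import FitWindow, _pixel_order, f_test_pvalue
from dlsi.models import ModelLevel

from conftest import make_curve

FS = 22881.0


def ideal_curve(tau_c, beta=1.0, rho=1.0, n=1.0, C=0.0, d=0.0, X=0.5,
                max_lag=8.8e-3, fs=FS):
    lags = np.arange(0, int(max_lag * fs) + 1) / fs
    if n == 0.5 and d == 0.0:
        d, X = 1.0, 0.5
    elif n == 2.0 and d == 0.0:
        d, X = 1.0, 2.0
    p = DLSIParams(beta=beta, rho=rho, tau_c=tau_c, d=d, X=X, C=C)
    return make_curve(lags, g2_forward(lags, p))


class TestTauCInitial:
    @pytest.mark.parametrize("tau_c", [100e-6, 500e-6, 2e-3])
    def test_closed_form_crossing(self, tau_c):
        """On 1 + exp(-2 tau/tau_c) the threshold 1 + (g2(0)-1)/e^2 is
        crossed exactly at tau_c."""
        lags = np.arange(0, 4 * tau_c, tau_c / 50)
        curve = make_curve(lags, 1 + np.exp(-2 * lags / tau_c))
        est, found = tau_c_initial(curve)
        assert found and abs(est - tau_c) / tau_c < 0.01

    def test_linear_interpolation(self):
        # threshold 1.1 between (1 ms, 1.2) and (2 ms, 1.0) -> 1.5 ms
        g0 = 1 + 0.1 * np.e**2
        curve = make_curve([0.0, 1e-3, 2e-3], [g0, 1.2, 1.0])
        est, found = tau_c_initial(curve)
        assert found and est == pytest.approx(1.5e-3, rel=1e-9)

    def test_flat_curve_not_found(self):
        curve = make_curve([0, 1e-3, 2e-3], [1.0, 1.0, 1.0])
        est, found = tau_c_initial(curve)
        assert not found and est == 2e-3

    def test_never_crossing_returns_max_lag(self):
        lags = np.linspace(0, 1e-3, 20)
        curve = make_curve(lags, 2.0 - 0.05 * lags / lags[-1])
        est, found = tau_c_initial(curve)
        assert not found and est == lags[-1]


class TestFitWindow:
    def test_tail_cut_with_five_point_floor(self):
        vals = 1 + np.array([1.0, 0.9, 0.5, 0.2, 0.11, 0.08, 0.05, 0.02])
        w = fit_window(make_curve(np.arange(8) / FS, vals))
        # cut begins at the 0.08 entry leaving 4 points -> floor of 5 applies
        assert w.indices.tolist() == [1, 2, 3, 4, 5]

    def test_fast_decay_keeps_first_five(self):
        vals = 1 + np.array([1.0, 0.5, 0.04, 0.01, 0.0, 0.0, 0.0, 0.0])
        w = fit_window(make_curve(np.arange(8) / FS, vals))
        assert w.indices.tolist() == [1, 2, 3, 4, 5]

    def test_slow_decay_keeps_everything(self):
        lags = np.arange(30) / FS
        vals = 1 + np.exp(-lags / 0.5)  # never drops below 10%
        w = fit_window(make_curve(lags, vals))
        assert w.indices.tolist() == list(range(1, 30))
        assert not w.short

    def test_short_curve_flagged(self):
        w = fit_window(make_curve(np.arange(4) / FS, [2.0, 1.8, 1.5, 1.2]))
        assert w.short and w.indices.tolist() == [1, 2, 3]

    def test_window_never_contains_zero_lag(self):
        with pytest.raises(ValueError):
            FitWindow(indices=np.array([0, 1, 2]))


class TestFitCurve:
    def test_noiseless_recovery_static_model(self):
        curve = ideal_curve(500e-6, beta=0.9, rho=0.8, n=1.0, C=0.02)
        res = fit_curve(curve, ModelSpec(level=ModelLevel.STATIC, n_fixed=1.0))
        p = res.params
        assert abs(p.tau_c - 500e-6) / 500e-6 < 1e-6
        assert abs(p.beta - 0.9) < 1e-6
        assert abs(p.rho - 0.8) < 1e-6
        assert abs(p.C - 0.02) < 1e-6
        assert res.converged and res.rss < 1e-15

    def test_noiseless_recovery_mixed_model(self):
        curve = ideal_curve(500e-6, beta=0.85, rho=0.9, d=0.4, X=2.0, C=0.01)
        res = fit_curve(curve, ModelSpec(level=ModelLevel.MIXED, X=2.0))
        assert abs(res.params.tau_c - 500e-6) / 500e-6 < 1e-5
        assert abs(res.params.d - 0.4) < 1e-5

    def test_flat_curve_degenerate(self):
        curve = make_curve(np.arange(20) / FS, np.ones(20))
        res = fit_curve(curve, ModelSpec(level=ModelLevel.SIEGERT, n_fixed=1.0))
        assert res.params.beta < 1e-3
        assert not res.converged

    def test_bounds_respected(self):
        curve = ideal_curve(500e-6, beta=0.9, rho=1.0, n=1.0)
        res = fit_curve(curve, ModelSpec(level=ModelLevel.SIEGERT, n_fixed=1.0),
                        bounds=FitBounds(beta_upper=0.5))
        assert res.params.beta <= 0.5 + 1e-12


class TestFTest:
    def test_hand_computed_f_statistic(self):
        # F = ((2-1)/1)/(1/20) = 20; P(F_{1,20} > 20) ~ 2.4e-4 < 0.05
        p = f_test_pvalue(2.0, 1.0, 1, 24, 4)
        assert p < 0.05
        from scipy.stats import f as fdist
        assert p == pytest.approx(float(fdist.sf(20.0, 1, 20)), rel=1e-12)

    def test_no_improvement_retains_simple(self):
        assert f_test_pvalue(1.0, 1.0, 1, 24, 4) == 1.0

    def test_perfect_complex_fit_accepted(self):
        assert f_test_pvalue(1.0, 0.0, 1, 24, 4) == 0.0

    def test_insufficient_dof_raises(self):
        with pytest.raises(ValueError):
            f_test_pvalue(1.0, 0.5, 1, 4, 5)


class TestSelectModel:
    def test_nested_rss_non_increasing(self):
        rng = np.random.default_rng(3)
        curve = ideal_curve(500e-6, beta=0.9, rho=0.85, n=0.5)
        noisy = make_curve(curve.lags,
                           curve.values + rng.normal(0, 0.005, len(curve)))
        _, record = select_model(noisy)
        rss = [r.rss for r in record]
        assert all(rss[i + 1] <= rss[i] + 1e-12 for i in range(len(rss) - 1))

    def test_static_truth_selected_with_correct_exponent(self):
        rng = np.random.default_rng(5)
        curve = ideal_curve(1e-3, beta=0.9, rho=0.7, n=0.5, C=0.01)
        noisy = make_curve(curve.lags,
                           curve.values + rng.normal(0, 0.001, len(curve)))
        best, _ = select_model(noisy)
        assert best.model.level == ModelLevel.STATIC
        assert best.model.n_fixed == 0.5
        assert best.regime is Regime.MU_N05
        assert abs(best.params.rho - 0.7) < 0.1

    def test_mixed_truth_selected(self):
        rng = np.random.default_rng(6)
        curve = ideal_curve(500e-6, beta=0.9, rho=0.8, d=0.5, X=0.5)
        noisy = make_curve(curve.lags,
                           curve.values + rng.normal(0, 0.001, len(curve)))
        best, _ = select_model(noisy)
        assert best.model.level == ModelLevel.MIXED
        assert best.regime is Regime.MIXED_MU_TO_N1
        assert abs(best.params.d - 0.5) < 0.15

    def test_accepted_model_fits_within_window_dof(self):
        # 6-point curve: mixed (5 params) must be skipped, static allowed
        lags = np.arange(7) / FS
        p = DLSIParams(beta=0.9, rho=0.8, tau_c=100e-6)
        curve = make_curve(lags, g2_forward(lags, p))
        best, _ = select_model(curve)
        assert best.model.free_parameter_count < len(best.window)


class TestFitImage:
    def test_pixel_order_descending_with_raster_ties(self):
        order = _pixel_order(np.array([1.0, 3.0, 3.0, 2.0]))
        assert order.tolist() == [1, 2, 3, 0]

    def test_uniform_phantom_constant_maps(self):
        curve = ideal_curve(300e-6, beta=0.8, rho=1.0, n=1.0, max_lag=4e-3)
        g2 = np.tile(curve.values, (2, 3, 1))
        maps = fit_image(curve.lags, g2,
                         model=ModelSpec(level=ModelLevel.SIEGERT, n_fixed=1.0))
        assert np.allclose(maps.tau_c, 300e-6, rtol=1e-6)
        assert np.allclose(maps.beta, 0.8, atol=1e-6)
        assert maps.converged.all()

    def test_adaptive_disabled_equals_per_pixel_fits(self):
        rng = np.random.default_rng(9)
        lags = np.arange(0, 60) / FS
        g2 = np.empty((2, 2, 60))
        taus = [200e-6, 400e-6, 800e-6, 1.6e-3]
        for j, tc in enumerate(taus):
            p = DLSIParams(beta=0.9, rho=1.0, tau_c=tc)
            g2[j // 2, j % 2] = g2_forward(lags, p) + rng.normal(0, 0.004, 60)
        spec = ModelSpec(level=ModelLevel.SIEGERT_OFFSET, n_fixed=1.0)
        maps = fit_image(lags, g2, model=spec, adaptive_bounds=False)
        for j in range(4):
            curve = make_curve(lags, g2[j // 2, j % 2])
            ref = fit_curve(curve, spec)
            assert maps.tau_c[j // 2, j % 2] == ref.params.tau_c
            assert maps.rss[j // 2, j % 2] == ref.rss

    def test_degenerate_pixels_keep_position(self):
        curve = ideal_curve(300e-6, beta=0.8, max_lag=4e-3)
        g2 = np.tile(curve.values, (2, 2, 1))
        degen = np.zeros((2, 2), bool)
        degen[0, 1] = True
        maps = fit_image(curve.lags, g2, degenerate=degen,
                         model=ModelSpec(level=ModelLevel.SIEGERT, n_fixed=1.0))
        assert np.isnan(maps.tau_c[0, 1]) and maps.regime[0, 1] == -1
        assert np.isfinite(maps.tau_c[1, 1])


def test_rcbf_dlsi():
    assert rcbf_dlsi(1e-3, 1e-3) == 1.0
    assert rcbf_dlsi(0.5e-3, 5e-3) == pytest.approx(0.1, rel=1e-12)
    with pytest.raises(ValueError):
        rcbf_dlsi(-1e-3, 1e-3)
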