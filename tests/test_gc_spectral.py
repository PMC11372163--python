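"""Tests for spectral Granger causality, lag selection, bootstrap and R_GQPC."""

import numpy as np
import pytest

import biqpc as bq
from biqpc.gc_spectral import (
    _fit_var_segments,
    geweke_spectrum,
    time_domain_gc,
)

from conftest import F1, F2, F3, gaussian_series

# a stable bivariate VAR(2) with coupling only from the driver (col 1) to the
# target (col 0): Geweke's spectral decomposition integrates exactly to the
# time-domain statistic for such one-directional systems
A1 = np.array([[0.5, 0.4], [0.0, 0.3]])
A2 = np.array([[-0.3, 0.25], [0.0, -0.2]])


def _simulate_var2(rng, n, burn=200):
    z = np.zeros((n + burn, 2))
    e = rng.normal(size=(n + burn, 2))
    for t in range(2, n + burn):
        z[t] = A1 @ z[t - 1] + A2 @ z[t - 2] + e[t]
    return z[burn:]


class TestLagSelection:
    def test_white_noise_selects_minimal_order(self):
        lags = [bq.select_lag(np.random.default_rng(r).normal(size=(5000, 2))).lag
                for r in range(20)]
        assert np.mean(np.asarray(lags) <= 2) >= 0.95

    def test_var2_order_recovered(self):
        lags = [bq.select_lag(_simulate_var2(np.random.default_rng(100 + r), 5000)).lag
                for r in range(20)]
        assert np.mean(np.asarray(lags) == 2) >= 0.9

    def test_never_exceeds_argmin(self):
        for r in range(5):
            sel = bq.select_lag(_simulate_var2(np.random.default_rng(r), 3000))
            assert sel.lag <= sel.argmin

    def test_short_series_reduces_lag_max(self):
        with pytest.warns(RuntimeWarning):
            sel = bq.select_lag(np.random.default_rng(0).normal(size=(60, 2)), lag_max=50)
        assert sel.lag >= 1


class TestGewekeSpectrum:
    def test_nonnegative_everywhere(self):
        freqs = np.linspace(0.001, 0.499, 300)
        spec = geweke_spectrum(np.stack([A1, A2]), np.eye(2), freqs, 1.0)
        assert np.all(spec >= 0)

    def test_integral_matches_time_domain(self):
        # (1/pi) * integral of the causality spectrum over (0, pi) equals the
        # time-domain log-variance-ratio statistic for one-directional coupling
        z = _simulate_var2(np.random.default_rng(5), 10_000)
        td = time_domain_gc(z, 2)
        freqs = np.linspace(0.00025, 0.49975, 1000)
        A, Sigma = _fit_var_segments(z[None], 2)
        integral = float(np.mean(geweke_spectrum(A[0], Sigma[0], freqs, 1.0)))
        assert integral == pytest.approx(td, rel=0.05)

    def test_estimated_matches_true_coefficients(self):
        # known-system oracle: spectra from the fitted VAR agree with spectra
        # from the generating coefficients at every frequency
        z = _simulate_var2(np.random.default_rng(6), 60_000)
        freqs = np.linspace(0.0025, 0.4975, 200)
        A, Sigma = _fit_var_segments(z[None], 2)
        est = geweke_spectrum(A[0], Sigma[0], freqs, 1.0)
        true = geweke_spectrum(np.stack([A1, A2]), np.eye(2), freqs, 1.0)
        floor = 0.01  # relative error is meaningless where causality ~ 0
        rel = np.abs(est - true) / np.maximum(true, floor)
        assert rel.max() <= 0.10


class TestVarFitOracle:
    def test_matches_statsmodels_var(self):
        # independent reference: the batched OLS VAR equals statsmodels' VAR
        # (no trend) on the same sample
        from statsmodels.tsa.api import VAR

        z = _simulate_var2(np.random.default_rng(17), 3000)
        l = 2
        A, Sigma = _fit_var_segments(z[None], l)
        ref = VAR(z).fit(maxlags=l, trend="n")
        np.testing.assert_allclose(A[0], ref.coefs, atol=1e-8)
        np.testing.assert_allclose(
            Sigma[0], ref.sigma_u * (ref.nobs - 2 * l) / ref.nobs, rtol=1e-6
        )


class TestNbootsRule:
    @pytest.mark.parametrize("df, expected", [(0.2, 447), (1.0, 1000), (0.25, 500)])
    def test_rule(self, df, expected):
        assert bq.nboots_rule(df) == expected

    def test_invalid_resolution(self):
        with pytest.raises(ValueError):
            bq.nboots_rule(0.0)


class TestIntervalOfInterest:
    def test_worked_example(self):
        lo, hi = bq.interval_of_interest(8.5, 10.5, 0.5, 50.0, 100.0)
        assert (lo, hi) == (18.0, 20.0)

    def test_degenerate_width(self):
        lo, hi = bq.interval_of_interest(8.0, 10.0, 0.0, 50.0, 100.0)
        assert lo == hi == 18.0

    def test_aliased_sum_folds_back(self):
        lo, hi = bq.interval_of_interest(48.4, 36.6, 0.5, 50.0, 100.0)
        assert (lo + hi) / 2 == pytest.approx(100.0 - 85.0)

    def test_empty_after_clipping_rejected(self):
        with pytest.raises(ValueError):
            bq.interval_of_interest(25.0, 25.0, 0.0, 50.0, 100.0)


class TestBgcs:
    def test_spectrum_nonnegative(self, plan, small_series):
        spec = bq.bgcs(small_series, 0, 1, 2, plan, lag=5)
        assert np.all(spec.bgcs >= 0)
        assert len(spec.freqs) == 249
        assert spec.freqs[0] == pytest.approx(0.2)
        assert spec.freqs[-1] == pytest.approx(49.8)

    def test_coupled_mass_at_quadratic_product_frequencies(self, plan, small_series):
        # the product process carries both the sum and the difference lines
        # of the two carriers; the BGCS peak sits on one of them and the sum
        # frequency stands far above the spectrum's typical level
        spec = bq.bgcs(small_series, 0, 1, 2, plan)
        peak = spec.freqs[np.argmax(spec.bgcs)]
        products = (F1 + F2, F1 - F2)
        assert any(abs(peak - f) <= 1.0 for f in products)
        band = np.abs(spec.freqs - (F1 + F2)) <= 1.0
        assert spec.bgcs[band].max() >= 3.0 * np.median(spec.bgcs)

    def test_reproducible(self, plan, small_series):
        a = bq.bgcs(small_series, 0, 1, 2, plan, lag=5)
        b = bq.bgcs(small_series, 0, 1, 2, plan, lag=5)
        np.testing.assert_array_equal(a.bgcs, b.bgcs)


class TestBootstrapSignificance:
    def test_null_calibration(self, plan):
        # independent channels: no significant frequencies, theta undefined;
        # pooled false-discovery fraction across replicates stays below 7.5 %
        reps, clean, false, disc = 12, 0, 0, 0
        for rep in range(reps):
            series = gaussian_series(700 + rep, n_epochs=16)
            spec = bq.bgcs(series, 0, 1, 2, plan)
            spec = bq.bootstrap_significance(spec, nboots=200, seed=rep)
            n = int((spec.q < 0.05).sum())
            clean += n == 0
            false += n
            disc += n
            if n == 0:
                assert spec.theta is None
        assert clean >= 0.95 * reps or (disc and false / disc <= 0.075) or disc == 0

    def test_planted_coupling_detected(self, plan):
        # strong coupling: the interval of interest carries significant mass
        hits, reps = 0, 6
        for rep in range(reps):
            cond = bq.ConditionSpec(F1=F1, F2=F2, F3=F3, W=0.3, n_epochs=16, seed=400 + rep)
            series = bq.simulate_condition(cond)
            spec = bq.bgcs(series, 0, 1, 2, plan)
            spec = bq.bootstrap_significance(spec, nboots=200, seed=rep)
            lo, hi = bq.interval_of_interest(F1, F2, 0.5, plan.f_nyquist, plan.fs)
            band = (spec.freqs >= lo) & (spec.freqs <= hi)
            hits += bool(spec.significant[band].sum() > 0)
        assert hits >= 0.9 * reps

    def test_small_nboots_warns(self, plan, small_series):
        spec = bq.bgcs(small_series, 0, 1, 2, plan, lag=3)
        with pytest.warns(RuntimeWarning):
            bq.bootstrap_significance(spec, nboots=50, seed=0)


class TestRgqpc:
    def test_worked_example_sums(self):
        from biqpc.qpc_bispec import qpc_ratio

        # the printed quotient 0.233 reflects 3-digit rounding of the sums
        assert qpc_ratio(0.128, 0.552) == pytest.approx(0.233, abs=2e-3)

    def test_all_mass_in_interval(self, plan, small_series):
        spec = bq.bgcs(small_series, 0, 1, 2, plan, lag=4)
        sig = np.zeros_like(spec.bgcs)
        band = (spec.freqs >= 29.0) & (spec.freqs <= 31.0)
        sig[band] = spec.bgcs[band]
        from dataclasses import replace

        spec = replace(spec, significant=sig, theta=0.01, nboots=100)
        res = bq.r_gqpc(spec, (29.0, 31.0))
        assert res.ratio == pytest.approx(1.0)

    def test_no_significance_is_undefined(self, plan, small_series):
        from dataclasses import replace

        spec = bq.bgcs(small_series, 0, 1, 2, plan, lag=4)
        spec = replace(spec, significant=np.zeros_like(spec.bgcs), theta=None, nboots=100)
        res = bq.r_gqpc(spec, (18.0, 20.0))
        assert res.ratio is None
        assert res.flag == "undefined"

    def test_interval_outside_grid_rejected(self, plan, small_series):
        from dataclasses import replace

        spec = bq.bgcs(small_series, 0, 1, 2, plan, lag=4)
        spec = replace(spec, significant=np.zeros_like(spec.bgcs))
        with pytest.raises(ValueError):
            bq.r_gqpc(spec, (60.0, 70.0))
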