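import numpy as np
import pytest
from scipy.special import gamma

import ringhet as rh
from conftest import make_curve, log_grid


class TestTau0ClosedForm:
    def test_beta_one_is_identity(self):
        for tau in (0.3, 1.0, 42.0):
            assert rh.tau0_from_kww(tau, 1.0) == pytest.approx(tau, rel=1e-14)

    def test_beta_half_doubles(self):
        # Gamma(2) / 0.5 = 2 exactly
        assert rh.tau0_from_kww(1.0, 0.5) == pytest.approx(2.0, rel=1e-14)

    @pytest.mark.parametrize("tau_kww,beta,tau0", [
        (7.1, 0.78, 8.2),
        (50.0, 0.66, 67.0),
        (91.0, 0.51, 174.0),
        (10.2, 0.70, 13.0),
    ])
    def test_reported_melt_and_blend_values(self, tau_kww, beta, tau0):
        """Closed form reproduces published terminal times within rounding."""
        assert rh.tau0_from_kww(tau_kww, beta) == pytest.approx(tau0, rel=0.02)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            rh.tau0_from_kww(1.0, 0.0)
        with pytest.raises(ValueError):
            rh.tau0_from_kww(-1.0, 0.5)


class TestFitKWW:
    def test_pure_exponential_reduces_to_beta_one(self):
        t = np.linspace(0, 50, 200)
        fit = rh.fit_kww(make_curve(t, np.exp(-t / 5)))
        assert fit.beta == pytest.approx(1.0, abs=1e-6)
        assert fit.tau_kww == pytest.approx(5.0, rel=1e-6)
        assert fit.converged

    @pytest.mark.parametrize("tau,beta", [(50.0, 0.6), (91.0, 0.51)])
    def test_recovers_generating_parameters(self, tau, beta):
        t = log_grid(0.01, 2000, 300)
        fit = rh.fit_kww(make_curve(t, rh.kww_curve(t, tau, beta)))
        assert fit.tau_kww == pytest.approx(tau, rel=1e-3)
        assert fit.beta == pytest.approx(beta, rel=1e-3)

    def test_blend_parameters_imply_reported_terminal_time(self):
        t = log_grid(0.01, 2000, 300)
        fit = rh.fit_kww(make_curve(t, rh.kww_curve(t, 91.0, 0.51)))
        assert fit.tau0 == pytest.approx(174.0, rel=0.02)

    def test_internal_consistency_is_structural(self):
        t = log_grid(0.01, 100, 120)
        fit = rh.fit_kww(make_curve(t, rh.kww_curve(t, 3.0, 0.7)))
        assert fit.tau0 == pytest.approx(fit.tau_kww * gamma(1 / fit.beta) / fit.beta,
                                         rel=1e-12)

    def test_too_few_points_rejected(self):
        t = np.linspace(0, 4, 5)
        with pytest.raises(ValueError, match="10"):
            rh.fit_kww(make_curve(t, np.exp(-t)))


class TestTau0Numeric:
    def test_exponential_integral(self):
        t = np.linspace(0, 12.0, 4000)
        rel = rh.tau0_numeric(make_curve(t, np.exp(-t), scope="molecule", molecule_id="m"))
        assert rel.tau0_numeric == pytest.approx(1.0, rel=1e-3)
        assert rel.truncated and rel.t_max is None

    def test_kww_integral_matches_closed_form(self):
        t = log_grid(1e-6, 1e4, 20000)
        rel = rh.tau0_numeric(make_curve(t, rh.kww_curve(t, 1.0, 0.5)))
        assert rel.tau0_numeric == pytest.approx(2.0, rel=5e-3)

    def test_window_ends_at_scan_crossing(self, mixture_run):
        curve = mixture_run["curves"][0]
        rel = rh.tau0_numeric(curve)
        t_cross = rh.first_negative_crossing(curve)
        assert rel.t_max == t_cross
        hi = int(np.searchsorted(curve.lags, t_cross))
        # independent quadrature: midpoint-rectangle rule on the same window
        mids = 0.5 * (curve.values[: hi] + curve.values[1 : hi + 1])
        widths = np.diff(curve.lags[: hi + 1])
        assert rel.tau0_numeric == pytest.approx(float(np.sum(mids * widths)), rel=1e-10)


class TestMultiExp:
    def test_single_exponential(self):
        t = log_grid(0.01, 30, 100)
        fit = rh.fit_multiexp(make_curve(t, np.exp(-t / 3)), 1)
        assert fit.n_modes == 1
        assert fit.taus[0] == pytest.approx(3.0, rel=1e-6)
        assert fit.amplitudes[0] == pytest.approx(1.0, abs=1e-9)

    def test_two_mode_recovery(self):
        t = log_grid(0.01, 1000, 250)
        y = 0.5 * np.exp(-t / 1.0) + 0.5 * np.exp(-t / 100.0)
        fit = rh.fit_multiexp(make_curve(t, y), 2)
        np.testing.assert_allclose(fit.taus, [1.0, 100.0], rtol=0.01)
        np.testing.assert_allclose(fit.amplitudes, [0.5, 0.5], rtol=0.01)

    def test_three_mode_ring_melt_parameters(self):
        """Noiseless three-mode melt curve: all taus and weights recovered."""
        taus = np.array([0.10, 1.1, 10.0])
        amps = np.array([0.06, 0.17, 0.77])
        t = log_grid(0.01, 200, 250)
        fit = rh.fit_multiexp(make_curve(t, rh.multiexp_curve(t, taus, amps)), 3)
        np.testing.assert_allclose(fit.taus, taus, rtol=0.01)
        np.testing.assert_allclose(fit.amplitudes, amps, rtol=0.01)

    def test_amplitudes_conserved(self):
        rng = np.random.default_rng(12)
        t = log_grid(0.01, 500, 200)
        y = 0.3 * np.exp(-t / 0.5) + 0.7 * np.exp(-t / 40) + rng.normal(0, 0.01, t.size)
        y[0] = 1.0
        fit = rh.fit_multiexp(make_curve(t, np.clip(y, -1, 1)), 3)
        assert abs(fit.amplitudes.sum() - 1.0) < 1e-6
        assert np.all(fit.amplitudes >= 0)

    def test_mean_integral_identity(self):
        taus = np.array([0.2, 5.0, 60.0])
        amps = np.array([0.2, 0.3, 0.5])
        t = log_grid(0.001, 2000, 300)
        fit = rh.fit_multiexp(make_curve(t, rh.multiexp_curve(t, taus, amps)), 3)
        assert fit.mean_relaxation_time == pytest.approx(float(taus @ amps), rel=1e-3)

    def test_mode_cap_enforced(self):
        t = log_grid(0.01, 10, 60)
        with pytest.raises(ValueError, match="maximum"):
            rh.fit_multiexp(make_curve(t, np.exp(-t)), 7)

    def test_time_rescaling_covariance(self):
        taus = np.array([0.5, 8.0])
        amps = np.array([0.4, 0.6])
        s = 3.7
        t = log_grid(0.01, 100, 200)
        base = rh.fit_multiexp(make_curve(t, rh.multiexp_curve(t, taus, amps)), 2)
        scaled = rh.fit_multiexp(
            make_curve(t * s, rh.multiexp_curve(t, taus, amps)), 2)
        np.testing.assert_allclose(scaled.taus, base.taus * s, rtol=1e-3)
        np.testing.assert_allclose(scaled.amplitudes, base.amplitudes, atol=1e-4)
        kww_base = rh.fit_kww(make_curve(t, rh.kww_curve(t, 5.0, 0.6)))
        kww_scaled = rh.fit_kww(make_curve(t * s, rh.kww_curve(t, 5.0, 0.6)))
        assert kww_scaled.beta == pytest.approx(kww_base.beta, rel=1e-4)
        assert kww_scaled.tau_kww == pytest.approx(kww_base.tau_kww * s, rel=1e-4)

    def test_multiexp_integral_converges_to_kww_tau0(self):
        # for a stretched curve the mode integral approaches the closed form
        t = log_grid(1e-3, 5e3, 300)
        curve = make_curve(t, rh.kww_curve(t, 5.0, 0.6))
        tau0 = rh.tau0_from_kww(5.0, 0.6)
        errs = [abs(rh.fit_multiexp(curve, n).mean_relaxation_time - tau0) / tau0
                for n in (1, 2, 3)]
        assert errs[1] < errs[0] and errs[2] < errs[1]
        assert errs[2] < 0.15


class TestSelectNumModes:
    def test_pure_exponential_needs_one(self):
        t = log_grid(0.01, 50, 150)
        n, fit = rh.select_num_modes(make_curve(t, np.exp(-t / 4)), 4)
        assert n == 1 and fit.n_modes == 1

    def test_melt_curve_needs_three(self):
        t = log_grid(0.01, 200, 250)
        y = rh.multiexp_curve(t, np.array([0.10, 1.1, 10.0]), np.array([0.06, 0.17, 0.77]))
        n, _ = rh.select_num_modes(make_curve(t, y), 5)
        assert n == 3

    def test_four_decade_separated_modes(self):
        t = log_grid(0.001, 2000, 300)
        taus = np.array([0.05, 0.5, 5.0, 50.0])
        amps = np.array([0.1, 0.2, 0.3, 0.4])
        n, fit = rh.select_num_modes(make_curve(t, rh.multiexp_curve(t, taus, amps)), 6)
        assert n == 4
        np.testing.assert_allclose(fit.taus, taus, rtol=0.05)
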