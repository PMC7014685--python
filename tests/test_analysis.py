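import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import rodcascade as rc
from rodcascade.analysis import (doubly_delayed_ramp, fit_rising_phase,
                                 fit_superlinearity, fit_tail_time_constant,
                                 measure_tsat, tsat_curve, tsat_prediction,
                                 tsat_tangent_slope)
from rodcascade.outer_segment import poisson_weights
from rodcascade.traces import DiscTrace, OuterSegmentTrace


def _trace_from_ramp(params, Q, nu, tau2, dt=2.5e-4, t_end=0.06):
    t = np.arange(0.0, t_end, dt)
    e = doubly_delayed_ramp(t, Q, nu, 1.0 / params.nu_Gst, tau2)
    e = np.clip(e, 0.0, params.E_tot)
    return DiscTrace(t=t, G_star=np.zeros_like(t),
                     E=params.E_tot - e, E_star=np.zeros_like(t),
                     E_starstar=e)


class TestRisingPhase:
    def test_exact_parameter_recovery(self, params):
        tr = _trace_from_ramp(params, 3, 400.0, 5e-3)
        fit = fit_rising_phase(tr, 3, params)
        assert fit.nu_Estst == pytest.approx(400.0, rel=1e-4)
        assert fit.tau2 == pytest.approx(5e-3, rel=1e-4)
        assert fit.tau1 == 1.0 / params.nu_Gst

    def test_requires_resolved_onset(self, params):
        tr = _trace_from_ramp(params, 3, 400.0, 5e-3, dt=2.5e-4, t_end=0.004)
        with pytest.raises(ValueError):
            fit_rising_phase(tr, 3, params)

    def test_ramp_is_causal(self, params):
        t = np.linspace(-0.01, 0.05, 200)
        e = doubly_delayed_ramp(t, 1, 400.0, 8e-4, 5e-3)
        assert np.all(e[t <= 0] == 0.0)
        assert np.all(np.diff(e[t > 0]) >= -1e-12)


class TestSuperlinearity:
    def test_exact_recovery(self):
        amps = {q: 1.42 * q * 1.32 ** (q - 1) for q in (1, 2, 3, 4)}
        fit = fit_superlinearity(amps)
        assert fit.rho == pytest.approx(0.32, abs=1e-12)
        assert fit.R1 == pytest.approx(1.42, abs=1e-12)

    def test_linear_amplitudes_give_zero_rho(self):
        fit = fit_superlinearity({q: 2.0 * q for q in (1, 2, 3, 4)})
        assert fit.rho == pytest.approx(0.0, abs=1e-12)

    def test_requires_first_four_Q(self):
        with pytest.raises(ValueError):
            fit_superlinearity({1: 1.0, 2: 2.0, 3: 3.5})

    def test_poisson_weighted_amplitude_identity(self, params):
        # sum_Q p_Q R_Q = phi e^{rho phi} R1 when R_Q follows the
        # super-linear scaling law exactly
        rho, R1 = 0.32, 1.42
        for phi in (0.2, 1.0, 3.0, 5.0):
            w = poisson_weights(phi * params.N_surfs, params.N_surfs,
                                mass_tolerance=1e-15)
            s = sum(p * R1 * q * (1 + rho) ** (q - 1)
                    for q, p in w.items() if q > 0)
            expected = phi * np.exp(rho * phi) * R1
            assert s == pytest.approx(expected, rel=1e-8)


class TestMeasureTsat:
    def _resp(self, t, J, J_dark=18.4):
        return OuterSegmentTrace(t=t, J=J, J_dark=J_dark)

    def test_linear_ramp(self):
        t = np.linspace(0, 2, 2001)
        r = self._resp(t, 18.4 * np.minimum(1.0, t))
        assert measure_tsat(r, 0.1) == pytest.approx(0.1, abs=1e-9)

    def test_unsaturated_response(self):
        t = np.linspace(0, 2, 200)
        r = self._resp(t, 18.4 * (0.5 + 0.5 * t / 2))
        assert measure_tsat(r, 0.1) is None

    @given(st.floats(0.05, 0.5), st.floats(0.1, 1.5))
    @settings(deadline=None, derandomize=True, max_examples=30)
    def test_delayed_exponential_family(self, tau, T):
        t = np.linspace(0, 8, 8001)
        J = 18.4 * np.clip(1.0 - np.exp(-(t - T) / tau), 0.0, None)
        r = self._resp(t, J)
        expected = T + tau * np.log(1.0 / (1.0 - 0.1))
        assert measure_tsat(r, 0.1) == pytest.approx(expected, abs=2e-3)


class TestTsatCurve:
    def test_degenerate_single_slope(self):
        tau, Phi0 = 0.25, 50.0

        def response_fn(Phi):
            T = tau * np.log(Phi / Phi0)
            t = np.linspace(0, 6, 6001)
            J = 18.4 * np.clip((t - T) / 1e-3, 0.0, 1.0)
            return OuterSegmentTrace(t=t, J=J, J_dark=18.4)

        curve = tsat_curve(10 ** np.arange(2.0, 4.8, 0.1), response_fn)
        assert curve.tau_D1 == pytest.approx(tau, rel=1e-3)
        assert curve.tau_D2 == pytest.approx(tau, rel=1e-3)
        assert np.all(np.diff(curve.T_sat) >= 0)

    def test_nonsaturating_points_excluded(self):
        def response_fn(Phi):
            t = np.linspace(0, 2, 200)
            if Phi < 400:
                return OuterSegmentTrace(t=t, J=np.full_like(t, 10.0),
                                         J_dark=18.4)
            T = 0.3 * np.log(Phi / 50)
            J = 18.4 * np.clip((t - T) / 1e-3, 0.0, 1.0)
            return OuterSegmentTrace(t=t, J=J, J_dark=18.4)

        curve = tsat_curve(10 ** np.arange(2.0, 4.8, 0.1), response_fn)
        assert curve.excluded and max(curve.excluded) < 400


class TestTsatPrediction:
    def test_zero_rho_is_straight_line(self, params):
        Phi = 10 ** np.linspace(2.5, 4.5, 30)
        pred = tsat_prediction(Phi, params, rho=0.0, t_offset=0.585)
        slopes = np.diff(pred) / np.diff(np.log(Phi))
        assert np.allclose(slopes, 1.0 / params.k_Estst, rtol=1e-9)

    def test_tangent_slope_factor_at_1000(self, params):
        slope = tsat_tangent_slope(1000.0, params, rho=0.32)
        factor = slope * params.k_Estst
        assert factor == pytest.approx(1.0 + 0.32 * 1000.0 / 1320.0, rel=1e-12)
        assert factor == pytest.approx(1.24, abs=0.005)

    def test_convex_increasing_in_log_intensity(self, params):
        lnPhi = np.linspace(np.log(100), np.log(62500), 200)
        pred = tsat_prediction(np.exp(lnPhi), params, rho=0.32)
        d1 = np.diff(pred)
        d2 = np.diff(d1)
        assert np.all(d1 > 0) and np.all(d2 > -1e-12)


class TestTailFit:
    def test_pure_exponential_recovered_exactly(self):
        t = np.linspace(0, 3, 3001)
        y = 50.0 * np.exp(-t / 0.2)
        assert fit_tail_time_constant(t, y, window=(0.5, 5.0)) == \
            pytest.approx(0.2, rel=1e-9)

    def test_rising_tail_rejected(self):
        t = np.linspace(0, 3, 301)
        y = np.concatenate([np.linspace(10, 1, 150), np.linspace(1, 4, 151)])
        with pytest.raises(ValueError):
            fit_tail_time_constant(t, y, window=(0.5, 5.0))
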