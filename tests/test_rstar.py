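import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from scipy.integrate import quad, solve_ivp

import rodcascade as rc
from rodcascade.rstar import (DepletionState, assign_event_types,
                              cumulative_gstar_created,
                              depletion_fraction_closed_form,
                              depletion_rate_factor, lifetime_sum_distribution,
                              mean_rstar_activity, sample_aberrant_lifetime,
                              sample_normal_lifetime)


class TestNormalLifetimes:
    def test_sample_mean_matches_gamma_mean(self, rng):
        x = sample_normal_lifetime(3, 60.0, rng, size=100_000)
        sem = x.std() / np.sqrt(len(x))
        assert abs(x.mean() - 4 / 60) < 3 * sem

    def test_single_stage_is_exponential(self, rng):
        x = sample_normal_lifetime(0, 60.0, rng, size=100_000)
        assert stats.kstest(x, "expon", args=(0, 1 / 60)).pvalue > 0.01

    def test_empirical_cdf_matches_survival_complement(self, rng):
        x = np.sort(sample_normal_lifetime(3, 60.0, rng, size=100_000))
        ecdf = np.arange(1, len(x) + 1) / len(x)
        cdf = 1.0 - mean_rstar_activity(x, 3, 60.0)
        assert np.max(np.abs(ecdf - cdf)) < 0.01


class TestMeanActivity:
    def test_starts_at_unity(self):
        assert mean_rstar_activity(0.0, 3, 60.0) == 1.0

    def test_integral_is_mean_lifetime(self):
        val, _ = quad(lambda t: mean_rstar_activity(t, 3, 60.0), 0, 2.0)
        assert val == pytest.approx(4 / 60, rel=1e-8)

    def test_equals_gamma_survival(self):
        t = 4 / 60
        assert mean_rstar_activity(t, 3, 60.0) == pytest.approx(
            stats.gamma(a=4, scale=1 / 60).sf(t), rel=1e-12)

    @given(st.floats(1e-4, 0.5), st.floats(1e-4, 0.5))
    @settings(deadline=None, derandomize=True, max_examples=30)
    def test_monotone_decreasing(self, t1, t2):
        lo, hi = sorted((t1, t2))
        assert mean_rstar_activity(hi, 3, 60.0) <= mean_rstar_activity(lo, 3, 60.0)


class TestLifetimeSums:
    def test_reduces_to_single_lifetime(self):
        d1 = lifetime_sum_distribution(1, 3, 60.0)
        t = np.linspace(0, 0.3, 50)
        assert np.allclose(d1.sf(t), mean_rstar_activity(t, 3, 60.0))

    def test_large_shape_density_normalized(self):
        # Q=30, M=3 gives shape 120, where naive factorial formulas overflow
        d = lifetime_sum_distribution(30, 3, 60.0)
        val, _ = quad(d.pdf, 0, 6.0, limit=200)
        assert val == pytest.approx(1.0, abs=1e-8)

    def test_matches_sum_of_samples(self, rng):
        sums = sample_normal_lifetime(3, 60.0, rng, size=(100_000, 5)).sum(axis=1)
        d = lifetime_sum_distribution(5, 3, 60.0)
        assert stats.kstest(sums, d.cdf).statistic < 0.01


class TestEventTypes:
    def test_degenerate_probabilities(self, rng):
        assert assign_event_types(7, 0.0, rng) == (7, 0)
        assert assign_event_types(7, 1.0, rng) == (0, 7)

    def test_aberrant_fraction(self, rng):
        _, q_ab = assign_event_types(1_000_000, 0.002, rng)
        se = np.sqrt(0.002 * 0.998 / 1e6)
        assert abs(q_ab / 1e6 - 0.002) < 3 * se

    def test_aberrant_lifetime_mean_and_law(self, rng):
        x = sample_aberrant_lifetime(4.0, rng, size=100_000)
        assert abs(x.mean() - 4.0) < 3 * x.std() / np.sqrt(len(x))
        assert stats.kstest(x, "expon", args=(0, 4.0)).pvalue > 0.01


class TestDepletion:
    def test_rate_factor_anchors(self):
        s = DepletionState(G0=100.0)
        assert depletion_rate_factor(s, 0.14) == pytest.approx(1.0)
        s = DepletionState(G0=100.0, cumulative_activated=100.0)
        assert depletion_rate_factor(s, 0.14) == 0.0
        assert depletion_rate_factor(14.0, 0.14, G0=100.0) == pytest.approx(0.57)

    def test_pool_bookkeeping(self):
        s = DepletionState(G0=10.0)
        s.record(4.0)
        assert s.G_remaining == 6.0
        with pytest.raises(ValueError):
            s.record(7.0)

    def test_closed_form_limits(self):
        assert depletion_fraction_closed_form(0.0, 75000.0, 3318.0, 0.14) == 0.0
        assert depletion_fraction_closed_form(10.0, 75000.0, 3318.0, 0.14) == \
            pytest.approx(1.0, abs=1e-12)

    def test_closed_form_matches_ode(self):
        nu0, G0, km = 60 * 1250.0, 3600.0, 0.14
        t = np.linspace(0.0, 0.2, 201)

        def ode(_, y):
            g = max(y[0], 0.0) / G0
            return [-nu0 * (g / (g + km)) * (1 + km)]

        sol = solve_ivp(ode, (0, 0.2), [G0], t_eval=t, rtol=1e-11, atol=1e-11)
        numeric = 1.0 - sol.y[0] / G0
        closed = depletion_fraction_closed_form(t, nu0, G0, km)
        assert np.max(np.abs(numeric - closed)) < 1e-6

    @given(st.integers(2, 40), st.floats(1e-3, 0.1))
    @settings(deadline=None, derandomize=True, max_examples=30)
    def test_time_scaling_law(self, Q, t):
        # depletion at rate Q*nu after time t equals depletion at rate nu
        # after time Q*t (the time axis simply scales with Q)
        a = depletion_fraction_closed_form(t, Q * 1250.0, 3318.0, 0.14)
        b = depletion_fraction_closed_form(Q * t, 1250.0, 3318.0, 0.14)
        assert a == pytest.approx(b, rel=1e-9, abs=1e-12)

    def test_creation_never_exceeds_pool(self):
        t = np.linspace(0, 50, 100)
        created = cumulative_gstar_created(t, 75000.0, 3318.0, 0.14)
        assert np.all(created <= 3318.0 + 1e-9)


class TestTimelines:
    def test_timeline_validation(self):
        with pytest.raises(ValueError):
            rc.RStarTimeline(0.0, 0.0)
        with pytest.raises(ValueError):
            rc.RStarTimeline(0.0, 1.0, activity=0.0)

    def test_sampled_timelines_structure(self, params, rng):
        tls = rc.sample_timelines(20, params, rng, include_aberrant=True)
        assert len(tls) == 20
        for tl in tls:
            assert tl.t_off > tl.t_on == 0.0
            assert tl.activity == (params.a_aberr if tl.is_aberrant else 1.0)
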