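import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import rodcascade as rc
from rodcascade.outer_segment import (mean_os_activity_method2,
                                      poisson_weights, simulate_os_method3)
from rodcascade.pipelines import per_Q_mean_traces


@pytest.fixture(scope="module")
def small_traces(params):
    # mean method-2 traces for the low-Q regime, shared across tests
    return per_Q_mean_traces(params, range(1, 12), n_trials=300, t_end=2.0,
                             seed=500)


class TestPoissonWeights:
    def test_dark_flash(self, params):
        assert poisson_weights(0.0, params.N_surfs) == {0: 1.0}

    @given(st.floats(0.1, 60000.0))
    @settings(deadline=None, derandomize=True, max_examples=40)
    def test_weights_normalized(self, Phi):
        w = poisson_weights(Phi, 1320)
        assert abs(sum(w.values()) - 1.0) < 1e-12

    def test_truncation_scale(self, params):
        # phi = 30 requires support up to roughly twice the mean
        w = poisson_weights(30.0 * params.N_surfs, params.N_surfs)
        assert 55 <= max(w) <= 80
        assert min(w) == 0


class TestMethod2Assembly:
    def test_linear_regime(self, params, small_traces):
        t, total = mean_os_activity_method2(1.0, small_traces, params.N_surfs)
        expected = small_traces[1].E_starstar  # Phi * mean SPR trace, Phi=1
        i = np.argmax(expected)
        assert total[i] == pytest.approx(expected[i], rel=0.01)

    def test_missing_Q_raises(self, params, small_traces):
        with pytest.raises(ValueError, match="missing mean trace"):
            mean_os_activity_method2(5000.0, small_traces, params.N_surfs)

    def test_matches_sampled_disc_assignment(self, params, small_traces):
        # brute-force check of the Poisson weighting: draw per-surface
        # counts and sum the corresponding mean traces
        Phi = 2000.0
        t, total = mean_os_activity_method2(
            Phi, small_traces, params.N_surfs, mass_tolerance=1e-5)
        rng = np.random.default_rng(8)
        acc = np.zeros_like(t)
        n_rep = 200
        for _ in range(n_rep):
            qs = rng.poisson(Phi / params.N_surfs, size=params.N_surfs)
            for q in qs[qs > 0]:
                acc += small_traces[min(int(q), max(small_traces))].E_starstar
        acc /= n_rep
        i = np.argmax(total)
        assert acc[i] == pytest.approx(total[i], rel=0.05)


class TestMethod3:
    def test_rejects_dark_flash(self, params):
        with pytest.raises(ValueError):
            simulate_os_method3(0.0, params)

    def test_aberrant_event_statistics(self, params):
        acts = simulate_os_method3(500.0, params, seed=31, n_trials=60,
                                   t_end=0.2)
        counts = np.array([a.meta["n_aberrant"] for a in acts])
        # expected Poisson(Phi * p_aberr) = Poisson(1.0)
        assert abs(counts.mean() - 1.0) < 3 * np.sqrt(1.0 / len(counts))
        frac_zero = (counts == 0).mean()
        se = np.sqrt(np.exp(-1) * (1 - np.exp(-1)) / len(counts))
        assert abs(frac_zero - np.exp(-1)) < 3 * se

    def test_total_isomerizations_match_intensity(self, params):
        acts = simulate_os_method3(1000.0, params, seed=32, n_trials=30,
                                   t_end=0.05)
        n = np.array([a.meta["n_isom"] for a in acts])
        assert abs(n.mean() - 1000.0) < 3 * np.sqrt(1000.0 / len(n))

    def test_consistent_with_method2_weighting(self, params, small_traces):
        # without aberrant events the trial-averaged total E** activity
        # must agree with the Poisson-weighted assembly
        Phi = 300.0
        acts = simulate_os_method3(Phi, params, seed=33, n_trials=40,
                                   t_end=2.0, include_aberrant=False)
        mean_total = np.mean([a.total for a in acts], axis=0)
        t, expected = mean_os_activity_method2(Phi, small_traces,
                                               params.N_surfs,
                                               mass_tolerance=1e-6)
        i = np.argmax(expected)
        # Monte-Carlo agreement at the peak (few percent at 40 trials)
        assert mean_total[i] == pytest.approx(expected[i], rel=0.10)

    def test_surfaces_spread_evenly_over_compartments(self, params):
        per_comp = np.bincount(
            [s * params.n_x // params.N_surfs for s in range(params.N_surfs)],
            minlength=params.n_x)
        assert per_comp.min() >= params.N_surfs // params.n_x
        assert per_comp.max() <= params.N_surfs // params.n_x + 1
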