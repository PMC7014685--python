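import numpy as np
import pytest

import rodcascade as rc
from rodcascade.disc_bulk import (gstar_lower_bound, mean_disc_bulk,
                                  simulate_disc_bulk,
                                  simulate_from_initial_gstar,
                                  timeshift_mean_trace)


class TestSimulateDiscBulk:
    def test_no_isomerizations_gives_silent_disc(self, params):
        tr = simulate_disc_bulk(0, params, t_end=1.0, timelines=[])
        assert np.all(tr.G_star == 0)
        assert np.all(tr.E_starstar == 0)
        assert np.all(tr.E == params.E_tot)

    def test_pde_conservation_exact(self, params):
        tr = simulate_disc_bulk(10, params, t_end=4.0, seed=3)
        assert np.max(np.abs(tr.E_total_check - params.E_tot)) < 1e-6 * params.E_tot

    def test_states_nonnegative(self, params):
        tr = simulate_disc_bulk(20, params, t_end=6.0, seed=4)
        for arr in (tr.G_star, tr.E, tr.E_star, tr.E_starstar):
            assert arr.min() >= 0.0

    def test_mean_tail_time_constant(self, params):
        m = mean_disc_bulk(10, params, t_end=6.0, n_trials=150, seed=11)
        tau = rc.fit_tail_time_constant(m.t, m.E_starstar, window=(0.5, 5.0))
        assert tau == pytest.approx(1.0 / params.k_Estst, rel=0.02)

    def test_timeline_longer_than_run_flags_warning(self, params):
        tls = [rc.RStarTimeline(0.0, 2.0)]
        tr = simulate_disc_bulk(1, params, t_end=0.5, timelines=tls)
        assert "warning" in tr.meta

    def test_recovery_shifts_later_with_Q(self, params):
        # later escape of E** below the saturation level as Q grows
        crossings = []
        for q in (6, 10, 20, 40):
            m = mean_disc_bulk(q, params, t_end=8.0, n_trials=120, seed=100 + q)
            below = np.nonzero(m.E_starstar <= 2.6)[0]
            tail = below[below > np.argmax(m.E_starstar)]
            crossings.append(m.t[tail[0]])
        assert all(b > a for a, b in zip(crossings, crossings[1:]))


class TestInitialGstarRelaxation:
    def test_lower_bound_holds_during_saturation(self, params):
        # the closed form assumes E** ~ E_tot, so anchor it where the
        # PDE first saturates (the loading transient consumes ~2*E_tot
        # extra G* that the bound does not account for)
        tr = simulate_from_initial_gstar(10_000.0, params, t_end=6.0)
        sat = np.nonzero(tr.E_starstar > 0.95 * params.E_tot)[0]
        i0 = sat[0]
        bound = gstar_lower_bound(tr.t[sat] - tr.t[i0], tr.G_star[i0], params)
        assert np.all(tr.G_star[sat] >= bound - 1e-6)
        # and the bound is tight: within 5% of the solution mid-decay
        mid = len(sat) // 2
        assert bound[mid] == pytest.approx(tr.G_star[sat[mid]], rel=0.05)

    def test_bound_anchors(self, params):
        assert gstar_lower_bound(0.0, 1234.0, params) == pytest.approx(1234.0)
        # with negligible E** drain the bound degenerates to pure decay
        p = params.replace(k_Estst=1e-12)
        t = np.linspace(0, 3, 10)
        assert np.allclose(gstar_lower_bound(t, 5000.0, p),
                           5000.0 * np.exp(-params.k_Gst * t), rtol=1e-9)

    def test_tiny_bolus_leaves_pde_inactive(self, params):
        tr = simulate_from_initial_gstar(1e-6, params, t_end=1.0)
        assert tr.E_starstar.max() < 1e-6

    def test_total_activated_transducin_nonincreasing(self, params):
        tr = simulate_from_initial_gstar(10_000.0, params, t_end=6.0)
        total = tr.G_star + tr.E_star + 2 * tr.E_starstar
        assert np.all(np.diff(total) <= 1e-6)


class TestTimeshiftFastPath:
    def test_rejects_small_Q(self, params):
        with pytest.raises(ValueError):
            timeshift_mean_trace(4, params)

    def test_single_quantile_is_pure_shift(self, params):
        base = simulate_from_initial_gstar(10_000.0, params, t_end=10.0)
        m = timeshift_mean_trace(12, params, base_trace=base, n_weights=1)
        # with one quantile the output must be the base waveform shifted
        # by a constant; verify against a manual reconstruction
        from rodcascade.rstar import (cumulative_gstar_created,
                                      lifetime_sum_distribution)
        total = lifetime_sum_distribution(12, params.M, params.mu).ppf(0.5)
        g0 = cumulative_gstar_created(total, params.nu_Gst, params.G0_surface,
                                      params.K_m_dep)
        base_total = base.G_star + base.E_star + 2 * base.E_starstar
        shift = np.interp(-g0, -base_total, base.t)
        off = m.meta["t_offset"]
        expect = np.interp(m.t - off + shift, base.t, base.E_starstar,
                           right=base.E_starstar[-1])
        expect[m.t < off] = 0.0
        assert np.max(np.abs(m.E_starstar - expect)) < 1e-9

    def test_weights_normalized(self, params):
        m = timeshift_mean_trace(10, params, n_weights=64)
        assert m.meta["weights_sum"] == pytest.approx(1.0, abs=1e-8)

    def test_matches_bulk_mean_in_tail(self, params):
        m_fast = timeshift_mean_trace(10, params, n_weights=400)
        m_ref = mean_disc_bulk(10, params, t_end=10.0, n_trials=1000, seed=21)
        w = (m_ref.t > 0.5) & (m_ref.t <= m_fast.t[-1])
        fast = np.interp(m_ref.t[w], m_fast.t, m_fast.E_starstar)
        assert np.max(np.abs(fast - m_ref.E_starstar[w])) < 3.0
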