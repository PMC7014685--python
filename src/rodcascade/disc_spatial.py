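"""Full 2D lattice simulation of disc-membrane reactions: method 1.

Molecules perform nearest-neighbour random walks on a square lattice
(spacing dx, tick dt) restricted to the inscribed circular disc, with
reflecting boundary. A molecule of diffusion coefficient D moves with
total probability 4*D*dt/dx^2 per tick (direction uniform), matching
D = dx^2 * p_move / (4 dt). Reactions are diffusion limited: a G* and a
reactable PDE molecule react on first co-occupancy of a lattice site
after a move. While an R* is active it emits G* at its current position
as a Poisson process at rate nu_G* * activity, thinned by the
G-protein depletion factor of the shared surface pool.

Per-molecule Bernoulli move/decay decisions are realized exactly (to
O(p^2) per tick) by drawing the number of events from a binomial and
assigning them to uniformly chosen molecules, which avoids scanning
every molecule every tick.

A second kernel reproduces the transducin-depletion experiment: R* and
explicitly diffusing G holomers only (PDE removed, all shut-off
disabled), a stochastic activation delay of mean 1/nu_G* following each
R*-G contact, and the cumulative G* count as output.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from .params import CascadeParams
from .rstar import sample_timelines
from .traces import DiscTrace

__all__ = ["simulate_disc_2d", "mean_disc_2d", "simulate_depletion_experiment"]

_OFF = np.array([[1, 0], [-1, 0], [0, 1], [0, -1]], dtype=np.int64)


@njit(cache=True)
def _disc_kernel(seed, n_ticks, sample_every,
                 rx, ry, r_act, r_off_tick,
                 px, py, pstate,
                 p_move_R, p_move_G, p_move_E, p_move_Es,
                 nu_dt, p_dec_G, p_dec_Es, p_dec_Ess,
                 G0, Km, R_sites,
                 out_counts, out_free_g, out_cum, out_ract):
    np.random.seed(seed)
    W = 2 * R_sites + 1
    R2 = R_sites * R_sites
    nP = px.shape[0]
    nR = rx.shape[0]
    pde_grid = -np.ones((W, W), dtype=np.int64)
    g_grid = -np.ones((W, W), dtype=np.int64)
    for q in range(nP):
        pde_grid[px[q], py[q]] = q
    cap = int(G0) + 4
    gx = np.zeros(cap, dtype=np.int64)
    gy = np.zeros(cap, dtype=np.int64)
    nG = 0
    cum = 0
    n_samples = out_counts.shape[1]
    isamp = 0
    for tick in range(n_ticks + 1):
        if tick % sample_every == 0 and isamp < n_samples:
            nE = 0
            nEs = 0
            nEss = 0
            for q in range(nP):
                s = pstate[q]
                if s == 0:
                    nE += 1
                elif s == 1:
                    nEs += 1
                else:
                    nEss += 1
            out_counts[0, isamp] = nE
            out_counts[1, isamp] = nEs
            out_counts[2, isamp] = nEss
            out_free_g[isamp] = nG
            out_cum[isamp] = cum
            nact = 0
            for i in range(nR):
                if tick < r_off_tick[i]:
                    nact += 1
            out_ract[isamp] = nact
            isamp += 1
        if tick == n_ticks:
            break
        # --- R*: G* emission then movement (inert after shut-off) -------
        g_rem = (G0 - cum) / G0
        if g_rem < 0.0:
            g_rem = 0.0
        fdep = (g_rem / (g_rem + Km)) * (1.0 + Km)
        for i in range(nR):
            if tick >= r_off_tick[i]:
                continue
            if np.random.random() < nu_dt * r_act[i] * fdep and cum < G0:
                gx[nG] = rx[i]
                gy[nG] = ry[i]
                if g_grid[rx[i], ry[i]] < 0:
                    g_grid[rx[i], ry[i]] = nG
                nG += 1
                cum += 1
            if np.random.random() < p_move_R:
                d = np.random.randint(0, 4)
                nx = rx[i] + _OFF[d, 0]
                ny = ry[i] + _OFF[d, 1]
                cx = nx - R_sites
                cy = ny - R_sites
                if cx * cx + cy * cy <= R2:
                    rx[i] = nx
                    ry[i] = ny
        # --- free G*: moves (with reaction on contact) ------------------
        if nG > 0:
            kmv = np.random.binomial(nG, p_move_G)
            for _ in range(kmv):
                if nG == 0:
                    break
                r = int(np.random.random() * (4.0 * nG))  # fused index+direction
                idx = r >> 2
                d = r & 3
                ox, oy = gx[idx], gy[idx]
                nx = ox + _OFF[d, 0]
                ny = oy + _OFF[d, 1]
                cx = nx - R_sites
                cy = ny - R_sites
                if cx * cx + cy * cy > R2:
                    continue
                if g_grid[ox, oy] == idx:
                    g_grid[ox, oy] = -1
                q = pde_grid[nx, ny]
                if q >= 0 and pstate[q] < 2:
                    # diffusion-limited binding: consume this G*
                    pstate[q] += 1
                    last = nG - 1
                    if idx != last:
                        gx[idx] = gx[last]
                        gy[idx] = gy[last]
                        if g_grid[gx[last], gy[last]] == last:
                            g_grid[gx[last], gy[last]] = idx
                    nG = last
                else:
                    gx[idx] = nx
                    gy[idx] = ny
                    g_grid[nx, ny] = idx
        # --- free G* decay (single-event Bernoulli: nG*p ~ 1e-3 per tick,
        # multi-event probability O((nG*p)^2) is negligible) -------------
        if nG > 0:
            if np.random.random() < nG * p_dec_G:
                idx = int(np.random.random() * nG)
                if g_grid[gx[idx], gy[idx]] == idx:
                    g_grid[gx[idx], gy[idx]] = -1
                last = nG - 1
                if idx != last:
                    gx[idx] = gx[last]
                    gy[idx] = gy[last]
                    if g_grid[gx[last], gy[last]] == last:
                        g_grid[gx[last], gy[last]] = idx
                nG = last
        # --- PDE moves (state-dependent rate via thinning) ---------------
        kmv = np.random.binomial(nP, p_move_E)
        for _ in range(kmv):
            r = int(np.random.random() * (4.0 * nP))  # fused index+direction
            q = r >> 2
            d = r & 3
            if pstate[q] != 0 and np.random.random() >= p_move_Es / p_move_E:
                continue
            ox, oy = px[q], py[q]
            nx = ox + _OFF[d, 0]
            ny = oy + _OFF[d, 1]
            cx = nx - R_sites
            cy = ny - R_sites
            if cx * cx + cy * cy > R2:
                continue
            if pde_grid[ox, oy] == q:
                pde_grid[ox, oy] = -1
            px[q] = nx
            py[q] = ny
            pde_grid[nx, ny] = q
            if pstate[q] < 2:
                idx = g_grid[nx, ny]
                if idx >= 0:
                    pstate[q] += 1
                    g_grid[nx, ny] = -1
                    last = nG - 1
                    if idx != last:
                        gx[idx] = gx[last]
                        gy[idx] = gy[last]
                        if g_grid[gx[last], gy[last]] == last:
                            g_grid[gx[last], gy[last]] = idx
                    nG = last
        # --- PDE shut-off steps E** -> E* -> E (thinned; single-event
        # Bernoulli, nP*p ~ 3e-4 per tick) --------------------------------
        if np.random.random() < nP * p_dec_Ess:
            q = int(np.random.random() * nP)
            if pstate[q] == 2:
                pstate[q] = 1
            elif pstate[q] == 1:
                if np.random.random() < p_dec_Es / p_dec_Ess:
                    pstate[q] = 0
    return cum


@njit(cache=True)
def _depletion_kernel(seed, n_ticks, sample_every,
                      rx, ry, r_busy_until,
                      hx, hy,
                      p_move_R, p_move_G, delay_ticks_mean,
                      R_sites, out_cum):
    """R* + diffusing G holomers only; all shut-off disabled, PDE absent."""
    np.random.seed(seed)
    W = 2 * R_sites + 1
    R2 = R_sites * R_sites
    nR = rx.shape[0]
    nH = hx.shape[0]
    r_grid = -np.ones((W, W), dtype=np.int64)
    h_grid = -np.ones((W, W), dtype=np.int64)
    for i in range(nR):
        r_grid[rx[i], ry[i]] = i
    for j in range(nH):
        h_grid[hx[j], hy[j]] = j
    cum = 0
    isamp = 0
    n_samples = out_cum.shape[0]
    for tick in range(n_ticks + 1):
        if tick % sample_every == 0 and isamp < n_samples:
            out_cum[isamp] = cum
            isamp += 1
        if tick == n_ticks:
            break
        # completions
        for i in range(nR):
            if r_busy_until[i] > 0 and tick >= r_busy_until[i]:
                r_busy_until[i] = 0
                cum += 1
                # immediately check for a holomer co-occupying this site
                j = h_grid[rx[i], ry[i]]
                if j >= 0:
                    h_grid[rx[i], ry[i]] = -1
                    last = nH - 1
                    if j != last:
                        hx[j] = hx[last]
                        hy[j] = hy[last]
                        if h_grid[hx[last], hy[last]] == last:
                            h_grid[hx[last], hy[last]] = j
                    nH = last
                    r_busy_until[i] = tick + 1 + int(
                        -math.log(1.0 - np.random.random()) * delay_ticks_mean)
        # R* moves
        for i in range(nR):
            if np.random.random() < p_move_R:
                ox, oy = rx[i], ry[i]
                d = np.random.randint(0, 4)
                nx = ox + _OFF[d, 0]
                ny = oy + _OFF[d, 1]
                cx = nx - R_sites
                cy = ny - R_sites
                if cx * cx + cy * cy > R2:
                    continue
                if r_grid[ox, oy] == i:
                    r_grid[ox, oy] = -1
                rx[i] = nx
                ry[i] = ny
                r_grid[nx, ny] = i
                if r_busy_until[i] == 0:
                    j = h_grid[nx, ny]
                    if j >= 0:
                        h_grid[nx, ny] = -1
                        last = nH - 1
                        if j != last:
                            hx[j] = hx[last]
                            hy[j] = hy[last]
                            if h_grid[hx[last], hy[last]] == last:
                                h_grid[hx[last], hy[last]] = j
                        nH = last
                        r_busy_until[i] = tick + 1 + int(
                            -math.log(1.0 - np.random.random())
                            * delay_ticks_mean)
        # holomer moves
        if nH > 0:
            kmv = np.random.binomial(nH, p_move_G)
            for _ in range(kmv):
                if nH == 0:
                    break
                r = int(np.random.random() * (4.0 * nH))  # fused index+direction
                j = r >> 2
                d = r & 3
                ox, oy = hx[j], hy[j]
                nx = ox + _OFF[d, 0]
                ny = oy + _OFF[d, 1]
                cx = nx - R_sites
                cy = ny - R_sites
                if cx * cx + cy * cy > R2:
                    continue
                if h_grid[ox, oy] == j:
                    h_grid[ox, oy] = -1
                i = r_grid[nx, ny]
                if i >= 0 and r_busy_until[i] == 0:
                    r_busy_until[i] = tick + 1 + int(
                        -math.log(1.0 - np.random.random()) * delay_ticks_mean)
                    last = nH - 1
                    if j != last:
                        hx[j] = hx[last]
                        hy[j] = hy[last]
                        if h_grid[hx[last], hy[last]] == last:
                            h_grid[hx[last], hy[last]] = j
                    nH = last
                else:
                    hx[j] = nx
                    hy[j] = ny
                    h_grid[nx, ny] = j
    return cum


# ---------------------------------------------------------------------------
# Wrappers
# ---------------------------------------------------------------------------

def _uniform_disc_sites(n, R_sites, rng):
    """n lattice sites uniformly distributed inside the inscribed circle."""
    xs = np.empty(n, dtype=np.int64)
    ys = np.empty(n, dtype=np.int64)
    got = 0
    while got < n:
        m = 2 * (n - got) + 8
        cand = rng.integers(-R_sites, R_sites + 1, size=(m, 2))
        ok = cand[:, 0] ** 2 + cand[:, 1] ** 2 <= R_sites ** 2
        cand = cand[ok][: n - got]
        xs[got:got + len(cand)] = cand[:, 0] + R_sites
        ys[got:got + len(cand)] = cand[:, 1] + R_sites
        got += len(cand)
    return xs, ys


def _lattice_constants(params: CascadeParams):
    dx_um = params.dx * 1e-3
    dt_s = params.dt * 1e-6
    R_sites = int(round(params.d / 2.0 / dx_um))
    mob = dt_s / dx_um ** 2  # p_move = 4 * D * mob
    return R_sites, dt_s, mob


def simulate_disc_2d(Q: int, params: CascadeParams, t_end: float,
                     seed=None, timelines=None, sample_dt: float = 1e-3,
                     rng: np.random.Generator | None = None) -> DiscTrace:
    """One method-1 trial: full 2D lattice simulation for Q isomerizations."""
    p = params
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    if Q < 0:
        raise ValueError("Q must be >= 0")
    if Q > p.G0_surface:
        raise ValueError("Q exceeds the disc G-protein capacity")
    if rng is None:
        rng = np.random.default_rng(seed)
    if timelines is None:
        timelines = sample_timelines(Q, p, rng)
    elif len(timelines) != Q:
        raise ValueError("len(timelines) must equal Q")

    R_sites, dt_s, mob = _lattice_constants(p)
    n_ticks = int(round(t_end / dt_s))
    sample_every = max(1, int(round(sample_dt / dt_s)))
    n_samples = n_ticks // sample_every + 1

    rx, ry = _uniform_disc_sites(Q, R_sites, rng)
    px, py = _uniform_disc_sites(p.E_tot, R_sites, rng)
    pstate = np.zeros(p.E_tot, dtype=np.int64)
    r_act = np.array([tl.activity for tl in timelines], dtype=np.float64)
    r_off = np.array([int(round(tl.t_off / dt_s)) for tl in timelines],
                     dtype=np.int64)

    out_counts = np.zeros((3, n_samples), dtype=np.int64)
    out_free_g = np.zeros(n_samples, dtype=np.int64)
    out_cum = np.zeros(n_samples, dtype=np.int64)
    out_ract = np.zeros(n_samples, dtype=np.int64)

    kseed = int(rng.integers(0, 2 ** 31 - 1))
    _disc_kernel(kseed, n_ticks, sample_every,
                 rx, ry, r_act, r_off,
                 px, py, pstate,
                 4 * p.D_Rst * mob, 4 * p.D_Gst * mob, 4 * p.D_E * mob,
                 4 * p.D_Est * mob,
                 p.nu_Gst * dt_s, p.k_Gst * dt_s, p.k_Est * dt_s,
                 p.k_Estst * dt_s,
                 float(p.G0_surface), p.K_m_dep, R_sites,
                 out_counts, out_free_g, out_cum, out_ract)

    t = np.arange(n_samples) * sample_every * dt_s
    meta = {"method": 1, "Q": Q, "cumulative_G_star": out_cum,
            "timelines": [(tl.t_on, tl.t_off, tl.activity, tl.is_aberrant)
                          for tl in timelines]}
    longest = max((tl.t_off for tl in timelines), default=0.0)
    if longest > t_end:
        meta["warning"] = "t_end shorter than longest R* timeline"
    return DiscTrace(t=t, G_star=out_free_g.astype(float),
                     E=out_counts[0].astype(float),
                     E_star=out_counts[1].astype(float),
                     E_starstar=out_counts[2].astype(float),
                     R_star=out_ract.astype(float), meta=meta)


def mean_disc_2d(Q: int, params: CascadeParams, t_end: float, n_trials: int,
                 seed=None, timelines_per_trial=None,
                 sample_dt: float = 1e-3) -> DiscTrace:
    """Trial-averaged method-1 disc trace for fixed Q."""
    ss = np.random.SeedSequence(seed)
    acc = None
    for i, child in enumerate(ss.spawn(n_trials)):
        rng = np.random.default_rng(child)
        tls = timelines_per_trial[i] if timelines_per_trial is not None else None
        tr = simulate_disc_2d(Q, params, t_end, timelines=tls, rng=rng,
                              sample_dt=sample_dt)
        stack = np.vstack([tr.G_star, tr.E, tr.E_star, tr.E_starstar])
        acc = stack if acc is None else acc + stack
    acc /= n_trials
    return DiscTrace(t=tr.t, G_star=acc[0], E=acc[1], E_star=acc[2],
                     E_starstar=acc[3],
                     meta={"method": 1, "n_trials": n_trials, "Q": Q})


def simulate_depletion_experiment(Q: int, params: CascadeParams, t_end: float,
                                  seed=None, sample_dt: float = 1e-3,
                                  rng: np.random.Generator | None = None):
    """Cumulative G* creation with shut-off disabled and PDE removed.

    Q permanently active R* interact with the full complement of
    explicitly diffusing G holomers; each R*-G contact is followed by a
    stochastic (exponential) activation delay of mean 1/nu_G*. Returns
    ``(t, cumulative_G_star)`` arrays for one trial.
    """
    p = params
    if Q < 1:
        raise ValueError("Q must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    R_sites, dt_s, mob = _lattice_constants(p)
    n_ticks = int(round(t_end / dt_s))
    sample_every = max(1, int(round(sample_dt / dt_s)))
    n_samples = n_ticks // sample_every + 1

    rx, ry = _uniform_disc_sites(Q, R_sites, rng)
    hx, hy = _uniform_disc_sites(p.G0_surface, R_sites, rng)
    r_busy = np.zeros(Q, dtype=np.int64)
    out_cum = np.zeros(n_samples, dtype=np.int64)
    kseed = int(rng.integers(0, 2 ** 31 - 1))
    _depletion_kernel(kseed, n_ticks, sample_every, rx, ry, r_busy, hx, hy,
                      4 * p.D_Rst * mob, 4 * p.D_Gst * mob,
                      (1.0 / p.nu_Gst) / dt_s, R_sites, out_cum)
    t = np.arange(n_samples) * sample_every * dt_s
    return t, out_cum.astype(float)
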