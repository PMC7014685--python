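"""Cytoplasmic cGMP/Ca2+ dynamics and the circulating photocurrent.

The E** drive produced by the disc engines enters the cGMP balance

    d cG/dt = alpha(Ca) - (beta_dark + beta_E** * E**_tot(t)) * cG

with GCAP-regulated cyclase alpha(Ca) = alpha_max / (1 + (Ca/K_GCAP)^m),
CNG-channel current J_cG = J_cG_max cG^n/(cG^n + K_cG^n) and exchanger
current J_ex = J_ex_max Ca/(Ca + K_ex). Calcium follows

    d Ca/dt = [ f_Ca J_cG / (2 F V_cyto) - J_ex / (F V_cyto) ] / B_Ca

(Ca2+ carries two charges through the CNG channel; the exchanger
stoichiometry is folded into J_ex_max). The outer segment is treated
either as a single lumped compartment, or as n_x longitudinal
compartments coupled by cGMP and Ca2+ diffusion with no-flux ends, each
carrying 1/n_x of the membrane conductances.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp

from .params import (CascadeParams, DarkState, ParameterError, cng_current,
                     cyclase_rate, exchanger_current, solve_dark_state,
                     FARADAY)
from .traces import OuterSegmentActivity, OuterSegmentTrace

__all__ = [
    "integrate_single_compartment",
    "integrate_longitudinal",
    "dark_adapt",
]


def _pa_to_nM_per_s(params: CascadeParams) -> float:
    """Concentration rate (nM/s) produced by 1 pA of monovalent flux
    into the cytoplasmic volume."""
    v_litre = params.V_cyto * 1e-12
    return 1e-12 / (FARADAY * v_litre) * 1e9


def _as_drive(drive, t_end):
    """Normalize a drive spec to a callable t -> E**_total."""
    if callable(drive):
        return drive
    t_arr, e_arr = drive
    t_arr = np.asarray(t_arr, dtype=float)
    e_arr = np.asarray(e_arr, dtype=float)
    if t_arr[-1] < t_end - 1e-9:
        raise ValueError("drive is undefined on part of the requested interval")

    def f(t):
        return np.interp(t, t_arr, e_arr)

    return f


def integrate_single_compartment(Estarstar_total, params: CascadeParams,
                                 dark: DarkState | None = None,
                                 t_end: float = 5.0,
                                 sample_dt: float = 1e-3,
                                 rtol: float = 1e-8,
                                 atol: float = 1e-8,
                                 max_step: float = 5e-3) -> OuterSegmentTrace:
    """Integrate the lumped-compartment downstream model.

    ``Estarstar_total`` is the whole-outer-segment E** drive: either a
    callable of time or a ``(t, E**)`` array pair covering [0, t_end].
    """
    p = params
    if dark is None:
        dark = solve_dark_state(p)
    drive = _as_drive(Estarstar_total, t_end)
    conv = _pa_to_nM_per_s(p)

    def rhs(t, y):
        cG, Ca = y
        cG = max(cG, 0.0)
        Ca = max(Ca, 0.0)
        beta = p.beta_dark + p.beta_Estst * drive(t)
        dcG = cyclase_rate(Ca, p) - beta * cG
        dCa = conv * (p.f_Ca * cng_current(cG, p) / 2.0
                      - exchanger_current(Ca, p)) / p.B_Ca
        return (dcG, dCa)

    t_grid = np.arange(0.0, t_end + 0.5 * sample_dt, sample_dt)
    # max_step bounds the solver so it cannot leap over a delayed drive
    # onset while the state still sits at the dark equilibrium
    sol = solve_ivp(rhs, (0.0, t_end), [dark.cG, dark.Ca], method="LSODA",
                    t_eval=t_grid, rtol=rtol, atol=atol, max_step=max_step)
    if not sol.success:
        raise RuntimeError(f"downstream integration failed: {sol.message}")
    cG, Ca = sol.y
    J = cng_current(cG, p) + exchanger_current(Ca, p)
    return OuterSegmentTrace(t=t_grid, J=np.asarray(J), J_dark=dark.J,
                             cG=cG, Ca=Ca,
                             meta={"mode": "single"})


def integrate_longitudinal(activity: OuterSegmentActivity,
                           params: CascadeParams,
                           dark: DarkState | None = None,
                           t_end: float | None = None,
                           sample_dt: float = 1e-3,
                           rtol: float = 1e-7,
                           atol: float = 1e-7,
                           max_step: float = 5e-3) -> OuterSegmentTrace:
    """Method-of-lines integration with longitudinal diffusion.

    Each of the n_x compartments carries 1/n_x of the CNG and exchanger
    conductances and receives its own E** drive; cGMP and Ca2+ diffuse
    along the outer-segment axis with no-flux boundary conditions.
    """
    p = params
    nx = p.n_x
    if activity.per_compartment.shape[0] != nx:
        raise ValueError("activity compartment count does not match n_x")
    if dark is None:
        dark = solve_dark_state(p)
    if t_end is None:
        t_end = float(activity.t[-1])
    if activity.t[-1] < t_end - 1e-9:
        raise ValueError("drive is undefined on part of the requested interval")
    h = p.L / nx
    lam_cG = p.D_cG / h ** 2
    lam_Ca = p.D_Ca / h ** 2
    conv = _pa_to_nM_per_s(p) * nx  # per-compartment volume is V_cyto/nx
    drive_t = activity.t
    drive = activity.per_compartment

    def drive_at(t):
        k = np.searchsorted(drive_t, t) - 1
        k = min(max(k, 0), len(drive_t) - 2)
        w = (t - drive_t[k]) / (drive_t[k + 1] - drive_t[k])
        return drive[:, k] + w * (drive[:, k + 1] - drive[:, k])

    def laplacian(c):
        out = np.empty_like(c)
        out[1:-1] = c[:-2] - 2.0 * c[1:-1] + c[2:]
        out[0] = c[1] - c[0]          # no-flux ends
        out[-1] = c[-2] - c[-1]
        return out

    def rhs(t, y):
        cG = np.clip(y[:nx], 0.0, None)
        Ca = np.clip(y[nx:], 0.0, None)
        e_comp = drive_at(t)
        beta = p.beta_dark + p.beta_Estst * nx * e_comp
        J_cG_i = cng_current(cG, p) / nx
        J_ex_i = exchanger_current(Ca, p) / nx
        dcG = cyclase_rate(Ca, p) - beta * cG + lam_cG * laplacian(cG)
        dCa = (conv * (p.f_Ca * J_cG_i / 2.0 - J_ex_i) / p.B_Ca
               + lam_Ca * laplacian(Ca))
        return np.concatenate([dcG, dCa])

    t_grid = np.arange(0.0, t_end + 0.5 * sample_dt, sample_dt)
    y0 = np.concatenate([np.full(nx, dark.cG), np.full(nx, dark.Ca)])
    sol = solve_ivp(rhs, (0.0, t_end), y0, method="LSODA", t_eval=t_grid,
                    rtol=rtol, atol=atol, max_step=max_step)
    if not sol.success:
        raise RuntimeError(f"downstream integration failed: {sol.message}")
    cG = sol.y[:nx]
    Ca = sol.y[nx:]
    J = (cng_current(cG, p).sum(axis=0) + exchanger_current(Ca, p).sum(axis=0)) / nx
    return OuterSegmentTrace(t=t_grid, J=np.asarray(J), J_dark=dark.J,
                             cG=cG, Ca=Ca, meta={"mode": "spatial"})


def dark_adapt(params: CascadeParams, verify_time: float = 5.0,
               tol: float = 1e-6) -> DarkState:
    """Solve the dark state and verify it is a fixed point of the
    drive-free downstream integrator."""
    dark = solve_dark_state(params)
    tr = integrate_single_compartment(lambda t: 0.0, params, dark,
                                      t_end=verify_time, rtol=1e-10,
                                      atol=1e-10)
    drift = np.max(np.abs(tr.J / dark.J - 1.0))
    if drift > tol:
        raise ParameterError(
            f"dark state is not stationary (relative drift {drift:.2e})")
    return dark
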