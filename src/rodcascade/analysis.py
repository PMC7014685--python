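"""Response-derived statistics: rising-phase fits, super-linearity,
time-in-saturation and dominant time constants.

The bright-flash recovery is characterized by the time T_sat the
photocurrent stays suppressed below a criterion fraction (default 10%)
of the dark current. Plotted against ln(flash intensity), T_sat shows
two quasi-linear regimes whose slopes are the first and second
"dominant time constants"; the dimeric-activation model predicts the
low-intensity regime to be curved, with tangent slope
(1 + rho*Phi/N_surfs)/k_E** set by the super-linearity parameter rho of
the E** tail amplitudes R_Q = R1 * Q * (1+rho)^(Q-1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import linregress

from .params import CascadeParams
from .traces import DiscTrace, OuterSegmentTrace

__all__ = [
    "RisingPhaseFit",
    "SuperlinearityFit",
    "TsatCurve",
    "doubly_delayed_ramp",
    "fit_rising_phase",
    "fit_superlinearity",
    "measure_tsat",
    "tsat_curve",
    "tsat_prediction",
    "tsat_tangent_slope",
    "fit_tail_time_constant",
]


# ---------------------------------------------------------------------------
# Rising phase
# ---------------------------------------------------------------------------

def doubly_delayed_ramp(t, Q, nu_Estst, tau1, tau2):
    """Ramp Q*nu_E***t convolved with two exponential delay stages.

    E**(t) = Q nu { t - (tau1+tau2)
                    + (tau1^2 e^{-t/tau1} - tau2^2 e^{-t/tau2})/(tau1-tau2) }
    for t > 0 (and 0 before).
    """
    t = np.asarray(t, dtype=float)
    if abs(tau1 - tau2) < 1e-12 * max(tau1, tau2):
        raise ValueError("delay stages must have distinct time constants")
    core = (t - (tau1 + tau2)
            + (tau1 ** 2 * np.exp(-t / tau1) - tau2 ** 2 * np.exp(-t / tau2))
            / (tau1 - tau2))
    return np.where(t > 0, Q * nu_Estst * core, 0.0)


@dataclass(frozen=True)
class RisingPhaseFit:
    nu_Estst: float          # E** creation rate per R* per surface, s^-1
    tau1: float              # fixed short delay 1/nu_G*, s
    tau2: float              # fitted longer delay, s
    Q: int
    n_points: int
    residual_norm: float
    ellipse: tuple = (0.030, 0.35)   # (time radius s, fraction of E_tot)


def fit_rising_phase(mean_trace: DiscTrace, Q: int, params: CascadeParams,
                     ellipse_t: float = 0.030,
                     ellipse_frac: float = 0.35) -> RisingPhaseFit:
    """Least-squares fit of the doubly delayed ramp to an E** onset.

    tau1 is held at 1/nu_G*; only points inside the elliptical region
    (t/ellipse_t)^2 + (E**/(ellipse_frac*E_tot))^2 <= 1 with t >= 0
    enter the fit.
    """
    p = params
    tau1 = 1.0 / p.nu_Gst
    t = mean_trace.t
    e = mean_trace.E_starstar
    if t[1] - t[0] > 1.001e-3 or t[-1] < ellipse_t - 1e-9:
        raise ValueError("trace must cover the fit region at <= 1 ms sampling")
    e_rad = ellipse_frac * p.E_tot
    inside = (t >= 0) & ((t / ellipse_t) ** 2 + (e / e_rad) ** 2 <= 1.0)
    if inside.sum() < 5:
        raise ValueError("fewer than 5 data points inside the fit region")

    def model(tt, nu, tau2):
        return doubly_delayed_ramp(tt, Q, nu, tau1, tau2)

    popt, _ = curve_fit(model, t[inside], e[inside], p0=(400.0, 5e-3),
                        bounds=([1e-3, 1e-5], [1e5, 0.5]), maxfev=20000)
    resid = model(t[inside], *popt) - e[inside]
    return RisingPhaseFit(nu_Estst=float(popt[0]), tau1=tau1,
                          tau2=float(popt[1]), Q=Q,
                          n_points=int(inside.sum()),
                          residual_norm=float(np.linalg.norm(resid)),
                          ellipse=(ellipse_t, ellipse_frac))


# ---------------------------------------------------------------------------
# Super-linearity of the E** tails
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SuperlinearityFit:
    rho: float               # super-linearity parameter
    R1: float                # single-isomerization tail amplitude, E**
    t_measure: float = 0.7   # measurement time, s


def fit_superlinearity(tail_amplitudes: dict[int, float],
                       t_measure: float = 0.7,
                       Q_max: int = 4) -> SuperlinearityFit:
    """Fit R_Q = R1 * Q * (1+rho)^(Q-1) to tail amplitudes at fixed time.

    The fit is linear in log space: ln(R_Q/Q) = ln R1 + (Q-1) ln(1+rho),
    using Q <= Q_max (the regime where PDE saturation does not compress
    the amplitudes).
    """
    qs = sorted(q for q in tail_amplitudes if 1 <= q <= Q_max)
    if not {1, 2, 3, 4}.issubset(qs):
        raise ValueError("tail amplitudes for Q = 1..4 are required")
    amps = np.array([tail_amplitudes[q] for q in qs], dtype=float)
    if np.any(amps <= 0):
        raise ValueError("tail amplitudes must be positive")
    x = np.array(qs, dtype=float) - 1.0
    y = np.log(amps / np.array(qs, dtype=float))
    res = linregress(x, y)
    return SuperlinearityFit(rho=float(np.exp(res.slope) - 1.0),
                             R1=float(np.exp(res.intercept)),
                             t_measure=t_measure)


# ---------------------------------------------------------------------------
# Time in saturation
# ---------------------------------------------------------------------------

def measure_tsat(response: OuterSegmentTrace,
                 criterion: float = 0.10) -> float | None:
    """Time of final escape from saturation.

    T_sat = max{t : J(t) <= criterion * J_dark}, located by linear
    interpolation between samples; returns None if the response never
    reaches the criterion level ("not saturated").
    """
    J = response.J
    thresh = criterion * response.J_dark
    below = J <= thresh
    if not below.any():
        return None
    i = int(np.nonzero(below)[0][-1])
    t = response.t
    if i == len(t) - 1 or J[i] == thresh:
        return float(t[i])
    # upward crossing between samples i and i+1
    return float(t[i] + (thresh - J[i]) * (t[i + 1] - t[i]) / (J[i + 1] - J[i]))


@dataclass
class TsatCurve:
    Phi: np.ndarray                  # flash intensities, R* per rod
    T_sat: np.ndarray                # time in saturation, s
    criterion: float
    tau_D1: float                    # slope of low-intensity line, s
    tau_D2: float                    # slope of high-intensity line, s
    Phi_trans: float                 # intersection intensity, R* per rod
    window_low: tuple
    window_high: tuple
    poly_log10: np.ndarray | None = None   # optional smoothing polynomial
    excluded: list = field(default_factory=list)


def tsat_curve(intensities, response_fn, criterion: float = 0.10,
               window_low=(300.0, 3000.0), window_high=(10000.0, 62500.0),
               smooth_poly_order: int | None = None) -> TsatCurve:
    """Measure T_sat over a set of intensities and fit the two lines.

    ``response_fn(Phi)`` must return an :class:`OuterSegmentTrace`.
    Straight lines are fitted by ordinary least squares in
    (ln Phi, T_sat) over the two windows; their slopes are the dominant
    time constants tau_D1/tau_D2 and their intersection Phi_trans.
    Non-saturating intensities are excluded (recorded in ``excluded``).
    """
    intensities = np.asarray(sorted(intensities), dtype=float)
    phis, tsats, excluded = [], [], []
    for Phi in intensities:
        ts = measure_tsat(response_fn(Phi), criterion)
        if ts is None:
            excluded.append(float(Phi))
            continue
        phis.append(Phi)
        tsats.append(ts)
    phis = np.array(phis)
    tsats = np.array(tsats)

    def fit_window(lo, hi):
        m = (phis >= lo * (1 - 1e-9)) & (phis <= hi * (1 + 1e-9))
        if m.sum() < 2:
            raise ValueError("fewer than 2 saturating points in fit window")
        res = linregress(np.log(phis[m]), tsats[m])
        return res.slope, res.intercept

    s1, b1 = fit_window(*window_low)
    s2, b2 = fit_window(*window_high)
    if abs(s2 - s1) < 1e-12:
        phi_trans = float("nan")   # degenerate: parallel lines
    else:
        phi_trans = float(np.exp((b1 - b2) / (s2 - s1)))
    poly = None
    if smooth_poly_order is not None:
        poly = np.polyfit(np.log10(phis), tsats, smooth_poly_order)
    return TsatCurve(Phi=phis, T_sat=tsats, criterion=criterion,
                     tau_D1=float(s1), tau_D2=float(s2), Phi_trans=phi_trans,
                     window_low=tuple(window_low),
                     window_high=tuple(window_high), poly_log10=poly,
                     excluded=excluded)


def tsat_prediction(Phi, params: CascadeParams, rho: float = 0.32,
                    t_offset: float = 0.585):
    """Analytic T_sat from the super-linearity of the E** tails.

    T_sat = ln(phi e^{rho phi}) / k_E** + t_offset with
    phi = Phi/N_surfs; t_offset is the time the Q=1 mean E** trace
    crosses the saturation level (~2.6 E** per surface).
    """
    Phi = np.asarray(Phi, dtype=float)
    if np.any(Phi <= 0):
        raise ValueError("Phi must be > 0")
    phi = Phi / params.N_surfs
    return (np.log(phi) + rho * phi) / params.k_Estst + t_offset


def tsat_tangent_slope(Phi, params: CascadeParams, rho: float = 0.32):
    """Tangent slope dT_sat/dlnPhi = (1 + rho*Phi/N_surfs)/k_E**, s."""
    Phi = np.asarray(Phi, dtype=float)
    return (1.0 + rho * Phi / params.N_surfs) / params.k_Estst


# ---------------------------------------------------------------------------
# Tail time constants
# ---------------------------------------------------------------------------

def fit_tail_time_constant(t, y, window=(0.005, 0.10)) -> float:
    """Exponential time constant of a decaying tail, by log-linear fit.

    Points after the global maximum with ``window[0] <= y <= window[1]``
    enter an OLS fit of ln y against t; returns -1/slope (s). Raises if
    the selected tail is not monotonically decaying (beyond small
    sample noise).
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    i_pk = int(np.argmax(y))
    m = np.zeros(len(t), dtype=bool)
    m[i_pk:] = (y[i_pk:] >= window[0]) & (y[i_pk:] <= window[1])
    if m.sum() < 5:
        raise ValueError("fewer than 5 points in the tail window")
    ysel = y[m]
    rises = np.diff(ysel) > 0
    if rises.mean() > 0.4:
        raise ValueError("tail is not monotonically decaying in the window")
    res = linregress(t[m], np.log(ysel))
    if res.slope >= 0:
        raise ValueError("tail does not decay in the window")
    return float(-1.0 / res.slope)
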