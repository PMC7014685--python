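"""Stochastic activated-rhodopsin (R*) kinetics and G-protein depletion.

Normal R* shut-off follows a multistep clock: M phosphorylation steps
followed by arrestin binding, each at the common rate mu, so the
lifetime of full activity is gamma distributed with shape M+1 and rate
mu. Rare aberrant events bypass the clock: the R* retains a reduced
fractional activity until an abrupt, exponentially distributed
shut-off. The transducin (G-protein) pool on a disc surface is finite;
its depletion throttles the G* creation rate through a saturating
(Michaelis-type) factor with a closed-form time course in terms of the
Lambert W function.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.special import gammaincc, lambertw

from .params import CascadeParams

__all__ = [
    "RStarTimeline",
    "DepletionState",
    "sample_normal_lifetime",
    "sample_timelines",
    "mean_rstar_activity",
    "lifetime_sum_distribution",
    "assign_event_types",
    "sample_aberrant_lifetime",
    "depletion_rate_factor",
    "depletion_fraction_closed_form",
    "cumulative_gstar_created",
]


@dataclass(frozen=True)
class RStarTimeline:
    """Activity history of one activated rhodopsin.

    The molecule is catalytically active at the constant fractional
    level ``activity`` on ``[t_on, t_off)`` and silent afterwards
    (binary shut-off).
    """

    t_on: float
    t_off: float
    activity: float = 1.0
    is_aberrant: bool = False

    def __post_init__(self):
        if not self.t_off > self.t_on:
            raise ValueError("t_off must exceed t_on")
        if not 0.0 < self.activity <= 1.0:
            raise ValueError("activity must lie in (0, 1]")

    @property
    def lifetime(self) -> float:
        return self.t_off - self.t_on


@dataclass
class DepletionState:
    """Book-keeping of the finite G-protein pool on one disc surface."""

    G0: float
    cumulative_activated: float = 0.0

    @property
    def G_remaining(self) -> float:
        return self.G0 - self.cumulative_activated

    def record(self, n: float) -> None:
        if self.cumulative_activated + n > self.G0 + 1e-9:
            raise ValueError("cannot activate more G* than the pool holds")
        self.cumulative_activated += n


# ---------------------------------------------------------------------------
# Lifetime distributions
# ---------------------------------------------------------------------------

def sample_normal_lifetime(M: int, mu: float, rng: np.random.Generator,
                           size=None):
    """Draw normal R* lifetime(s): gamma with shape M+1, rate mu (s)."""
    if M < 0 or mu <= 0:
        raise ValueError("require M >= 0 and mu > 0")
    return rng.gamma(shape=M + 1, scale=1.0 / mu, size=size)


def mean_rstar_activity(t, M: int, mu: float):
    """Mean fractional R* activity at time t after activation.

    This is the gamma survival function exp(-mu t) * sum_{k<=M} (mu t)^k/k!,
    evaluated stably as the regularized upper incomplete gamma function.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    return gammaincc(M + 1, mu * t)


def lifetime_sum_distribution(Q: int, M: int, mu: float):
    """Distribution of the summed lifetimes of Q independent R*.

    Returns a frozen scipy distribution: gamma with shape Q*(M+1) and
    rate mu. Evaluation is numerically stable even for large shapes
    (e.g. 120), where naive factorial formulas overflow.
    """
    if Q < 1:
        raise ValueError("Q must be >= 1")
    return stats.gamma(a=Q * (M + 1), scale=1.0 / mu)


def assign_event_types(Q: int, p_aberr: float, rng: np.random.Generator):
    """Split Q isomerizations into (normal, aberrant) counts.

    Each event is independently aberrant with probability ``p_aberr``.
    """
    if not 0.0 <= p_aberr <= 1.0:
        raise ValueError("p_aberr must lie in [0, 1]")
    q_aberr = int(rng.binomial(Q, p_aberr)) if Q > 0 else 0
    return Q - q_aberr, q_aberr


def sample_aberrant_lifetime(tau_aberr: float, rng: np.random.Generator,
                             size=None):
    """Draw aberrant R* lifetime(s): exponential with mean tau_aberr (s)."""
    if tau_aberr <= 0:
        raise ValueError("tau_aberr must be > 0")
    return rng.exponential(scale=tau_aberr, size=size)


def sample_timelines(Q: int, params: CascadeParams, rng: np.random.Generator,
                     include_aberrant: bool = False, t_on: float = 0.0):
    """Sample R* timelines for Q synchronous isomerizations.

    With ``include_aberrant`` each event may, with probability
    ``p_aberr``, be an aberrant event of reduced activity ``a_aberr``
    and exponential lifetime; otherwise all events are normal.
    """
    q_norm, q_aberr = (Q, 0)
    if include_aberrant:
        q_norm, q_aberr = assign_event_types(Q, params.p_aberr, rng)
    timelines = [
        RStarTimeline(t_on, t_on + float(lt))
        for lt in np.atleast_1d(sample_normal_lifetime(params.M, params.mu, rng,
                                                       size=q_norm))
    ] if q_norm else []
    timelines += [
        RStarTimeline(t_on, t_on + float(lt), activity=params.a_aberr,
                      is_aberrant=True)
        for lt in np.atleast_1d(sample_aberrant_lifetime(params.tau_aberr, rng,
                                                         size=q_aberr))
    ] if q_aberr else []
    return timelines


# ---------------------------------------------------------------------------
# G-protein depletion
# ---------------------------------------------------------------------------

def depletion_rate_factor(state: DepletionState | float, K_m_dep: float,
                          G0: float | None = None):
    """Multiplier on the G* creation rate at the current depletion level.

    ``(g/(g + K_m)) * (1 + K_m)`` with g the remaining pool fraction;
    normalized to 1 at zero depletion and 0 at full depletion. Accepts
    either a :class:`DepletionState` or a remaining count with ``G0``.
    """
    if isinstance(state, DepletionState):
        g = state.G_remaining / state.G0
    else:
        if G0 is None:
            raise TypeError("G0 required when passing a raw count")
        g = state / G0
    g = np.clip(g, 0.0, 1.0)
    return (g / (g + K_m_dep)) * (1.0 + K_m_dep)


def depletion_fraction_closed_form(t, nu0: float, G0: float, K_m_dep: float):
    """Fraction of the G-protein pool consumed by time t (closed form).

    Solves dG/dt = -nu0 * (g/(g+Km)) * (1+Km), g = G/G0, from g(0)=1:
    the remaining fraction is ``Km * W0{(1/Km) exp(1/Km - (1+1/Km) nu0 t/G0)}``
    and the depleted fraction is one minus that. The principal branch
    W0 applies throughout; for large arguments the scipy implementation
    is evaluated via logarithms to avoid overflow.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    km = K_m_dep
    # argument of W is exp(z)/km with z = 1/km - (1 + 1/km) * nu0 * t / G0
    z = 1.0 / km - (1.0 + 1.0 / km) * nu0 * t / G0
    logarg = z - np.log(km)
    out = np.empty_like(np.broadcast_to(z, np.shape(z)), dtype=float)
    big = logarg > 650.0  # exp would overflow; use asymptotic W(e^y) ~ y - ln y
    small = ~big
    if np.any(small):
        w = lambertw(np.exp(logarg[small]), k=0)
        if np.any(np.abs(w.imag) > 1e-12):
            raise ValueError("Lambert W argument left the principal branch")
        out[small] = w.real
    if np.any(big):
        y = logarg[big]
        w = y - np.log(y)
        for _ in range(4):  # Newton refinement of w e^w = e^y in log form
            w = w - (w + np.log(w) - y) / (1.0 + 1.0 / w)
        out[big] = w
    frac_remaining = km * out
    return np.clip(1.0 - frac_remaining, 0.0, 1.0) if out.ndim else float(
        np.clip(1.0 - frac_remaining, 0.0, 1.0))


def cumulative_gstar_created(active_time, nu: float, G0: float, K_m_dep: float):
    """G* created after ``active_time`` seconds of unit R* activity at rate nu,
    accounting for depletion of the finite pool G0."""
    return G0 * depletion_fraction_closed_form(active_time, nu, G0, K_m_dep)
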