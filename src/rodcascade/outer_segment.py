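"""Whole-outer-segment assembly of disc activity: Poisson statistics and
method 3 (per-surface simulation with aberrant R* shut-off events).

A flash of ``Phi`` photoisomerizations per outer segment delivers a
Poisson-distributed number Q of isomerizations to each of the N_surfs
disc surfaces (mean phi = Phi / N_surfs). Method 2 responses are
assembled by Poisson-weighting per-Q mean disc traces; method 3
simulates every active surface explicitly, including the rare aberrant
events, and maps each surface's E** activity to its longitudinal
compartment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .disc_bulk import simulate_disc_bulk
from .params import CascadeParams
from .rstar import RStarTimeline, sample_aberrant_lifetime, sample_normal_lifetime
from .traces import DiscTrace, OuterSegmentActivity

__all__ = [
    "FlashStimulus",
    "poisson_weights",
    "mean_os_activity_method2",
    "simulate_os_method3",
]


@dataclass(frozen=True)
class FlashStimulus:
    """A brief flash delivering Phi isomerizations per outer segment."""

    Phi: float
    t_deliver: float = 0.0

    def __post_init__(self):
        if self.Phi < 0:
            raise ValueError("Phi must be >= 0")

    def phi_per_surface(self, N_surfs: int) -> float:
        return self.Phi / N_surfs


def poisson_weights(Phi: float, N_surfs: int,
                    mass_tolerance: float = 1e-9) -> dict[int, float]:
    """Per-surface isomerization-count probabilities p_Q, renormalized.

    Q runs from 0 to the smallest Q_max capturing cumulative mass
    >= 1 - mass_tolerance.
    """
    if Phi < 0:
        raise ValueError("Phi must be >= 0")
    phi = Phi / N_surfs
    if phi == 0.0:
        return {0: 1.0}
    q_max = int(stats.poisson.ppf(1.0 - mass_tolerance, phi))
    qs = np.arange(q_max + 1)
    w = stats.poisson.pmf(qs, phi)
    while w.sum() < 1.0 - mass_tolerance:
        q_max += 1
        qs = np.arange(q_max + 1)
        w = stats.poisson.pmf(qs, phi)
    w = w / w.sum()
    return {int(q): float(p) for q, p in zip(qs, w)}


def mean_os_activity_method2(Phi: float, per_Q_mean_traces: dict[int, DiscTrace],
                             N_surfs: int,
                             mass_tolerance: float = 1e-9):
    """Total mean E**(t) over the outer segment by Poisson weighting.

    Returns ``(t, E**_total)``; the Q=0 surface contributes zero and
    need not be supplied.
    """
    weights = poisson_weights(Phi, N_surfs, mass_tolerance)
    t_ref = None
    total = None
    for q, w in weights.items():
        if q == 0:
            continue
        if q not in per_Q_mean_traces:
            raise ValueError(f"missing mean trace for Q={q} "
                             f"(weight {w:.2e} > mass tolerance)")
        tr = per_Q_mean_traces[q]
        if t_ref is None:
            t_ref = tr.t
            total = np.zeros_like(t_ref)
        elif len(tr.t) != len(t_ref) or abs(tr.t[-1] - t_ref[-1]) > 1e-9:
            raise ValueError("per-Q traces must share a common time grid")
        total += w * tr.E_starstar
    if t_ref is None:  # Phi == 0
        raise ValueError("flash delivers no isomerizations")
    return t_ref, N_surfs * total


def simulate_os_method3(Phi: float, params: CascadeParams, seed=None,
                        n_trials: int = 1, t_end: float = 15.0,
                        sample_dt: float = 1e-3,
                        include_aberrant: bool = True) -> list[OuterSegmentActivity]:
    """Method 3: explicit per-surface simulation with aberrant events.

    Per trial, each of the N_surfs surfaces draws independent Poisson
    numbers of normal and aberrant events (thinning of the photon
    Poisson process); surfaces with events are simulated with the
    mass-action disc engine using mixed R* timelines, and their E**
    activity is deposited in the surface's longitudinal compartment
    (surfaces evenly assigned to the n_x compartments).
    """
    if Phi <= 0:
        raise ValueError("Phi must be > 0")
    p = params
    phi = Phi / p.N_surfs
    p_ab = p.p_aberr if include_aberrant else 0.0
    ss = np.random.SeedSequence(seed)
    out = []
    n_grid = int(round(t_end / sample_dt)) + 1
    t_grid = np.arange(n_grid) * sample_dt
    for child in ss.spawn(n_trials):
        rng = np.random.default_rng(child)
        per_comp = np.zeros((p.n_x, n_grid))
        q_norm = rng.poisson(phi * (1.0 - p_ab), size=p.N_surfs)
        q_aberr = rng.poisson(phi * p_ab, size=p.N_surfs)
        n_aberr = int(q_aberr.sum())
        for s in np.nonzero(q_norm + q_aberr)[0]:
            timelines = [
                RStarTimeline(0.0, float(lt))
                for lt in np.atleast_1d(sample_normal_lifetime(
                    p.M, p.mu, rng, size=q_norm[s]))
            ] if q_norm[s] else []
            timelines += [
                RStarTimeline(0.0, float(lt), activity=p.a_aberr,
                              is_aberrant=True)
                for lt in np.atleast_1d(sample_aberrant_lifetime(
                    p.tau_aberr, rng, size=q_aberr[s]))
            ] if q_aberr[s] else []
            tr = simulate_disc_bulk(len(timelines), p, t_end,
                                    timelines=timelines, sample_dt=sample_dt)
            comp = s * p.n_x // p.N_surfs
            per_comp[comp] += tr.E_starstar
        out.append(OuterSegmentActivity(
            t=t_grid, per_compartment=per_comp,
            meta={"Phi": Phi, "n_isom": int(q_norm.sum() + q_aberr.sum()),
                  "n_aberrant": n_aberr}))
    return out
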