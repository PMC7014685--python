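"""End-to-end bright-flash pipelines built from the lower-level modules.

These are the workflows behind the headline analyses: compute mean
method-2 disc traces for every needed Q once, assemble Poisson-weighted
outer-segment drives over a grid of flash intensities, integrate the
downstream model and measure the time-in-saturation curve with its
dominant time constants.
"""

from __future__ import annotations

import numpy as np

from . import analysis
from .disc_bulk import mean_disc_bulk
from .downstream import integrate_single_compartment
from .outer_segment import mean_os_activity_method2, poisson_weights
from .params import CascadeParams
from .downstream import dark_adapt
from .traces import DiscTrace, OuterSegmentTrace

__all__ = [
    "per_Q_mean_traces",
    "method2_response",
    "tsat_analysis_method2",
]


def per_Q_mean_traces(params: CascadeParams, Q_values, n_trials: int,
                      t_end: float, seed=None) -> dict[int, DiscTrace]:
    """Trial-averaged method-2 disc traces for each Q in ``Q_values``."""
    ss = np.random.SeedSequence(seed)
    traces = {}
    for q, child in zip(Q_values, ss.spawn(len(list(Q_values)))):
        traces[int(q)] = mean_disc_bulk(int(q), params, t_end, n_trials,
                                        seed=child)
    return traces


def method2_response(Phi: float, params: CascadeParams,
                     traces: dict[int, DiscTrace], dark=None,
                     t_end: float | None = None) -> OuterSegmentTrace:
    """Downstream response to a flash, from per-Q method-2 mean traces."""
    t, total = mean_os_activity_method2(Phi, traces, params.N_surfs)
    if t_end is None:
        t_end = float(t[-1])
    return integrate_single_compartment((t, total), params, dark, t_end=t_end)


def tsat_analysis_method2(params: CascadeParams, intensities=None,
                          n_trials_per_Q: int = 200, t_end: float = 9.0,
                          seed=None, criterion: float = 0.10,
                          window_low=(300.0, 3000.0),
                          window_high=(10000.0, 62500.0)):
    """Full method-2 T_sat pipeline.

    Simulates mean disc traces for every Q needed by the Poisson
    weights of the largest intensity, assembles and integrates the
    downstream response per intensity, measures T_sat and fits the two
    dominant-time-constant lines. Returns ``(TsatCurve, traces)``.
    """
    p = params
    if intensities is None:
        # 100 to 62500 R* at 0.05 log10 spacing
        intensities = 10 ** np.arange(2.0, np.log10(62500) + 1e-9, 0.05)
    intensities = np.asarray(intensities, dtype=float)
    q_max = max(poisson_weights(float(intensities.max()), p.N_surfs))
    traces = per_Q_mean_traces(p, range(1, q_max + 1), n_trials_per_Q, t_end,
                               seed=seed)
    dark = dark_adapt(p)

    def response_fn(Phi):
        return method2_response(Phi, p, traces, dark, t_end=t_end)

    curve = analysis.tsat_curve(intensities, response_fn, criterion=criterion,
                                window_low=window_low,
                                window_high=window_high)
    return curve, traces
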