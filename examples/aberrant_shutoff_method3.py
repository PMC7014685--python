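"""Aberrant R* shut-off events and the late slow recovery (method 3).

A small fraction (p_aberr ~ 0.002) of R* fail to inactivate normally
and instead retain a fraction a_aberr of full activity for seconds.
Method 3 simulates every active disc surface, places it in its
longitudinal compartment, and integrates the spatial downstream model;
the aberrant events produce a plateau of a few percent of the dark
current and a seconds-long tail after bright flashes.
"""

import numpy as np

import rodcascade as rc

params = rc.load_params()
dark = rc.dark_adapt(params)
Phi = 500.0

acts = rc.simulate_os_method3(Phi, params, seed=3, n_trials=6, t_end=8.0)
for i, act in enumerate(acts):
    resp = rc.integrate_longitudinal(act, params, dark)
    plateau = resp.fractional_response[np.searchsorted(resp.t, 4.0):].mean()
    print(f"trial {i}: {act.meta['n_isom']:4d} isomerizations, "
          f"{act.meta['n_aberrant']} aberrant event(s); "
          f"late plateau {100*plateau:5.2f}% of dark current")

print("\ntrials without aberrant events recover fully; each aberrant "
      "event holds a plateau comparable to the single-photon amplitude "
      "(~4% of the dark current) until its exponential shut-off")
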