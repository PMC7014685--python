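"""Solve the dark resting state and run the biochemical cross-checks.

The dark state balances cGMP synthesis against hydrolysis and Ca2+
influx against extrusion; the cross-checks tie the model's E**
hydrolytic rate and cGMP buffering power back to measured biochemistry.
"""

import rodcascade as rc

params = rc.load_params()
dark = rc.solve_dark_state(params)

print("Dark resting state")
print(f"  cGMP           {dark.cG:6.2f} uM")
print(f"  Ca2+           {dark.Ca:6.0f} nM")
print(f"  cyclase rate   {dark.alpha:6.1f} uM/s")
print(f"  dark current   {dark.J:6.1f} pA "
      f"(CNG {dark.J_cG:.1f} + exchanger {dark.J_ex:.2f})")

b_cg = rc.buffering_power_cgmp(params)
beta_pred = rc.predicted_beta_estarstar(params, B_cG=b_cg)
print("\nBiochemical cross-checks")
print(f"  cGMP buffering power B_cG       {b_cg:.2f}")
print(f"  predicted beta_E**              {beta_pred:.4f} /s "
      f"(model uses {params.beta_Estst})")
print(f"  PDE6 per disc surface           {params.E_tot}")
print(f"  PDE6 per outer segment          {params.pde_per_os}")
print(f"  G protein per disc surface      {params.G0_surface}")
print(f"  minimum activation rate         {params.min_activation_rate():.0f} G*/s"
      " (to cover all PDE6 sites at the transition intensity)")
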