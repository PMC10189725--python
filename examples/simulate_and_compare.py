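"""Run the axisymmetric simulator and compare it with the analytic limits.

Simulates dimensionless uptake for Z_max = 0.01 across the saturation
transition and prints how the computed rate moves from the Cottrell regime
onto the rim-cylinder limit.
"""

import numpy as np

from cuticle_uptake import (
    DiskCylinderGeom,
    GridSpec,
    cottrell_rate,
    cylinder_rate,
    simulate_uptake,
)

Z = 0.01
geom = DiskCylinderGeom(Z)
spec = GridSpec(T_min=1e-6, T_max=1.0, steps_per_decade=40)
curve = simulate_uptake(Z, spec)
print(f"simulated {len(curve.T)} output times on {curve.diagnostics['n_unknowns']} "
      f"grid nodes; mass balance residual "
      f"{curve.diagnostics['mass_balance_residual']:.1e}\n")

print(f"{'T/Z^2':>10} {'rate':>12} {'rate/cottrell':>14} {'rate/cylinder':>14}")
for x in (0.01, 0.1, 0.5, 1.0, 10.0, 1e3, 1e4):
    T = x * Z**2
    r = curve.rate_at(T)
    print(f"{x:10.3g} {r:12.4g} {r / cottrell_rate(T):14.3f} "
          f"{r / cylinder_rate(T, geom):14.3f}")

print(
    "\nrate/cottrell falls below 1 once T ~ 0.5 Z^2 (longitudinal\n"
    "saturation) while rate/cylinder approaches 1 at long times: the\n"
    "simulator reproduces both limiting regimes and the transition between\n"
    "them.  M(T_end) = %.4g exceeds the saturated-column mass pi*Z = %.4g\n"
    "because radial spread keeps feeding the cuticle." % (curve.M[-1], np.pi * Z)
)
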