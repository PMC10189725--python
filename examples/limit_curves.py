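"""Evaluate the four closed-form uptake-rate limits for a thin cuticle.

Builds the dimensionless geometry of a 50 nm maize cuticle under a 450 um
droplet deposit and prints the rate predicted by each limiting regime at a
few dimensionless times around the saturation transition.
"""

import numpy as np

from cuticle_uptake import (
    DiskCylinderGeom,
    composite_thin_cuticle_rate,
    cottrell_rate,
    crank_rate,
    cylinder_rate,
    shoup_szabo_rate,
    transition_time,
)

Z_max = 50e-9 / 450e-6  # cuticle thickness / deposit radius
geom = DiskCylinderGeom(Z_max)
T_tr = transition_time(geom)

print(f"Z_max = {Z_max:.4g}  (thin cuticle: Z_max << 1)")
print(f"saturation transition at T = 0.5 Z_max^2 = {T_tr:.3g}\n")
print(f"{'T/T_tr':>8} {'cottrell':>12} {'shoup-szabo':>12} {'crank':>12} "
      f"{'cylinder':>12} {'composite':>12}")
for f in (0.01, 0.1, 1.0, 10.0, 100.0):
    T = f * T_tr
    print(
        f"{f:8.2f} {cottrell_rate(T, geom):12.4g} {shoup_szabo_rate(T):12.4g} "
        f"{crank_rate(T, geom):12.4g} {cylinder_rate(T, geom):12.4g} "
        f"{composite_thin_cuticle_rate(T, geom):12.4g}"
    )

print(
    "\nBefore the transition all curves are Cottrellian (dM/dT ~ T^-1/2).\n"
    "After it the plane-sheet (crank) rate collapses -- the cuticle column\n"
    "under the droplet is saturated -- and uptake continues only by radial\n"
    "diffusion from the rim at the much smaller cylinder rate.  The\n"
    "composite column is the no-simulation estimate of the full curve."
)
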