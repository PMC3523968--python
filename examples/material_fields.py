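"""The graded material fields along the cell.

Prints the actin density a(x), elastic modulus E(x), substrate drag
beta(x) and contractile stress tau(x) at a few stations of the resting
cell, plus the two derived scalars that set the simulation scales: the
protrusive stress sigma_active = F_active/S_cell and the minimum
viscoelastic time constant mu / max E(x), which bounds the stable step.
"""

import numpy as np

from cellwalk import load_preset

params = load_preset("table1")
L = params.L0
x = np.linspace(0.0, L, 5)
x_mid = 0.5 * L

a = params.actin_density(x, x_mid)
E = params.elastic_modulus(x, x_mid)
beta = params.drag_coefficient(x, 0.0, L)
tau = params.active_stress_profile(x, 0.0, L, x_mid)

print(f"{'x (mm)':>8} {'a (1/mm)':>11} {'E (N/mm^2)':>11} "
      f"{'beta':>11} {'tau (N/mm^2)':>13}")
for xi, ai, Ei, bi, ti in zip(x, a, E, beta, tau):
    print(f"{xi:8.4f} {ai:11.3e} {Ei:11.4f} {bi:11.3e} {ti:13.4f}")

print()
print(f"sigma_active = F/S          : {params.sigma_active:.4f} N/mm^2")
print(f"min time constant mu/max E  : {params.min_time_constant():.6f} min")
print()
print("Stiffness and contractility rise toward the front (actin-rich);")
print("drag is weakest at the rear, where adhesions dissociate fastest.")
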