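"""Choosing the critical stress by comparison with the steady model.

Sweeps candidate sigma_c values, runs the walking model for each and
measures how closely its length trajectory tracks the steady reference
(RMSE on a common time grid).  Thresholds above the rear-stress plateau
can never trigger a release -- the cell freezes after its first
protrusion -- and fit the steady reference worse than thresholds that
produce sustained cycling.
"""

import numpy as np

from cellwalk import calibrate_sigma_c, load_preset

params = load_preset("table1_calibrated")
plateau = params.sigma_active
candidates = np.array([0.4, 0.6, 0.8, 1.5]) * plateau

res = calibrate_sigma_c(params, candidates, T=5.0, dt=1e-4, n=101, sample_every=100)

print(f"rear-stress plateau : {plateau:.3e} N/mm^2")
print(f"{'sigma_c':>12} {'length RMSE (mm)':>18} {'front RMSE (mm)':>17}")
for c, d, p in zip(res.candidates, res.discrepancies, res.position_discrepancies):
    print(f"{c:12.3e} {d:18.3e} {p:17.3e}")
print(f"selected sigma_c    : {res.selected:.3e} N/mm^2")
print(f"steady speed        : {res.reference_speed:.4f} um/min")
print(f"walking speed there : {res.candidate_speed:.4f} um/min")
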