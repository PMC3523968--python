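# Tabulated reference cell with the documented stress-scale calibration
# (see docs/methods.md):
#   active_scale -- fitted so the steady 100-minute run at dt=1e-4 min,
#                   101 nodes travels at 0.2 um/min;
#   tau_scale    -- set so the peak contractile strain |tau|/E is ~10%,
#                   keeping the cell length nearly constant.
k_s: 0.05
psi1: 3.33
psi2: 10.0
km_ratio: 0.3
kreg_ratio: 0.1
alpha: 0.2
beta0: 5.0e-6
n_f: 5490.0
n_b0: 12500.0
n_b: 12500.0
m_f: 690.0
tau0: 4.2e-10
E0: 4.2e-11
mu: 2.0e-4
L0: 0.05
F_active: 1.0e-6
S_cell: 3.0e-5
sigma_c: 1.4e-7
active_scale: 2.09633e-7
tau_scale: 1.0e-3
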