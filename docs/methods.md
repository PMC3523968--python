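# Methods

## The model

`cellwalk` simulates a crawling ameboid cell as a one-dimensional
viscoelastic continuum on a frictional substrate.  The cell occupies
[r(t), f(t)] (rear to front) and its cumulative displacement field u(x, t)
obeys the overdamped force balance

    d(sigma)/dx = beta(x) du/dt,
    sigma = E(x) du/dx + mu d2u/(dt dx) + tau(x),

a Kelvin–Voigt solid (elastic + viscous stress in parallel) augmented by a
contractile actomyosin stress tau(x) <= 0, dragged against the substrate
with a graded friction beta(x).  Units are mm, minutes and N throughout;
stresses are N/mm^2, mu is N·min/mm^2, beta is N·min/mm^3.

The material is graded front-to-rear through a smoothed actin-density step
a(x) centred on the cell midpoint (arctan profile, gain 700/mm):
stiffness E = E0·a(x) and contractility follow the actin, so the front is
stiff and strongly contractile; drag is weakest at the rear, where
adhesion bonds dissociate fastest (factor psi1), and strongest at the
front.  The midpoint of the actin step is re-evaluated as (r+f)/2 every
step so the material profile travels with the cell; a profile frozen in
the lab frame would leave a migrating cell on a featureless plateau within
a few steps.

Locomotion is driven two ways:

* a protrusive stress sigma_active = active_scale · F_active / S_cell
  applied at the leading edge (polymerization push), and
* the two-step *walking* cycle: with the tail anchored the rear stress
  sigma_1 builds toward the transmitted protrusive stress; when it reaches
  the critical value sigma_c the tail detaches (front anchors instead) and
  is dragged forward; when sigma_1 has relaxed back to zero the tail
  re-anchors and the cycle repeats.

## Discretization

100 segments / 101 nodes (configurable), updated-Lagrangian: u is the
cumulative displacement from the initial uniform grid, positions are
updated as x = x0 + u after every solve, and all spacings and fields are
re-evaluated on the deformed grid.  The viscous stress is treated
implicitly and the elastic and active stresses explicitly, giving one
tridiagonal solve A u^{j+1} = B u^j + C per step (banded LAPACK solve;
pinned-node values are reasserted after the solve because the banded
factorization pivots and would otherwise smear ~1 ulp into the Dirichlet
rows).  The explicit elastic update requires dt below the minimum
Kelvin–Voigt time constant mu / max E(x) = 6.7e-4 min for the reference
cell; the default dt = 1e-4 min.  A larger dt triggers a warning, not an
error.

Two discretization choices deserve emphasis because the parameter regime
is extreme (substrate drag is ~10^5 softer than the internal stresses, so
the net-force budget of the whole cell is ~10^-9 N/mm^2 while internal
stress terms are ~10^-3):

* **Conservative edge rows.**  The free-edge rows are half-cell flux
  balances with *face-averaged* E and tau, so the weighted row sum
  telescopes exactly to sigma_active.  Node-valued edge rows with a
  full-spacing divisor (the naive one-sided form) are non-conservative
  and inject a spurious net force that drives the cell at ~37 mm/min —
  five orders of magnitude above the physical speed.  With conservative
  rows the exact continuum identity  v̄ · ∫beta dx = sigma_active  is
  reproduced to 0.04%.
* **Face-flux rear-stress monitor.**  sigma_1 is evaluated from the first
  segment with the same face-averaged coefficients the assembled system
  uses:  E_face (u_2-u_1)/dx_1 + tau_face  while the tail is anchored,
  plus  mu (u_1^{j+1}-u_1^j)/dt  while it retracts.  A node-centred
  reconstruction (E_1 u_2/dx_1 + tau_1) carries an O(dx) bias from the
  curvature of tau(x) that is orders of magnitude larger than the
  transmitted stress.  With the face form, sigma_1 equals sigma_active
  exactly at the discrete rear-anchored equilibrium and relaxes exactly
  to zero at the rear-released equilibrium — the two arms of the
  switching cycle.

Anchoring is pin-in-place: the Dirichlet row holds the node at its
current position (u^{j+1} = u^j).  In the very first tail-anchored phase
this coincides with u_1 = 0; after the tail has moved, resetting it to
zero would teleport it back to the origin.

Switching thresholds are inclusive (sigma_1 >= sigma_c releases the tail,
sigma_1 <= tol re-anchors it).  `tol` defaults to 0, but because sigma_1
approaches zero only asymptotically during retraction, cycling studies
should pass a small positive tolerance; all bundled studies use
tol = 0.01 · sigma_c.  Mode changes take effect at the next assembly; the
full state is recorded at every switch so per-cycle statistics are exact.

## Parameters and the calibrated preset

All physical constants live in `CellParameters`; the bundled `table1`
preset is the tabulated reference cell (k_s = 0.05, psi1 = 3.33,
psi2 = 10, beta0 = 5e-6, n_f = 5490, n_b0 = 12500, m_f = 690,
tau0 = 4.2e-10, E0 = 4.2e-11, mu = 2e-4, L0 = 0.05 mm,
F_active = 1000 nN, S_cell = 30 um^2, sigma_c = 1.4e-7).  The bound
integrin density n_b has no tabulated value and integrin kinetics are out
of scope; it defaults to n_b0, making the Hill factor
n_b^alpha/(n_b0^alpha+n_b^alpha) exactly 1/2, and is exposed as a
parameter.

The tabulated stress magnitudes are not mutually consistent in this unit
system.  Taken literally, tau(x) reaches ~-31 N/mm^2 against
E <= 0.3 N/mm^2 (strains of 10–100: the grid folds within a few steps),
and sigma_active = F/S = 3.3e-2 N/mm^2 exceeds the critical stress
1.4e-7 N/mm^2 by five orders of magnitude.  Two dimensionless multipliers
therefore dress the active stresses: `active_scale` on sigma_active and
`tau_scale` on tau(x), both defaulting to 1 (the literal tabulated
model).  The `table1_calibrated` preset documents the calibration used
for all quantitative runs:

* `tau_scale = 1e-3`, chosen so the peak contractile strain |tau|/E is
  ~10%, which keeps the cell length within a few percent of L0 — the
  regime the published length trajectories display.  The resulting
  one-off contractile stretch is 1.36 um.
* `active_scale = 2.09633e-7`, fitted (secant iteration on full
  simulations; the measured speed is affine in the scale to high
  accuracy) so the steady 100-minute run at dt = 1e-4, 101 nodes travels
  at 0.200 um/min, the experimental crawling speed.  The analytic
  net-force estimate sigma_active/∫beta gives the starting point.

### A structural inconsistency, quantified

With conservative dynamics the steady speed and the rear-stress plateau
are rigidly linked: v = sigma_active/∫beta dx and the rear-anchored
sigma_1 saturates at exactly sigma_active.  With the tabulated drag and
geometry, a 0.2 um/min cell has sigma_active,eff = 7.0e-9 N/mm^2 — a
factor ~22 below the published rear-stress maximum 1.6e-7 and below the
published critical stress 1.4e-7.  Consequently, at the calibrated scales
a walking threshold of 1.4e-7 is unreachable (the cell never releases its
tail), and conversely an active stress large enough to reach 1.6e-7 would
drive steady creep at ~4.5 um/min.  No choice of the two scale factors
reconciles the printed speed, rear-stress maximum and critical stress
simultaneously; the package calibrates to the speed (the quantity with an
experimental anchor) and reports the others as the model actually
produces them.  Relatedly, sustained walking translocation is set by the
stored elastic strain sigma/E per cycle, which at these stress scales is
nanometres per cycle: the walking cell cycles cleanly but advances far
more slowly than the free-creeping steady cell.

## What the simulations emulate — and what they do not

The generator of all inputs is the parameter preset itself: there is no
external data.  The runs emulate a single cell crawling at constant
polarity on a rigid, uniform substrate with time-independent actin
density and myosin kinetics folded into static spatial profiles.  Not
represented: actin-network turnover dynamics, integrin binding kinetics
(n_b is constant), substrate deformability, 2D shape, stochastic
adhesion, or any feedback of stress on the kinetic rates.  Passing tests
therefore certify the continuum mechanics, the discretization and the
switching logic — not the biochemical realism of the stress profiles.

## Numerical choices and degenerate inputs

* Tie-break in the critical-stress sweep: equal length-RMSE selects the
  larger sigma_c.  The comparison grid is 1-minute linear interpolation
  of both length series (switch events make native sampling unequal).
  The front-position RMSE is reported alongside but not used to select.
* The rear-anchored stress experiment stops once sigma_1 has declined 5%
  from a positive running maximum; if no decline occurs by T the maximum
  is flagged censored (at the calibrated scales sigma_1 saturates rather
  than peaks, so censoring is the normal outcome).
* Degenerate geometry (front not ahead of rear, non-monotone grid) raises
  `GeometryError`; a mid-run violation aborts with the partial trajectory
  attached (`SimulationAborted`).
* Zero forcing is an exact fixed point of the discrete update; it is held
  to |u| < 1e-14 mm over 10^6 steps in the test suite.
* Trajectory CSVs are written with 12 significant digits, making repeated
  runs byte-identical and round-trips lossless at that precision.

## Problem sizes used in the bundled studies

The quantitative anchors (steady and walking 100-minute runs) use the
published resolution: 101 nodes, dt = 1e-4 min (10^6 steps, a few minutes
of CPU).  Unit and property tests exercise the same code paths on shorter
horizons (0.05–10 min) and coarser grids (5–101 nodes), which fully
resolve every relaxation time in the problem (the slowest is ~0.05 min).

## Known limitations

* The literal tabulated parameter set (both scale factors = 1) is
  numerically untenable, as described above; it is retained as the
  default because it is the documented reference, and the solver guards
  fail loudly when it folds the grid.
* Walking speed is quantitatively meaningful only relative to the model's
  own stress scales; see the inconsistency note.
* First-order accuracy in time (explicit elastic terms); no remeshing or
  adaptive stepping.
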