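# cellwalk

A simulator of ameboid cell crawling as a one-dimensional viscoelastic
continuum that *walks*: the cell alternates between a tail-anchored phase,
in which a protrusive stress drives the leading edge forward and load
builds on the rear adhesion, and a front-anchored phase, in which the tail
detaches and is dragged forward, triggered whenever the rear stress
crosses a critical value σ_c and releases again when it relaxes to zero.
It is aimed at cell-mechanics and mechanobiology modellers who want an
explicit, inspectable implementation of critical-stress stepping on top of
the classic steadily-creeping viscoelastic cell.

## Model

The cell occupies [r, f] with cumulative displacement u(x, t) obeying the
overdamped balance of a Kelvin–Voigt solid with active stress on a
frictional substrate,

    ∂σ/∂x = β(x) ∂u/∂t,        σ = E(x) ∂u/∂x + μ ∂²u/∂t∂x + τ(x),

with graded material fields: actin density a(x) (smoothed arctan step
travelling with the cell midpoint), stiffness E = E₀·a(x), contractile
stress τ(x) ≤ 0 (myosin kinetics × regulatory activation × Hill-type
integrin factor × a(x)), drag β(x) weakest at the rear (bond dissociation
gradient ψ₁), and a protrusive stress σ_active = F_active/S_cell at the
leading edge.  Time stepping is an implicit-viscous / explicit-elastic
finite-difference scheme on a moving 101-node grid: one tridiagonal solve
per step, in conservative flux form so the discrete net force on the cell
telescopes exactly to σ_active.  Units: mm, minutes, N.

Three boundary-condition policies: `steady` (both edges free — the
classic creeping cell), `front_advance`/`rear_retract` (one edge
anchored), and `walking` (the critical-stress state machine between the
last two).  See `docs/methods.md` for the discretization, the rear-stress
monitor, and the documented stress-scale calibration of the bundled
`table1_calibrated` preset.

## Worked example

```python
from cellwalk import average_speed, load_preset, simulate

params = load_preset("table1_calibrated")
traj = simulate(params, "steady", T=10.0, dt=1e-4, n=101, sample_every=1000)
print(f"average speed         : {average_speed(traj):.4f} um/min")
print(f"cell length start/end : {traj.length[0]:.6f} / {traj.length[-1]:.6f} mm")
```

prints

    average speed         : 0.2721 um/min
    cell length start/end : 0.050000 / 0.051360 mm

The cell stretches by 1.36 µm while its contraction equilibrates, then
translates at constant length; over the full 100-minute run the average
leading-edge speed is 0.200 µm/min, matching the experimental crawling
speed the calibration targets.  More narrative scripts live in
`examples/` (material fields, rear-stress build-up, walking cycles,
critical-stress sweep), and a thin CLI mirrors them:

    cellwalk simulate --policy steady -T 100 -o run
    cellwalk max-stress -T 5 -o rear
    cellwalk calibrate --grid 1.6e-7:1.2e-7:5 -o sweep
    cellwalk preset --name table1_calibrated

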