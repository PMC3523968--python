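"""Implicit finite-difference core on a moving 1D grid.

Discretizes the overdamped force balance

    d(sigma)/dx = beta(x) * du/dt,
    sigma = E(x) * du/dx + mu * d2u/(dt dx) + tau(x)

on a nonuniform node grid in face-flux form.  The viscous part of the
stress is treated implicitly, the elastic and active parts explicitly,
which yields one tridiagonal solve A u^{j+1} = B u^j + C per time step.
``u`` is the cumulative displacement from the initial configuration;
positions are updated as x = x0 + u after every solve and all spacings and
fields are re-evaluated on the updated grid (updated-Lagrangian stepping).

Boundary rows depend on the active :class:`~cellwalk.modes.BoundaryMode`:
free edges carry the protrusive stress (front) or zero external stress
(rear); an anchored edge is held in place by a Dirichlet row
u^{j+1} = u^j.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Union

import numpy as np
from scipy.linalg import solve_banded

from .modes import BoundaryMode
from .parameters import (
    CellParameters,
    FieldValues,
    GeometryError,
    ParameterFields,
)

__all__ = ["CellState", "TridiagonalSystem", "initial_state", "assemble", "step",
           "stress_field", "rear_stress"]

FieldSource = Union[CellParameters, ParameterFields]


def _as_fields(fields: FieldSource) -> ParameterFields:
    if isinstance(fields, CellParameters):
        return fields.fields()
    return fields


@dataclasses.dataclass
class CellState:
    """Node positions, cumulative displacements, time and active mode."""

    x: np.ndarray  # node positions, mm, strictly increasing
    u: np.ndarray  # cumulative displacement from the initial grid, mm
    t: float  # minutes
    mode: BoundaryMode

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.u = np.asarray(self.u, dtype=float)
        if self.x.ndim != 1 or self.x.shape != self.u.shape:
            raise ValueError("x and u must be 1D arrays of equal length")
        if self.t < 0:
            raise ValueError("t must be non-negative")
        if np.any(np.diff(self.x) <= 0):
            raise GeometryError("node positions must be strictly increasing")

    @property
    def n(self) -> int:
        return self.x.size

    @property
    def rear(self) -> float:
        return float(self.x[0])

    @property
    def front(self) -> float:
        return float(self.x[-1])

    @property
    def length(self) -> float:
        return self.front - self.rear

    @property
    def x0(self) -> np.ndarray:
        """Initial (reference) grid, recovered as x - u."""
        return self.x - self.u


def initial_state(
    params_or_L0: Union[CellParameters, float],
    n: int = 101,
    mode: BoundaryMode = BoundaryMode.STEADY,
) -> CellState:
    """Uniform grid on [0, L0], zero displacement, t = 0 (cell at rest)."""
    L0 = params_or_L0.L0 if isinstance(params_or_L0, CellParameters) else float(params_or_L0)
    if n < 3:
        raise ValueError(f"need at least 3 nodes, got {n}")
    x = np.linspace(0.0, L0, n)
    return CellState(x=x, u=np.zeros(n), t=0.0, mode=mode)


@dataclasses.dataclass
class TridiagonalSystem:
    """Banded per-step system A u^{j+1} = B u^j + C.

    Band convention: ``A_lower[i]`` multiplies u[i-1] in row i (entry 0
    unused), ``A_upper[i]`` multiplies u[i+1] (last entry unused).
    """

    A_lower: np.ndarray
    A_diag: np.ndarray
    A_upper: np.ndarray
    B_lower: np.ndarray
    B_diag: np.ndarray
    B_upper: np.ndarray
    C: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.A_diag == 0.0):
            raise np.linalg.LinAlgError("zero diagonal entry in implicit matrix")

    def rhs(self, u: np.ndarray) -> np.ndarray:
        """B u + C evaluated bandwise."""
        out = self.B_diag * u + self.C
        out[1:] += self.B_lower[1:] * u[:-1]
        out[:-1] += self.B_upper[:-1] * u[1:]
        return out

    def solve(self, u: np.ndarray) -> np.ndarray:
        """Solve A u^{j+1} = B u + C by banded (Thomas-type) elimination."""
        n = self.A_diag.size
        ab = np.zeros((3, n))
        ab[0, 1:] = self.A_upper[:-1]
        ab[1, :] = self.A_diag
        ab[2, :-1] = self.A_lower[1:]
        return solve_banded((1, 1), ab, self.rhs(u))


def assemble(
    state: CellState,
    fields: FieldSource,
    dt: float,
    *,
    field_values: FieldValues = None,
) -> TridiagonalSystem:
    """Assemble the per-step tridiagonal system on the current grid.

    Interior rows are the face-flux discretization with the harmonic
    spacing factor M = 2*mu/(dx_{i-1} + dx_i) and arithmetically
    face-averaged moduli.  Boundary rows follow ``state.mode``.
    """
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    provider = _as_fields(fields)
    x = state.x
    n = x.size
    dx = np.diff(x)
    if np.any(dx <= 0):
        raise GeometryError("node positions must be strictly increasing")
    fv = field_values if field_values is not None else provider.evaluate(x)
    mu = fv.mu

    if isinstance(fields, CellParameters) and dt >= fields.min_time_constant():
        warnings.warn(
            f"dt={dt} is not below the minimum viscoelastic time constant "
            f"{fields.min_time_constant():.3g} min; the explicit elastic "
            "update may be inaccurate",
            stacklevel=2,
        )

    A_lower = np.zeros(n)
    A_diag = np.zeros(n)
    A_upper = np.zeros(n)
    B_lower = np.zeros(n)
    B_diag = np.zeros(n)
    B_upper = np.zeros(n)
    C = np.zeros(n)

    # interior rows
    h_l = dx[:-1]
    h_r = dx[1:]
    span = h_l + h_r
    M = 2.0 * mu / span
    E_face_l = 0.5 * (fv.E[:-2] + fv.E[1:-1])
    E_face_r = 0.5 * (fv.E[1:-1] + fv.E[2:])
    w = 2.0 * dt / span
    A_lower[1:-1] = -M / h_l
    A_diag[1:-1] = fv.beta[1:-1] + M / h_l + M / h_r
    A_upper[1:-1] = -M / h_r
    B_lower[1:-1] = A_lower[1:-1] + w * E_face_l / h_l
    B_diag[1:-1] = A_diag[1:-1] - w * (E_face_l / h_l + E_face_r / h_r)
    B_upper[1:-1] = A_upper[1:-1] + w * E_face_r / h_r
    C[1:-1] = dt * (fv.tau[2:] - fv.tau[:-2]) / span

    mode = state.mode

    # Free-edge rows are half-cell balances in the same flux form as the
    # interior rows, with face-averaged E and tau at the inner face and the
    # imposed external stress (sigma_active at the front, 0 at the rear) at
    # the outer face.  This makes the weighted row sum telescope exactly to
    # sigma_active: the discretization transmits zero spurious net force,
    # which matters because the substrate drag balancing that force is
    # many orders of magnitude softer than the internal stresses.

    # leading edge (node n-1)
    if mode in (BoundaryMode.STEADY, BoundaryMode.FRONT_ADVANCE):
        h = dx[-1]
        wgt = 0.5 * h  # half-cell length
        E_face = 0.5 * (fv.E[-2] + fv.E[-1])
        tau_face = 0.5 * (fv.tau[-2] + fv.tau[-1])
        A_diag[-1] = fv.beta[-1] + mu / (h * wgt)
        A_lower[-1] = -mu / (h * wgt)
        B_diag[-1] = fv.beta[-1] + mu / (h * wgt) - dt * E_face / (h * wgt)
        B_lower[-1] = -mu / (h * wgt) + dt * E_face / (h * wgt)
        C[-1] = dt * (fv.sigma_active - tau_face) / wgt
    else:  # REAR_RETRACT: front anchored in place
        A_diag[-1] = 1.0
        B_diag[-1] = 1.0

    # trailing edge (node 0)
    if mode in (BoundaryMode.STEADY, BoundaryMode.REAR_RETRACT):
        h = dx[0]
        wgt = 0.5 * h
        E_face = 0.5 * (fv.E[0] + fv.E[1])
        tau_face = 0.5 * (fv.tau[0] + fv.tau[1])
        A_diag[0] = fv.beta[0] + mu / (h * wgt)
        A_upper[0] = -mu / (h * wgt)
        B_diag[0] = fv.beta[0] + mu / (h * wgt) - dt * E_face / (h * wgt)
        B_upper[0] = -mu / (h * wgt) + dt * E_face / (h * wgt)
        C[0] = dt * tau_face / wgt
    else:  # FRONT_ADVANCE: rear anchored in place
        A_diag[0] = 1.0
        B_diag[0] = 1.0

    return TridiagonalSystem(A_lower, A_diag, A_upper, B_lower, B_diag, B_upper, C)


def step(state: CellState, fields: FieldSource, dt: float) -> CellState:
    """Advance one time step: solve, update u, move the grid, advance t."""
    system = assemble(state, fields, dt)
    u_new = system.solve(state.u)
    # the banded solver pivots, smearing ~1 ulp into the Dirichlet rows;
    # anchored nodes must not creep, so reassert their values exactly
    if state.mode is BoundaryMode.FRONT_ADVANCE:
        u_new[0] = state.u[0]
    elif state.mode is BoundaryMode.REAR_RETRACT:
        u_new[-1] = state.u[-1]
    x_new = state.x0 + u_new
    if np.any(np.diff(x_new) <= 0):
        raise GeometryError(
            f"grid lost monotonicity at t={state.t + dt:.6g} min"
        )
    return CellState(x=x_new, u=u_new, t=state.t + dt, mode=state.mode)


def _gradient(u: np.ndarray, x: np.ndarray) -> np.ndarray:
    """du/dx: nonuniform central differences inside, one-sided at edges."""
    g = np.empty_like(u)
    h_l = x[1:-1] - x[:-2]
    h_r = x[2:] - x[1:-1]
    g[1:-1] = (
        h_l**2 * u[2:] - h_r**2 * u[:-2] + (h_r**2 - h_l**2) * u[1:-1]
    ) / (h_l * h_r * (h_l + h_r))
    g[0] = (u[1] - u[0]) / (x[1] - x[0])
    g[-1] = (u[-1] - u[-2]) / (x[-1] - x[-2])
    return g


def stress_field(
    state: CellState,
    u_prev: np.ndarray,
    dt: float,
    fields: FieldSource,
) -> np.ndarray:
    """Total stress sigma_i = E du/dx + mu d2u/(dt dx) + tau on the current grid."""
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    u_prev = np.asarray(u_prev, dtype=float)
    if u_prev.shape != state.u.shape:
        raise ValueError("u_prev must be conformable with state.u")
    fv = _as_fields(fields).evaluate(state.x)
    dudx = _gradient(state.u, state.x)
    dudx_prev = _gradient(u_prev, state.x)
    return fv.E * dudx + fv.mu * (dudx - dudx_prev) / dt + fv.tau


def rear_stress(
    state: CellState,
    u_prev: np.ndarray,
    dt: float,
    fields: FieldSource,
) -> float:
    """Stress sigma_1 carried by the first (rearmost) segment -- the
    switching monitor.

    With the rear anchored (FRONT_ADVANCE, and likewise for the free
    STEADY edge) the monitor is the elastic + active stress of the first
    segment -- the load the rear adhesion must resist:

        sigma_1 = E_{1/2} (u_2 - u_1)/dx_1 + tau_{1/2}.

    With the rear released (REAR_RETRACT) the rate term of the moving rear
    node is added and decays to zero as the tail comes to rest:

        sigma_1 = E_{1/2} (u_2 - u_1)/dx_1 + mu (u_1^{j+1} - u_1^j)/dt
                + tau_{1/2}.

    Both coefficients are face-averaged, matching the assembled fluxes: at
    the discrete rear-anchored equilibrium the face fluxes are uniform, so
    sigma_1 equals sigma_active exactly, and at the rear-released
    equilibrium it relaxes exactly to zero.  (A node-centred
    reconstruction E_1 u_2/dx_1 + tau_1 would carry an O(dx) bias from the
    strongly curved contractile profile, orders of magnitude above the
    transmitted stress at this model's scales.)
    """
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    fv = _as_fields(fields).evaluate(state.x[:2], r=state.rear, f=state.front)
    dx1 = state.x[1] - state.x[0]
    E_face = 0.5 * (fv.E[0] + fv.E[1])
    tau_face = 0.5 * (fv.tau[0] + fv.tau[1])
    sigma = E_face * (state.u[1] - state.u[0]) / dx1 + tau_face
    if state.mode is BoundaryMode.REAR_RETRACT:
        sigma += fv.mu * (state.u[0] - u_prev[0]) / dt
    return float(sigma)
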