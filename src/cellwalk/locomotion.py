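"""Simulation policies and the critical-stress walking state machine.

Three boundary-condition policies are supported:

* ``"steady"`` -- both edges free for the whole run (the steadily creeping
  reference cell).
* ``"front_advance"`` / ``"rear_retract"`` -- a single anchored-edge mode
  held fixed for the whole run (the rear-anchored run is the numerical
  experiment that records the build-up of rear stress).
* ``"walking"`` -- the two-step cycle: the run starts with the tail
  anchored and the protrusive stress driving the front
  (``FRONT_ADVANCE``); when the rear stress sigma_1 reaches the critical
  value sigma_c the anchors swap (``REAR_RETRACT``); when sigma_1 relaxes
  back to zero the cycle restarts.

Mode switches take effect at the next assembly; the full state is recorded
at every switch event in addition to the regular sampling stride so that
per-cycle statistics are exact.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import List, Optional, Union

import numpy as np
import pandas as pd

from . import fd
from .modes import BoundaryMode
from .parameters import CellParameters, GeometryError, ParameterFields

__all__ = ["BoundaryMode", "Trajectory", "SwitchEvent", "SimulationAborted",
           "update_mode", "simulate", "POLICIES"]

logger = logging.getLogger(__name__)

POLICIES = ("steady", "front_advance", "rear_retract", "walking")

_POLICY_MODE = {
    "steady": BoundaryMode.STEADY,
    "front_advance": BoundaryMode.FRONT_ADVANCE,
    "rear_retract": BoundaryMode.REAR_RETRACT,
    # the walk starts with the tail attached and the front advancing
    "walking": BoundaryMode.FRONT_ADVANCE,
}


@dataclasses.dataclass(frozen=True)
class SwitchEvent:
    t: float
    from_mode: BoundaryMode
    to_mode: BoundaryMode
    sigma1: float


@dataclasses.dataclass
class Trajectory:
    """Time series of edge positions, length, rear stress and mode."""

    t: np.ndarray
    rear: np.ndarray
    front: np.ndarray
    length: np.ndarray
    sigma1: np.ndarray
    mode: np.ndarray  # mode labels (str) per sample
    switch_times: List[SwitchEvent] = dataclasses.field(default_factory=list)

    def __post_init__(self) -> None:
        n = self.t.size
        for name in ("rear", "front", "length", "sigma1", "mode"):
            if getattr(self, name).size != n:
                raise ValueError(f"trajectory column {name!r} has wrong length")
        if n >= 2 and np.any(np.diff(self.t) <= 0):
            raise ValueError("sample times must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return self.t.size

    @property
    def n_switches(self) -> int:
        return len(self.switch_times)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.t,
                "rear": self.rear,
                "front": self.front,
                "length": self.length,
                "sigma1": self.sigma1,
                "mode": self.mode,
            }
        )

    def switches_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "t": ev.t,
                    "from": str(ev.from_mode),
                    "to": str(ev.to_mode),
                    "sigma1": ev.sigma1,
                }
                for ev in self.switch_times
            ],
            columns=["t", "from", "to", "sigma1"],
        )


class SimulationAborted(RuntimeError):
    """Mid-run geometry violation; carries the partial trajectory."""

    def __init__(self, reason: str, trajectory: Trajectory):
        super().__init__(reason)
        self.reason = reason
        self.trajectory = trajectory


def update_mode(
    mode: BoundaryMode,
    sigma1: float,
    sigma_c: float,
    tol: float = 0.0,
) -> BoundaryMode:
    """One transition of the critical-stress state machine.

    FRONT_ADVANCE -> REAR_RETRACT when the rear stress has reached the
    critical value (sigma1 >= sigma_c, inclusive); REAR_RETRACT ->
    FRONT_ADVANCE when it has relaxed to zero (sigma1 <= tol, inclusive).
    STEADY never switches.
    """
    if sigma_c <= 0:
        raise ValueError(f"sigma_c must be positive, got {sigma_c}")
    if mode is BoundaryMode.FRONT_ADVANCE and sigma1 >= sigma_c:
        return BoundaryMode.REAR_RETRACT
    if mode is BoundaryMode.REAR_RETRACT and sigma1 <= tol:
        return BoundaryMode.FRONT_ADVANCE
    return mode


class _Recorder:
    def __init__(self) -> None:
        self.t: List[float] = []
        self.rear: List[float] = []
        self.front: List[float] = []
        self.sigma1: List[float] = []
        self.mode: List[str] = []
        self.switches: List[SwitchEvent] = []

    def sample(self, state: fd.CellState, sigma1: float) -> None:
        # switch events may coincide with the sampling stride: keep one row
        if self.t and state.t == self.t[-1]:
            return
        self.t.append(state.t)
        self.rear.append(state.rear)
        self.front.append(state.front)
        self.sigma1.append(sigma1)
        self.mode.append(str(state.mode))

    def build(self) -> Trajectory:
        t = np.asarray(self.t)
        rear = np.asarray(self.rear)
        front = np.asarray(self.front)
        return Trajectory(
            t=t,
            rear=rear,
            front=front,
            length=front - rear,
            sigma1=np.asarray(self.sigma1),
            mode=np.asarray(self.mode, dtype=object),
            switch_times=self.switches,
        )


def simulate(
    params: CellParameters,
    policy: Union[str, BoundaryMode] = "steady",
    T: float = 100.0,
    dt: float = 1e-4,
    n: int = 101,
    sample_every: int = 100,
    tol: float = 0.0,
    sigma_c: Optional[float] = None,
) -> Trajectory:
    """Run the cell for ``T`` minutes and return its trajectory.

    ``sigma_c`` overrides ``params.sigma_c`` for the walking policy.  The
    run is deterministic: identical inputs give identical trajectories.
    """
    if isinstance(policy, BoundaryMode):
        policy = policy.value
    if policy not in POLICIES:
        raise ValueError(f"unknown policy {policy!r}; expected one of {POLICIES}")
    if T <= 0 or dt <= 0:
        raise ValueError("T and dt must be positive")
    if n < 3:
        raise ValueError(f"need at least 3 nodes, got {n}")
    if sample_every < 1:
        raise ValueError("sample_every must be >= 1")
    if dt >= params.min_time_constant():
        warnings.warn(
            f"dt={dt} min is not below the minimum viscoelastic time constant "
            f"{params.min_time_constant():.3g} min",
            stacklevel=2,
        )
    sigma_c = params.sigma_c if sigma_c is None else float(sigma_c)
    walking = policy == "walking"

    provider = ParameterFields(params)
    state = fd.initial_state(params, n=n, mode=_POLICY_MODE[policy])
    rec = _Recorder()
    rec.sample(state, fd.rear_stress(state, state.u, dt, provider))

    n_steps = int(round(T / dt))
    try:
        for j in range(n_steps):
            u_prev = state.u
            state = fd.step(state, provider, dt)
            sigma1 = fd.rear_stress(state, u_prev, dt, provider)
            if walking:
                new_mode = update_mode(state.mode, sigma1, sigma_c, tol)
                if new_mode is not state.mode:
                    ev = SwitchEvent(state.t, state.mode, new_mode, sigma1)
                    rec.switches.append(ev)
                    rec.sample(state, sigma1)
                    logger.info(
                        "t=%.6f min: %s -> %s (sigma1=%.6g N/mm^2)",
                        ev.t, ev.from_mode, ev.to_mode, ev.sigma1,
                    )
                    state.mode = new_mode
            if (j + 1) % sample_every == 0 or j == n_steps - 1:
                rec.sample(state, sigma1)
    except GeometryError as err:
        traj = rec.build()
        raise SimulationAborted(
            f"simulation aborted at t={state.t:.6g} min: {err}", traj
        ) from err
    return rec.build()
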