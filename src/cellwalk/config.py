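"""Configuration loading, presets and result serialization.

A run is described by a flat YAML (or JSON) mapping holding any subset of
the :class:`~cellwalk.parameters.CellParameters` fields plus the run
settings (policy, T, dt, n_nodes, sample_every, output_prefix, log_level,
seed).  Missing physical parameters are filled from the bundled ``table1``
preset; unknown keys are rejected.

Two presets ship with the package:

* ``table1`` -- the tabulated reference cell, all scale factors 1.
* ``table1_calibrated`` -- same cell with the documented stress-scale
  calibration applied (see docs/methods.md): ``active_scale`` fitted so
  the steady 100-minute run travels at 0.2 um/min and ``tau_scale`` set so
  the peak contractile strain is ~10%.

Trajectory tables are written as CSV with 12 significant digits so that
repeated runs are byte-identical and parse back losslessly.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import json
import logging
from pathlib import Path
from typing import Optional, Union

import pandas as pd
import yaml

from .locomotion import SwitchEvent, Trajectory
from .modes import BoundaryMode
from .parameters import CellParameters, InvalidParameterError

__all__ = [
    "RunConfig",
    "load_config",
    "save_config",
    "load_preset",
    "preset_path",
    "params_to_dict",
    "trajectory_to_csv",
    "trajectory_from_csv",
    "switches_to_csv",
]

logger = logging.getLogger(__name__)

PARAM_KEYS = tuple(f.name for f in dataclasses.fields(CellParameters))
RUN_KEYS = ("policy", "T", "dt", "n_nodes", "sample_every", "output_prefix",
            "log_level", "seed")

#: CSV float format: 12 significant digits
FLOAT_FMT = "%.12g"


@dataclasses.dataclass
class RunConfig:
    """Validated bundle of physical parameters and run settings."""

    params: CellParameters = dataclasses.field(default_factory=CellParameters)
    policy: str = "steady"
    T: float = 100.0
    dt: float = 1e-4
    n_nodes: int = 101
    sample_every: int = 100
    output_prefix: str = "cellwalk"
    log_level: str = "INFO"
    seed: int = 0  # reserved; the model is deterministic

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise InvalidParameterError(f"T must be positive, got {self.T}")
        if self.dt <= 0:
            raise InvalidParameterError(f"dt must be positive, got {self.dt}")
        if self.n_nodes < 3:
            raise InvalidParameterError(f"n_nodes must be >= 3, got {self.n_nodes}")
        if self.sample_every < 1:
            raise InvalidParameterError(
                f"sample_every must be >= 1, got {self.sample_every}"
            )
        if self.dt >= self.params.min_time_constant():
            logger.warning(
                "dt=%g min is not below the minimum viscoelastic time "
                "constant %g min", self.dt, self.params.min_time_constant(),
            )


def params_to_dict(params: CellParameters) -> dict:
    return dataclasses.asdict(params)


def preset_path(name: str = "table1") -> Path:
    """Filesystem path of a bundled preset YAML."""
    ref = importlib.resources.files("cellwalk") / "presets" / f"{name}.yaml"
    if not ref.is_file():
        raise FileNotFoundError(f"no bundled preset named {name!r}")
    return Path(str(ref))


def load_preset(name: str = "table1") -> CellParameters:
    """Load a bundled parameter preset by name."""
    with open(preset_path(name)) as fh:
        raw = yaml.safe_load(fh) or {}
    return CellParameters(**raw)


def _build_params(raw: dict) -> CellParameters:
    try:
        return CellParameters(**raw)
    except TypeError as err:  # unexpected kw never happens: keys pre-checked
        raise InvalidParameterError(str(err)) from err


def load_config(path: Union[str, Path]) -> RunConfig:
    """Read and validate a run configuration file (YAML or JSON).

    An empty file yields the full table1 defaults.  Unknown keys are
    rejected with a descriptive error; missing physical parameters are
    filled from the table1 preset with a logged notice.
    """
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise InvalidParameterError(
            f"{path}: expected a key-value mapping at the top level"
        )
    unknown = sorted(set(raw) - set(PARAM_KEYS) - set(RUN_KEYS))
    if unknown:
        raise InvalidParameterError(
            f"{path}: unknown configuration key(s): {', '.join(unknown)}"
        )
    param_raw = {k: raw[k] for k in raw if k in PARAM_KEYS}
    run_raw = {k: raw[k] for k in raw if k in RUN_KEYS}
    missing = sorted(set(PARAM_KEYS) - set(param_raw))
    if missing:
        logger.info(
            "%s: %d parameter(s) not given, filled from the table1 preset: %s",
            path, len(missing), ", ".join(missing),
        )
    return RunConfig(params=_build_params(param_raw), **run_raw)


def save_config(config: RunConfig, path: Union[str, Path]) -> None:
    """Serialize a RunConfig back to YAML (round-trips value-identically)."""
    data = dict(params_to_dict(config.params))
    for key in RUN_KEYS:
        data[key] = getattr(config, key)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


# -- trajectory serialization ---------------------------------------------


def trajectory_to_csv(traj: Trajectory, path: Union[str, Path]) -> None:
    traj.to_frame().to_csv(path, index=False, float_format=FLOAT_FMT)


def switches_to_csv(traj: Trajectory, path: Union[str, Path]) -> None:
    traj.switches_frame().to_csv(path, index=False, float_format=FLOAT_FMT)


def trajectory_from_csv(
    path: Union[str, Path], switches: Optional[Union[str, Path]] = None
) -> Trajectory:
    df = pd.read_csv(path)
    events = []
    if switches is not None:
        sw = pd.read_csv(switches)
        events = [
            SwitchEvent(
                t=float(row["t"]),
                from_mode=BoundaryMode(row["from"]),
                to_mode=BoundaryMode(row["to"]),
                sigma1=float(row["sigma1"]),
            )
            for row in sw.to_dict("records")
        ]
    return Trajectory(
        t=df["t"].to_numpy(),
        rear=df["rear"].to_numpy(),
        front=df["front"].to_numpy(),
        length=df["length"].to_numpy(),
        sigma1=df["sigma1"].to_numpy(),
        mode=df["mode"].to_numpy(dtype=object),
        switch_times=events,
    )
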