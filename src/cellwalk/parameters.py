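"""Physical parameters and spatially varying material fields.

Unit system: length in mm, time in minutes, force in N.  Stresses are
N/mm^2, the viscosity ``mu`` is N*min/mm^2 and the drag constant ``beta0``
is N*min/mm^3.  With these conventions the minimum viscoelastic time
constant mu / max E(x) of the default cell is 6.67e-4 minutes, which fixes
the admissible time step of the solver.

The cell is graded front to rear:

* ``actin_density`` a(x): a smoothed step (arctan) in the actin network
  density, low behind the midpoint and high ahead of it.
* ``elastic_modulus`` E(x) = E0 * a(x): stiffness follows the actin density.
* ``drag_coefficient`` beta(x): adhesive friction against the substrate,
  weakest at the rear (bond dissociation increases rearwards by the factor
  psi1) and strongest at the front.
* ``active_stress_profile`` tau(x): contractile actomyosin stress
  (non-positive), modulated by myosin kinetics, a regulatory-protein
  activation ratio, a Hill-type bound-integrin factor and the actin density.

All field functions are pure.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Union

import numpy as np

__all__ = [
    "CellParameters",
    "FieldValues",
    "ParameterFields",
    "GeometryError",
    "InvalidParameterError",
    "actin_density",
    "elastic_modulus",
    "drag_coefficient",
    "active_stress_profile",
    "frontal_active_stress",
    "min_time_constant",
    "ACTIN_BASE",
    "ACTIN_SUP",
    "ACTIN_GAIN",
]

ArrayLike = Union[float, np.ndarray]

#: prefactor of the fitted actin-density step, 1/mm
ACTIN_BASE = 2.381e9
#: steepness of the step, 1/mm
ACTIN_GAIN = 700.0
#: supremum of a(x): base * (2 + 1) as arctan -> pi/2
ACTIN_SUP = 3.0 * ACTIN_BASE


class GeometryError(ValueError):
    """Raised when the cell geometry is degenerate (front not ahead of rear)."""


class InvalidParameterError(ValueError):
    """Raised when a physical parameter violates its constraints."""


def actin_density(x: ArrayLike, x_mid: ArrayLike) -> ArrayLike:
    """Actin network density a(x) in 1/mm.

    A smoothed step centred on ``x_mid``: a = base * ((2/pi) * arctan(
    gain*(x - x_mid)) + 2).  Strictly increasing, bounded in
    (ACTIN_BASE, ACTIN_SUP).
    """
    return ACTIN_BASE * ((2.0 / np.pi) * np.arctan(ACTIN_GAIN * (x - x_mid)) + 2.0)


def elastic_modulus(x: ArrayLike, x_mid: ArrayLike, E0: float) -> ArrayLike:
    """Elastic modulus E(x) = E0 * a(x), N/mm^2."""
    return E0 * actin_density(x, x_mid)


def _edge_fraction(x: ArrayLike, r: float, f: float) -> ArrayLike:
    if not f > r:
        raise GeometryError(f"degenerate cell: front {f} not ahead of rear {r}")
    return (np.asarray(x) - r) / (f - r)


def drag_coefficient(
    x: ArrayLike,
    r: float,
    f: float,
    *,
    beta0: float,
    k_s: float,
    psi1: float,
    n_f: float,
) -> ArrayLike:
    """Cell--substrate drag beta(x), N*min/mm^3.

    beta = beta0 * k_s * n_f / [psi1 + (1 - psi1)*(x - r)/(f - r)].  The
    bracket interpolates from psi1 at the rear to 1 at the front, so for
    psi1 > 1 adhesion (drag) is weakest at the rear, where bond
    dissociation is fastest, and strongest at the leading edge.
    """
    s = _edge_fraction(x, r, f)
    return beta0 * k_s * n_f / (psi1 + (1.0 - psi1) * s)


def active_stress_profile(
    x: ArrayLike,
    r: float,
    f: float,
    x_mid: float,
    *,
    tau0: float,
    kreg_ratio: float,
    psi2: float,
    n_b: float,
    n_b0: float,
    alpha: float,
    km_ratio: float,
    m_f: float,
    tau_scale: float = 1.0,
) -> ArrayLike:
    """Contractile actomyosin stress tau(x) <= 0, N/mm^2.

    tau = -tau_scale * tau0 * kreg_ratio / [psi2 + (1-psi2)*(x-r)/(f-r)]
          * n_b^alpha / (n_b0^alpha + n_b^alpha) * km_ratio * m_f * a(x)

    The magnitude grows toward the front through the actin density a(x)
    and shrinks toward the rear through the psi2 bracket.
    """
    s = _edge_fraction(x, r, f)
    hill = n_b**alpha / (n_b0**alpha + n_b**alpha)
    return (
        -tau_scale
        * tau0
        * kreg_ratio
        / (psi2 + (1.0 - psi2) * s)
        * hill
        * km_ratio
        * m_f
        * actin_density(x, x_mid)
    )


def frontal_active_stress(F_active: float, S_cell: float, active_scale: float = 1.0) -> float:
    """Protrusive stress at the leading edge, sigma_active = scale * F / S."""
    if S_cell <= 0:
        raise InvalidParameterError(f"S_cell must be positive, got {S_cell}")
    return active_scale * F_active / S_cell


def min_time_constant(mu: float, E0: float) -> float:
    """Minimum Kelvin--Voigt time constant mu / max_x E(x), in minutes."""
    if E0 <= 0:
        raise InvalidParameterError(f"E0 must be positive, got {E0}")
    return mu / (E0 * ACTIN_SUP)


_POSITIVE = (
    "k_s",
    "km_ratio",
    "kreg_ratio",
    "alpha",
    "beta0",
    "n_f",
    "n_b0",
    "n_b",
    "m_f",
    "tau0",
    "E0",
    "mu",
    "L0",
    "S_cell",
    "sigma_c",
)
_NON_NEGATIVE = ("F_active", "active_scale", "tau_scale")


@dataclasses.dataclass(frozen=True)
class CellParameters:
    """Single source of the physical constants of the model cell.

    Defaults are the tabulated reference cell; ``active_scale`` and
    ``tau_scale`` are dimensionless multipliers (default 1) on the
    protrusive stress and the contractile stress respectively -- the knobs
    the calibrated preset uses to bring the tabulated stress magnitudes
    into the regime where the observed migration speed is reproduced.
    """

    k_s: float = 0.05  # cell-substrate interaction coefficient
    psi1: float = 3.33  # rearward increase of bond dissociation (drag)
    psi2: float = 10.0  # analogous gradient factor in tau(x)
    km_ratio: float = 0.3  # myosin binding/decay rate ratio
    kreg_ratio: float = 0.1  # regulatory activation ratio
    alpha: float = 0.2  # regulatory-protein/integrin coupling degree
    beta0: float = 5e-6  # drag constant, N*min/mm^3
    n_f: float = 5490.0  # free integrin density, 1/mm
    n_b0: float = 12500.0  # typical bound integrin density, 1/mm
    n_b: float = 12500.0  # bound integrin density, 1/mm (taken = n_b0)
    m_f: float = 690.0  # free myosin concentration, 1/mm
    tau0: float = 4.2e-10  # active stress constant, N/mm
    E0: float = 0.42e-10  # elastic modulus constant, N/mm
    mu: float = 0.0002  # viscosity, N*min/mm^2
    L0: float = 0.05  # initial cell length, mm
    F_active: float = 1e-6  # frontal protrusive force, N (1000 nN)
    S_cell: float = 3e-5  # cell cross-section, mm^2 (30 um^2)
    sigma_c: float = 1.4e-7  # critical rear stress, N/mm^2
    active_scale: float = 1.0  # multiplier on sigma_active
    tau_scale: float = 1.0  # multiplier on tau(x)

    def __post_init__(self) -> None:
        for name in _POSITIVE:
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise InvalidParameterError(f"{name} must be strictly positive, got {v}")
        for name in _NON_NEGATIVE:
            v = getattr(self, name)
            if not (math.isfinite(v) and v >= 0):
                raise InvalidParameterError(f"{name} must be non-negative, got {v}")
        if self.psi1 < 1:
            raise InvalidParameterError(f"psi1 must be >= 1, got {self.psi1}")
        if self.psi2 < 1:
            raise InvalidParameterError(f"psi2 must be >= 1, got {self.psi2}")

    # -- bound field evaluators -------------------------------------------

    def actin_density(self, x: ArrayLike, x_mid: float) -> ArrayLike:
        return actin_density(x, x_mid)

    def elastic_modulus(self, x: ArrayLike, x_mid: float) -> ArrayLike:
        return elastic_modulus(x, x_mid, self.E0)

    def drag_coefficient(self, x: ArrayLike, r: float, f: float) -> ArrayLike:
        return drag_coefficient(
            x, r, f, beta0=self.beta0, k_s=self.k_s, psi1=self.psi1, n_f=self.n_f
        )

    def active_stress_profile(
        self, x: ArrayLike, r: float, f: float, x_mid: float
    ) -> ArrayLike:
        return active_stress_profile(
            x,
            r,
            f,
            x_mid,
            tau0=self.tau0,
            kreg_ratio=self.kreg_ratio,
            psi2=self.psi2,
            n_b=self.n_b,
            n_b0=self.n_b0,
            alpha=self.alpha,
            km_ratio=self.km_ratio,
            m_f=self.m_f,
            tau_scale=self.tau_scale,
        )

    @property
    def sigma_active(self) -> float:
        return frontal_active_stress(self.F_active, self.S_cell, self.active_scale)

    def min_time_constant(self) -> float:
        return min_time_constant(self.mu, self.E0)

    def replace(self, **changes) -> "CellParameters":
        return dataclasses.replace(self, **changes)

    def fields(self) -> "ParameterFields":
        return ParameterFields(self)


@dataclasses.dataclass(frozen=True)
class FieldValues:
    """Material fields evaluated on a node array."""

    beta: np.ndarray  # drag, N*min/mm^3
    E: np.ndarray  # elastic modulus, N/mm^2
    tau: np.ndarray  # active stress, N/mm^2
    sigma_active: float  # protrusive stress at the front, N/mm^2
    mu: float  # viscosity, N*min/mm^2


class ParameterFields:
    """Evaluates the material fields of a :class:`CellParameters` cell.

    The midpoint of the actin step is re-evaluated as (r + f)/2 on every
    call, so the stiffness/contractility profile travels with the cell.
    """

    def __init__(self, params: CellParameters):
        self.params = params
        p = params
        # geometry-independent prefactors, hoisted out of the stepping loop
        self._beta_num = p.beta0 * p.k_s * p.n_f
        hill = p.n_b**p.alpha / (p.n_b0**p.alpha + p.n_b**p.alpha)
        self._tau_num = p.tau_scale * p.tau0 * p.kreg_ratio * hill * p.km_ratio * p.m_f
        self._sigma_active = p.sigma_active

    def evaluate(self, x: np.ndarray, r: float = None, f: float = None) -> FieldValues:
        """Fields on node array ``x``; cell extent defaults to [x[0], x[-1]].

        Passing ``r``/``f`` explicitly evaluates on a sub-array of a larger
        cell without changing the geometry the gradients refer to.
        """
        p = self.params
        if r is None:
            r = float(x[0])
        if f is None:
            f = float(x[-1])
        if not f > r:
            raise GeometryError(f"degenerate cell: front {f} not ahead of rear {r}")
        x_mid = 0.5 * (r + f)
        s = (x - r) / (f - r)
        a = actin_density(x, x_mid)
        return FieldValues(
            beta=self._beta_num / (p.psi1 + (1.0 - p.psi1) * s),
            E=p.E0 * a,
            tau=-self._tau_num / (p.psi2 + (1.0 - p.psi2) * s) * a,
            sigma_active=self._sigma_active,
            mu=p.mu,
        )
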