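"""Finite-difference core: oracle equivalence, fixed points, closed forms."""

import numpy as np
import pytest

from cellwalk import CellParameters, GeometryError, initial_state, rear_stress, step, stress_field
from cellwalk import fd
from cellwalk.modes import BoundaryMode


def dense_step(state, fields, dt):
    """Independent oracle: assemble the per-step system as dense matrices
    directly from the discretized balance law (scalar loops, no shared code
    with the banded implementation) and solve with numpy."""
    x = state.x
    n = x.size
    fv = fields.evaluate(x)
    beta, E, tau, mu, sig_a = fv.beta, fv.E, fv.tau, fv.mu, fv.sigma_active
    A = np.zeros((n, n))
    B = np.zeros((n, n))
    C = np.zeros(n)

    def face(arr, i, j):
        return 0.5 * (arr[i] + arr[j])

    for i in range(1, n - 1):
        hl = x[i] - x[i - 1]
        hr = x[i + 1] - x[i]
        w = 0.5 * (hl + hr)
        # beta_i du/dt = d(sigma)/dx, viscous implicit / elastic+tau explicit
        A[i, i - 1] += -mu / (hl * w)
        A[i, i] += beta[i] + mu / (hl * w) + mu / (hr * w)
        A[i, i + 1] += -mu / (hr * w)
        B[i, i - 1] += -mu / (hl * w) + dt * face(E, i - 1, i) / (hl * w)
        B[i, i] += (
            beta[i]
            + mu / (hl * w)
            + mu / (hr * w)
            - dt * (face(E, i - 1, i) / hl + face(E, i, i + 1) / hr) / w
        )
        B[i, i + 1] += -mu / (hr * w) + dt * face(E, i, i + 1) / (hr * w)
        C[i] += dt * (face(tau, i, i + 1) - face(tau, i - 1, i)) / w

    # leading edge
    if state.mode in (BoundaryMode.STEADY, BoundaryMode.FRONT_ADVANCE):
        h = x[-1] - x[-2]
        w = 0.5 * h
        A[-1, -2] += -mu / (h * w)
        A[-1, -1] += beta[-1] + mu / (h * w)
        B[-1, -2] += -mu / (h * w) + dt * face(E, n - 2, n - 1) / (h * w)
        B[-1, -1] += beta[-1] + mu / (h * w) - dt * face(E, n - 2, n - 1) / (h * w)
        C[-1] += dt * (sig_a - face(tau, n - 2, n - 1)) / w
    else:
        A[-1, -1] = 1.0
        B[-1, -1] = 1.0

    # trailing edge
    if state.mode in (BoundaryMode.STEADY, BoundaryMode.REAR_RETRACT):
        h = x[1] - x[0]
        w = 0.5 * h
        A[0, 1] += -mu / (h * w)
        A[0, 0] += beta[0] + mu / (h * w)
        B[0, 1] += -mu / (h * w) + dt * face(E, 0, 1) / (h * w)
        B[0, 0] += beta[0] + mu / (h * w) - dt * face(E, 0, 1) / (h * w)
        C[0] += dt * face(tau, 0, 1) / w
    else:
        A[0, 0] = 1.0
        B[0, 0] = 1.0

    return np.linalg.solve(A, B @ state.u + C)


@pytest.mark.parametrize("mode", list(BoundaryMode))
@pytest.mark.parametrize("n", [3, 5, 11])
def test_banded_solution_matches_dense_oracle(table1, mode, n):
    """Every step of the banded solver equals an independent dense solve."""
    params = table1.replace(tau_scale=1e-3, active_scale=2e-7)
    provider = params.fields()
    state = initial_state(params, n=n, mode=mode)
    dt = 1e-4
    for _ in range(5):
        expected = dense_step(state, provider, dt)
        state = step(state, provider, dt)
        np.testing.assert_allclose(state.u, expected, rtol=1e-12, atol=1e-15)


def test_zero_forcing_fixed_point_long_run(constant_fields_factory):
    """With no forcing the rest state is preserved over one million steps."""
    fields = constant_fields_factory(beta=1e-3, E=0.2, tau=0.0, sigma_active=0.0, mu=2e-4)
    state = initial_state(0.05, n=11, mode=BoundaryMode.STEADY)
    dt = 1e-4
    for _ in range(1_000_000):
        state = step(state, fields, dt)
    assert np.max(np.abs(state.u)) < 1e-14
    assert state.t == pytest.approx(100.0, rel=1e-9)


def test_zero_forcing_is_exact_fixed_point_each_mode(constant_fields_factory):
    fields = constant_fields_factory(beta=1e-3, E=0.2, tau=0.0, sigma_active=0.0, mu=2e-4)
    for mode in BoundaryMode:
        state = initial_state(0.05, n=7, mode=mode)
        out = step(state, fields, 1e-4)
        assert np.max(np.abs(out.u)) < 1e-16
        assert out.t == pytest.approx(1e-4)


def test_constant_coefficient_closed_form_limit(constant_fields_factory):
    """Rear-anchored rod under constant frontal stress relaxes to a linear
    displacement profile with uniform stress equal to sigma_active.

    The strain is measured on the deformed grid, so the converged profile
    in the reference coordinate is u = c/(1-c) * (x0 - x0_rear) with
    c = sigma_active/E (a 0.5% finite-strain correction at these values)."""
    E, mu, beta, sig_a = 0.2, 2e-4, 1e-3, 1e-3
    fields = constant_fields_factory(beta=beta, E=E, tau=0.0, sigma_active=sig_a, mu=mu)
    state = initial_state(0.05, n=21, mode=BoundaryMode.FRONT_ADVANCE)
    dt = 1e-4
    relax = mu / E  # slowest time constant here
    u_prev = state.u
    for _ in range(int(10 * relax / dt) + 200):
        u_prev = state.u
        state = step(state, fields, dt)
    c = sig_a / E
    expected = c / (1.0 - c) * (state.x0 - state.x0[0])
    np.testing.assert_allclose(state.u, expected, rtol=1e-3, atol=1e-12)
    sigma = stress_field(state, u_prev, dt, fields)
    assert np.max(np.abs(sigma - sig_a)) / sig_a < 1e-3


def test_dirichlet_rows_pin_nodes_exactly(constant_fields_factory):
    fields = constant_fields_factory(beta=1e-3, E=0.2, tau=-0.01, sigma_active=1e-3, mu=2e-4)
    rear_pinned = initial_state(0.05, n=9, mode=BoundaryMode.FRONT_ADVANCE)
    for _ in range(50):
        rear_pinned = step(rear_pinned, fields, 1e-4)
    assert rear_pinned.u[0] == 0.0
    front_pinned = initial_state(0.05, n=9, mode=BoundaryMode.REAR_RETRACT)
    for _ in range(50):
        front_pinned = step(front_pinned, fields, 1e-4)
    assert front_pinned.u[-1] == 0.0


def test_dt_refinement_first_order_convergence(constant_fields_factory):
    """Halving dt shrinks the front-displacement error consistently with at
    least first-order accuracy in time."""
    fields = constant_fields_factory(beta=1e-3, E=0.2, tau=0.0, sigma_active=1e-3, mu=2e-4)

    def front_disp(dt, T=4e-3):
        state = initial_state(0.05, n=11, mode=BoundaryMode.FRONT_ADVANCE)
        for _ in range(int(round(T / dt))):
            state = step(state, fields, dt)
        return state.u[-1]

    ref = front_disp(2e-5 / 16)
    errors = [abs(front_disp(dt) - ref) for dt in (2e-5, 1e-5, 5e-6)]
    ratios = [errors[i] / errors[i + 1] for i in range(2)]
    assert all(r >= 1.8 for r in ratios), ratios


def test_grid_monotonicity_guard():
    params = CellParameters()  # printed scales: contraction far too strong
    provider = params.fields()
    state = initial_state(params, n=101, mode=BoundaryMode.STEADY)
    with pytest.raises(GeometryError):
        for _ in range(100):
            state = step(state, provider, 1e-4)


class TestStressField:
    def test_zero_state(self, constant_fields_factory):
        fields = constant_fields_factory(beta=1e-3, E=0.2, tau=0.0, sigma_active=0.0, mu=2e-4)
        state = initial_state(0.05, n=11)
        sigma = stress_field(state, state.u, 1e-4, fields)
        assert np.all(sigma == 0.0)

    def test_linear_static_field(self, constant_fields_factory):
        E = 0.2
        fields = constant_fields_factory(beta=1e-3, E=E, tau=0.0, sigma_active=0.0, mu=2e-4)
        state = initial_state(0.05, n=11)
        c = 1e-3
        u = c * (state.x - state.x[0])
        state = fd.CellState(x=state.x, u=u, t=0.0, mode=BoundaryMode.STEADY)
        sigma = stress_field(state, u, 1e-4, fields)
        np.testing.assert_allclose(sigma, E * c, rtol=1e-12)

    def test_converges_to_analytic_derivative(self, constant_fields_factory):
        E = 0.2
        fields = constant_fields_factory(beta=1e-3, E=E, tau=0.0, sigma_active=0.0, mu=2e-4)

        def err(n):
            x = np.linspace(0.0, 0.05, n)
            u = 1e-3 * np.sin(40.0 * x)
            state = fd.CellState(x=x, u=u, t=0.0, mode=BoundaryMode.STEADY)
            sigma = stress_field(state, u, 1e-4, fields)
            exact = E * 1e-3 * 40.0 * np.cos(40.0 * x)
            return np.max(np.abs(sigma[1:-1] - exact[1:-1]))

        assert err(801) < err(101) / 16  # interior differences are second order

    def test_rejects_bad_dt(self, constant_fields_factory):
        fields = constant_fields_factory(beta=1e-3, E=0.2, tau=0.0, sigma_active=0.0, mu=2e-4)
        state = initial_state(0.05, n=5)
        with pytest.raises(ValueError):
            stress_field(state, state.u, 0.0, fields)


class TestRearStress:
    def test_zero_displacement_zero_tau(self, constant_fields_factory):
        fields = constant_fields_factory(beta=1e-3, E=0.2, tau=0.0, sigma_active=0.0, mu=2e-4)
        state = initial_state(0.05, n=11, mode=BoundaryMode.FRONT_ADVANCE)
        assert rear_stress(state, state.u, 1e-4, fields) == 0.0

    def test_elastic_term_value(self, constant_fields_factory):
        # sigma_1 = E1 * u2 / dx1 = 0.2 * 1e-6 / 5e-4 = 4e-4
        fields = constant_fields_factory(beta=1e-3, E=0.2, tau=0.0, sigma_active=0.0, mu=2e-4)
        state = initial_state(0.05, n=101, mode=BoundaryMode.FRONT_ADVANCE)
        u = np.zeros(101)
        u[1:] = 1e-6
        state = fd.CellState(x=state.x, u=u, t=0.0, mode=BoundaryMode.FRONT_ADVANCE)
        assert rear_stress(state, u, 1e-4, fields) == pytest.approx(4e-4, rel=1e-12)

    def test_viscous_rate_term_of_moving_rear(self, constant_fields_factory):
        mu = 2e-4
        fields = constant_fields_factory(beta=1e-3, E=0.2, tau=0.0, sigma_active=0.0, mu=mu)
        x = np.linspace(0.0, 0.05, 11)
        u = np.full(11, 2e-6)  # uniform: elastic part vanishes
        state = fd.CellState(x=x, u=u, t=1.0, mode=BoundaryMode.REAR_RETRACT)
        u_prev = u.copy()
        u_prev[0] = 1e-6  # rear node moved during the last step
        dt = 1e-4
        expected = mu * (u[0] - u_prev[0]) / dt
        assert rear_stress(state, u_prev, dt, fields) == pytest.approx(expected, rel=1e-12)

    def test_rate_term_vanishes_when_strain_static(self, constant_fields_factory):
        """A statically strained cell reads the same rear stress in either
        anchoring mode (the rate term only reflects strain-rate)."""
        fields = constant_fields_factory(beta=1e-3, E=0.2, tau=0.0, sigma_active=0.0, mu=2e-4)
        x = np.linspace(0.0, 0.05, 11)
        u = 1e-5 * (x - x[0])
        sa = fd.CellState(x=x, u=u, t=1.0, mode=BoundaryMode.REAR_RETRACT)
        sb = fd.CellState(x=x, u=u, t=1.0, mode=BoundaryMode.FRONT_ADVANCE)
        assert rear_stress(sa, u, 1e-4, fields) == rear_stress(sb, u, 1e-4, fields)
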