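import numpy as np
import pytest
from scipy.integrate import solve_ivp

from tanwell import Geometry, SolverConfig, build_grid, run, step
from tanwell.geometry import ConfigurationError
from tanwell.kinetics import FIELDS, IDX, State, TreatmentFlags, reaction_rates


def _no_transport(p):
    return p.replace(
        D_n=0.0, D_N1=0.0, D_N2=0.0, D_C=0.0, D_G=0.0, D_E=0.0, D_P=0.0,
        D_D=0.0, D_M=0.0, D_A=0.0, chi_E=0.0, chi_rho=0.0, chi_N1=0.0,
        chi_N2=0.0, gamma_cells=0.0, gamma_mol=0.0,
    )


class TestSolverConfig:
    def test_inconsistent_steps_rejected(self):
        with pytest.raises(ConfigurationError):
            SolverConfig(dt_init=1e-3, dt_min=1e-2)

    def test_nonpositive_tolerance_rejected(self):
        with pytest.raises(ConfigurationError):
            SolverConfig(newton_tol=0.0)


class TestStep:
    def test_zero_state_is_a_fixed_point(self, params, grid):
        out = step(State.zeros(grid.n_cells), 0.01, params, grid)
        assert not np.any(out.fields)
        assert out.t == pytest.approx(0.01)

    def test_pure_decay_matches_exponential(self, params, grid):
        """Single-field decay over one step; trapezoidal kinetics keep the
        one-step defect at third order in dt."""
        p = _no_transport(params).replace(lam_C=0.0)
        s = State.zeros(grid.n_cells)
        s["C"] = 1.0
        dt = 1e-2
        out = step(s, dt, p, grid)
        exact = np.exp(-p.mu_C * dt)
        assert np.max(np.abs(out["C"] - exact)) < (p.mu_C * dt) ** 3

    def test_nonpositive_dt_rejected(self, params, grid):
        with pytest.raises(ConfigurationError):
            step(State.zeros(grid.n_cells), 0.0, params, grid)


class TestWellMixedOracle:
    def test_transport_off_matches_independent_ode_solver(self, params):
        """Uniform fields with all transport off reduce to one ODE system
        per cell; an independent stiff integration of the same kinetics
        agrees to 1e-8."""
        geo = Geometry(ecm_interval=(0.25, 0.75))
        grid = build_grid(geo, 0.25)
        p = _no_transport(params).replace(lam_A=1.0)
        flags = TreatmentFlags(dnase=True, timp=True, antibody=True)
        s = State.zeros(grid.n_cells)
        for name, v in [("n", 0.4), ("N1", 0.8), ("N2", 0.05), ("rho", 1.0),
                        ("G", 0.2), ("E", 0.1), ("C", 0.3)]:
            s[name] = v
        S_mask = grid.ecm_mask()
        inj = grid.injection_mask()
        t_end = 1.5

        cfg = SolverConfig(dt_init=1e-4, dt_max=2e-4, newton_tol=1e-13)
        traj = run(s, p, grid, t_end, cfg=cfg, flags=flags)
        got = traj.final().fields

        # oracle: scipy LSODA on the per-cell ODE (whole grid at once)
        def rhs(_, y):
            u = y.reshape(len(FIELDS), grid.n_cells)
            r = reaction_rates(u, p, S_mask, inj, flags)
            # match the integrator's floor at rho = 0
            r[IDX["rho"]][u[IDX["rho"]] <= 0.0] = 0.0
            return r.ravel()

        sol = solve_ivp(rhs, (0.0, t_end), s.fields.ravel(), method="LSODA",
                        rtol=1e-11, atol=1e-12)
        ref = sol.y[:, -1].reshape(len(FIELDS), grid.n_cells)
        assert np.max(np.abs(got - ref)) < 1e-8


class TestRun:
    def test_zero_horizon_returns_initial_state_only(self, params, grid):
        s = State.zeros(grid.n_cells)
        s["n"] = 0.5
        traj = run(s, params, grid, 0.0)
        assert traj.times == [0.0]
        assert np.array_equal(traj.final().fields, s.fields)

    def test_deterministic_bit_identical(self, params, grid):
        s = State.zeros(grid.n_cells)
        s["n"] = grid.upper_mask()
        s["N1"] = grid.lower_mask()
        s["rho"] = grid.ecm_mask()
        a = run(s, params, grid, 0.5)
        b = run(s, params, grid, 0.5)
        assert np.array_equal(a.final().fields, b.final().fields)
        assert a.stats == b.stats

    def test_output_schedule_does_not_perturb_shared_states(self, params, grid):
        s = State.zeros(grid.n_cells)
        s["n"] = grid.upper_mask()
        s["rho"] = grid.ecm_mask()
        cfg = SolverConfig(dt_init=1e-3, dt_max=1e-3)  # step-aligned schedules
        coarse = run(s, params, grid, 0.02, cfg=cfg,
                     output_times=np.array([0.01, 0.02]))
        fine = run(s, params, grid, 0.02, cfg=cfg,
                   output_times=np.array([0.005, 0.01, 0.015, 0.02]))
        assert np.array_equal(coarse.states[1].fields, fine.states[2].fields)
        # identical up to float-time roundoff in the step accumulator
        assert np.allclose(coarse.final().fields, fine.final().fields,
                           rtol=1e-12, atol=1e-13)

    def test_snapshot_times_strictly_increase(self, params, grid):
        s = State.zeros(grid.n_cells)
        traj = run(s, params, grid, 0.03, output_times=np.array([0.01, 0.02, 0.03]))
        assert np.all(np.diff(traj.times) > 0)
        assert traj.times[0] == 0.0 and traj.times[-1] == pytest.approx(0.03)

    def test_output_beyond_horizon_rejected(self, params, grid):
        with pytest.raises(ConfigurationError):
            run(State.zeros(grid.n_cells), params, grid, 1.0,
                output_times=np.array([2.0]))


class TestSelfConvergence:
    def test_observed_spatial_order_at_least_one(self, params):
        """Successive grid halvings on smooth transported profiles
        contract the solution difference at first order or better.

        The manufactured problem keeps all mass away from the membrane
        (whose advection-blocking jump law is a genuinely non-smooth
        model feature) and uses a chemotactic boundary-layer width
        D_n/chi_E wide enough for every grid to resolve (otherwise
        chemotaxis aggregates cells into grid-scale cusps).  The substep
        count scales with the grid so the temporal error is subdominant.
        """
        from tanwell.transport import TransportOperator

        params = params.replace(D_n=5e-4, chi_E=5e-3)

        def solve(h):
            grid = build_grid(Geometry(), h)
            x = grid.cell_centers
            u = np.zeros((len(FIELDS), grid.n_cells))
            u[IDX["n"]] = np.exp(-((x - 0.22) ** 2) / 0.005)
            u[IDX["E"]] = 0.5 * np.exp(-((x - 0.32) ** 2) / 0.01)
            op = TransportOperator(params, grid)
            dt = op.stable_dt(0.2)
            n_steps = round(0.5 / dt)
            dt = 0.5 / n_steps
            for _ in range(n_steps):
                u = op.step(u, dt)
            return u

        def restrict(u):
            return 0.5 * (u[:, ::2] + u[:, 1::2])

        u1, u2, u3 = solve(0.02), solve(0.01), solve(0.005)
        e12 = np.max(np.abs(restrict(u2) - u1))
        e23 = np.max(np.abs(restrict(u3) - u2))
        order = np.log2(e12 / e23)
        assert order >= 0.9

    def test_observed_temporal_order_at_least_one(self, params):
        """Macro-step halving on a kinetics-dominated uniform problem."""
        geo = Geometry(ecm_interval=(0.25, 0.75))
        grid = build_grid(geo, 0.25)
        p = _no_transport(params)
        s = State.zeros(grid.n_cells)
        s["n"], s["N1"], s["G"], s["rho"] = 0.4, 0.8, 0.3, 1.0

        def solve(dt):
            cfg = SolverConfig(dt_init=dt, dt_max=dt)
            return run(s, p, grid, 1.0, cfg=cfg).final().fields

        e12 = np.max(np.abs(solve(0.01) - solve(0.005)))
        e23 = np.max(np.abs(solve(0.005) - solve(0.0025)))
        assert np.log2(e12 / e23) >= 1.0
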