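import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tmad.morphometry import AnatomicalConstants, TrumpetGrid, effective_capacity
from tmad.physiology import ExchangeParams
from tmad.solver import (
    LungState,
    NumericsConfig,
    PhaseStepper,
    SolverError,
    TridiagonalSystem,
    assemble_system,
    solve_tridiagonal,
    source_terms,
    step,
)

ZERO_SOURCES = ExchangeParams(J_aw=0.0, D_aw=0.0, J_A=0.0, D_A=0.0)


def tiny_grid(n=10, dz=0.5, alveolar_nodes=3):
    """Hand-built small trumpet: growing airway area, alveoli at the far end."""
    z = np.arange(n) * dz
    A_aw = 1.0 + 0.5 * z**2
    N_alv = np.zeros(n)
    N_alv[-alveolar_nodes:] = np.arange(1, alveolar_nodes + 1, dtype=float)
    N_alv *= 480e6 / (N_alv.sum() * dz)
    w_alv = N_alv / 480e6
    A_alv = w_alv * 200.0  # 200 ml alveolar capacity
    n_max = N_alv.max()
    w_aw_raw = A_aw * (1 - N_alv / n_max)
    w_aw = w_aw_raw / (w_aw_raw.sum() * dz)
    return TrumpetGrid(
        dz=dz, z=z, A_aw=A_aw, A_alv=A_alv, N_alv=N_alv, w_aw=w_aw,
        w_alv=w_alv, constants=AnatomicalConstants(), N_max_effective=n_max,
    )


class TestTridiagonal:
    def test_identity_returns_rhs(self):
        rhs = np.array([3.0, -1.0, 2.5])
        system = TridiagonalSystem(
            lower=np.zeros(3), diag=np.ones(3), upper=np.zeros(3), rhs=rhs
        )
        assert np.allclose(solve_tridiagonal(system), rhs)

    def test_matches_dense_solver_on_random_system(self):
        rng = np.random.default_rng(42)
        n = 5
        lower = rng.normal(size=n)
        upper = rng.normal(size=n)
        diag = 4.0 + np.abs(rng.normal(size=n))  # diagonally dominant
        rhs = rng.normal(size=n)
        system = TridiagonalSystem(lower=lower, diag=diag, upper=upper, rhs=rhs)
        dense = np.linalg.solve(system.to_dense(), rhs)
        assert np.allclose(solve_tridiagonal(system), dense, rtol=1e-10)

    def test_zero_pivot_rejected(self):
        with pytest.raises(SolverError, match="pivot"):
            TridiagonalSystem(
                lower=np.zeros(3), diag=np.array([1.0, 0.0, 1.0]),
                upper=np.zeros(3), rhs=np.ones(3),
            )

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            TridiagonalSystem(
                lower=np.zeros(2), diag=np.ones(3), upper=np.zeros(3),
                rhs=np.ones(3),
            )


class TestSourceTerms:
    def test_equilibrium_concentration_nulls_alveolar_source(self):
        grid = tiny_grid()
        params = ExchangeParams(J_aw=0.0, D_aw=0.0, J_A=1e6, D_A=500.0)
        C = np.full(grid.n_nodes, params.alveolar_equilibrium)
        s = source_terms(grid, C, params)
        assert np.allclose(s, 0.0, atol=1e-9)

    def test_zero_concentration_gives_maximum_source(self, grid, row_b_params):
        s = source_terms(grid, np.zeros(grid.n_nodes), row_b_params)
        expected = (
            grid.w_aw * row_b_params.J_aw + grid.w_alv * row_b_params.J_A
        )
        assert np.allclose(s, expected)

    def test_total_source_at_zero_equals_total_fluxes(self, grid, row_b_params):
        """Integrating the C=0 source over the trumpet recovers the configured
        total fluxes, because the weights integrate to one."""
        s = source_terms(grid, np.zeros(grid.n_nodes), row_b_params)
        assert s.sum() * grid.dz == pytest.approx(
            row_b_params.J_aw + row_b_params.J_A, rel=1e-12
        )

    def test_effective_capacity_splits(self, grid):
        conducting = int(np.argmax(grid.z > 10.0))
        assert effective_capacity(grid, conducting) == grid.A_aw[conducting]
        assert effective_capacity(grid, grid.n_nodes - 1) > grid.A_aw[-1]


class TestAssembly:
    def test_no_transport_no_sources_is_identity(self):
        grid = tiny_grid()
        state = LungState(0.0, np.linspace(10.0, 50.0, grid.n_nodes))
        params = ExchangeParams(J_aw=0, D_aw=0, J_A=0, D_A=0, D_gas=0.0)
        new = step(grid, params, state, flow=0.0, dt=0.01)
        assert np.allclose(new.C, state.C, rtol=1e-14)

    @pytest.mark.parametrize("flow", [-100.0, 0.0, 100.0])
    def test_uniform_field_invariant_without_sources(self, flow):
        grid = tiny_grid()
        params = ExchangeParams(J_aw=0, D_aw=0, J_A=0, D_A=0, D_gas=0.21)
        state = LungState(0.0, np.full(grid.n_nodes, 1234.5))
        new = step(grid, params, state, flow=flow, dt=0.05)
        assert np.allclose(new.C, 1234.5, rtol=1e-12)

    def test_single_node_matches_scalar_backward_euler(self):
        """One-node system against a hand-written scalar implicit update:
        (cap/dt + sink) C1 = cap/dt * C0 + src."""
        dz = 0.5
        grid = TrumpetGrid(
            dz=dz, z=np.array([0.0]), A_aw=np.array([2.0]),
            A_alv=np.array([3.0]), N_alv=np.array([480e6 / dz]),
            w_aw=np.array([1 / dz]), w_alv=np.array([1 / dz]),
            constants=AnatomicalConstants(), N_max_effective=480e6 / dz,
        )
        params = ExchangeParams(J_aw=100.0, D_aw=2.0, J_A=1000.0, D_A=5.0)
        dt = 0.02
        state = LungState(0.0, np.zeros(1))
        new = step(grid, params, state, flow=0.0, dt=dt,
                   numerics=NumericsConfig(dz=dz, dt=dt))
        cap = 5.0
        src = (params.J_aw + params.J_A) / dz
        sink = (params.D_aw + params.D_A) / dz
        expected = src / (cap / dt + sink)
        assert new.C[0] == pytest.approx(expected, rel=1e-12)

    def test_dirichlet_mouth_row(self):
        grid = tiny_grid()
        state = LungState(0.0, np.zeros(grid.n_nodes))
        system = assemble_system(
            grid, ZERO_SOURCES, state, flow=50.0, dt=0.01,
            mouth_dirichlet=130.0,
        )
        assert system.diag[0] == 1.0 and system.upper[0] == 0.0
        assert system.rhs[0] == 130.0

    def test_zero_capacity_rejected(self):
        grid = tiny_grid()
        bad = TrumpetGrid(
            dz=grid.dz, z=grid.z, A_aw=np.zeros_like(grid.A_aw),
            A_alv=np.zeros_like(grid.A_alv), N_alv=grid.N_alv,
            w_aw=grid.w_aw, w_alv=grid.w_alv, constants=grid.constants,
            N_max_effective=grid.N_max_effective,
        )
        with pytest.raises(SolverError, match="capacity"):
            step(bad, ZERO_SOURCES, LungState(0.0, np.zeros(grid.n_nodes)),
                 flow=0.0, dt=0.01)


class TestStepProperties:
    def test_equilibrium_fixed_point(self, grid):
        """A state at the common equilibrium of all reservoirs is unchanged."""
        C_eq = 1500.0
        params = ExchangeParams(
            J_aw=1.6 * C_eq, D_aw=1.6, J_A=7400.0 * C_eq, D_A=7400.0
        )
        state = LungState(0.0, np.full(grid.n_nodes, C_eq))
        new = step(grid, params, state, flow=0.0, dt=0.01)
        assert np.abs(new.C - C_eq).max() < 1e-9

    def test_conservation_with_closed_boundaries(self, grid):
        """Sources off, flow zero, diffusion on: total CO content conserved
        to better than 1e-6 relative over 1,000 steps."""
        rng = np.random.default_rng(7)
        state = LungState(0.0, rng.uniform(50.0, 2500.0, grid.n_nodes))
        stepper = PhaseStepper(grid, ZERO_SOURCES, 0.0, 0.01)
        total0 = float((grid.capacity * state.C).sum())
        for _ in range(1000):
            state = stepper(state)
        total1 = float((grid.capacity * state.C).sum())
        assert abs(total1 / total0 - 1.0) < 1e-6

    @pytest.mark.parametrize("dt", [0.01, 0.1, 1.0])
    def test_unconditional_stability(self, grid, row_b_params, dt):
        """No blow-up at high exhalation flow even for 100x the default dt."""
        state = LungState(0.0, np.zeros(grid.n_nodes))
        stepper = PhaseStepper(grid, row_b_params, -220.0, dt)
        for _ in range(int(round(10.0 / dt))):
            state = stepper(state)
        assert np.all(np.isfinite(state.C))
        assert state.C.max() <= row_b_params.alveolar_equilibrium * 1.001

    def test_long_quiescent_integration_reaches_equilibria(self, grid, row_b_params):
        """With no flow, alveolar-dominated nodes relax to J_A/D_A within 1%
        in 60 s; airway nodes stay strictly below the alveolar level."""
        state = LungState(0.0, np.zeros(grid.n_nodes))
        stepper = PhaseStepper(grid, row_b_params, 0.0, 0.01)
        for _ in range(6000):
            state = stepper(state)
        C_A = row_b_params.alveolar_equilibrium
        alveolar = grid.w_alv > 0.5 * grid.w_alv.max()
        assert np.abs(state.C[alveolar] / C_A - 1.0).max() < 0.01
        airway = grid.A_alv == 0.0
        assert np.all(state.C[airway] < C_A)
        assert np.all(state.C[airway] > 0.0)

    def test_implicit_solution_matches_fine_explicit_oracle(self):
        """10-node instance: the implicit solver agrees with an independently
        assembled explicit integration at dt=1e-5 within 0.5% at t = 1 s
        (implicit dt = 1e-3 so the O(dt) time-discretization error sits well
        below the comparison tolerance)."""
        grid = tiny_grid()
        params = ExchangeParams(J_aw=200.0, D_aw=1.5, J_A=2e5, D_A=100.0)
        dt = 1e-3
        state = LungState(0.0, np.zeros(grid.n_nodes))
        stepper = PhaseStepper(grid, params, 0.0, dt)
        for _ in range(1000):
            state = stepper(state)

        # explicit oracle, assembled from scratch with plain loops
        n = grid.n_nodes
        dz = grid.dz
        cap = grid.A_aw + grid.A_alv
        C = np.zeros(n)
        dte = 1e-5
        for _ in range(100000):
            rate = np.zeros(n)
            for i in range(n):
                if i > 0:
                    a = 0.5 * (grid.A_aw[i] + grid.A_aw[i - 1])
                    rate[i] += params.D_gas * a * (C[i - 1] - C[i]) / dz**2
                if i < n - 1:
                    a = 0.5 * (grid.A_aw[i] + grid.A_aw[i + 1])
                    rate[i] += params.D_gas * a * (C[i + 1] - C[i]) / dz**2
                rate[i] += grid.w_aw[i] * (params.J_aw - params.D_aw * C[i])
                rate[i] += grid.w_alv[i] * (params.J_A - params.D_A * C[i])
            C = C + dte * rate / cap
        assert np.abs(state.C / C - 1.0).max() < 5e-3

    @settings(deadline=None, max_examples=10)
    @given(st.integers(0, 2**31 - 1))
    def test_positivity_preserved(self, seed):
        grid = tiny_grid()
        params = ExchangeParams(J_aw=100.0, D_aw=2.0, J_A=1e5, D_A=80.0)
        rng = np.random.default_rng(seed)
        state = LungState(0.0, rng.uniform(0.0, 3000.0, grid.n_nodes))
        flow = rng.uniform(-200.0, 200.0)
        for _ in range(20):
            state = step(grid, params, state, flow, 0.05)
        assert np.all(state.C >= 0.0)

    def test_nonfinite_state_detected(self):
        grid = tiny_grid()
        state = LungState(0.0, np.full(grid.n_nodes, np.nan))
        with pytest.raises(SolverError):
            step(grid, ZERO_SOURCES, state, 0.0, 0.01)


class TestNumericsConfig:
    def test_invalid_steps_rejected(self):
        with pytest.raises(ValueError):
            NumericsConfig(dt=0.0)
        with pytest.raises(ValueError):
            NumericsConfig(dz=-0.1)
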