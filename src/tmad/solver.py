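"""Implicit finite-difference solver for the trumpet gas-exchange equation.

The axial mass balance solved here is, per unit axial distance,

    [A_aw(z) + A_alv(z)] dC/dt = -Vdot dC/dz
                                 + D_gas d/dz[A_aw(z) dC/dz]
                                 + w_aw(z) (J_aw - D_aw C)
                                 + w_alv(z) (J_A - D_A C)

with C the gas-phase concentration (ppb mole fraction), Vdot the signed
volumetric flow (ml/s, positive toward the distal end during inhalation),
D_gas the molecular diffusivity in air (cm^2/s, airway area only in the
diffusion term), and the source weights w_aw, w_alv (1/cm) normalized so the
total maximum fluxes J (pl/s) and diffusing capacities D (pl s^-1 ppb^-1)
enter without further constants (1 pl/s of gas = 1 ppb cm^3/s).

Discretization: method of lines on the uniform grid; first-order upwind
advection selected by the flow sign; conservative central differencing of the
diffusion term with arithmetic-mean face areas; backward (implicit) Euler in
time with the linear sink terms kept in the implicit matrix.  Each step is a
tridiagonal solve.  The scheme is unconditionally stable and, being an
M-matrix system, positivity preserving.

Zero-gradient boundaries are imposed by ghost-node reflection, which keeps
the full storage and source terms at the boundary nodes and makes the
diffusion flux through the end faces exactly zero.  A Dirichlet condition at
the mouth (inhalation) replaces the first row.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.linalg import solve_banded
from scipy.sparse import csc_matrix, diags
from scipy.sparse.linalg import splu

from .morphometry import TrumpetGrid, effective_capacity
from .physiology import ExchangeParams

__all__ = [
    "LungState",
    "NumericsConfig",
    "TridiagonalSystem",
    "SolverError",
    "effective_capacity",
    "source_terms",
    "assemble_system",
    "solve_tridiagonal",
    "step",
    "PhaseStepper",
]


class SolverError(RuntimeError):
    """Numerical failure inside the transport solver."""


@dataclass(frozen=True)
class NumericsConfig:
    """Numerical settings of the transport solver.

    dz and dt default to 0.1 cm and 0.01 s.  ``nonnegativity_clip`` zeroes
    round-off negatives above ``clip_floor`` (ppb); more negative values
    raise, since the implicit upwind scheme should preserve positivity.
    """

    dz: float = 0.1
    dt: float = 0.01
    axial_diffusion_enabled: bool = True
    nonnegativity_clip: bool = True
    clip_floor: float = -1e-9

    def __post_init__(self) -> None:
        if self.dz <= 0 or self.dt <= 0:
            raise ValueError("dz and dt must be positive")


@dataclass
class LungState:
    """Axial concentration field at one time instant."""

    t: float
    C: np.ndarray

    def copy(self) -> "LungState":
        return LungState(self.t, self.C.copy())


@dataclass
class TridiagonalSystem:
    """Tridiagonal linear system ``M x = rhs``.

    ``lower[i]`` couples row i to i-1 (``lower[0]`` unused), ``upper[i]`` to
    i+1 (``upper[-1]`` unused).
    """

    lower: np.ndarray
    diag: np.ndarray
    upper: np.ndarray
    rhs: np.ndarray

    def __post_init__(self) -> None:
        n = self.diag.size
        if not (self.lower.size == self.upper.size == self.rhs.size == n):
            raise ValueError("inconsistent tridiagonal system dimensions")
        if np.any(self.diag == 0.0):
            raise SolverError("zero pivot on the main diagonal")

    def to_dense(self) -> np.ndarray:
        n = self.diag.size
        return (
            np.diag(self.diag)
            + np.diag(self.lower[1:], -1)
            + np.diag(self.upper[:-1], 1)
        )


def solve_tridiagonal(system: TridiagonalSystem) -> np.ndarray:
    """Solve a tridiagonal system (banded LAPACK solve).

    The assembled transport systems are diagonally dominant; the solution is
    checked against the system to a relative residual of 1e-10.
    """
    if not np.all(np.isfinite(system.rhs)):
        raise SolverError("non-finite right-hand side")
    n = system.diag.size
    ab = np.zeros((3, n))
    ab[0, 1:] = system.upper[:-1]
    ab[1, :] = system.diag
    ab[2, :-1] = system.lower[1:]
    x = solve_banded((1, 1), ab, system.rhs)
    resid = (
        system.diag * x
        + np.concatenate(([0.0], system.lower[1:] * x[:-1]))
        + np.concatenate((system.upper[:-1] * x[1:], [0.0]))
        - system.rhs
    )
    scale = max(np.abs(system.rhs).max(), np.abs(x).max(), 1.0)
    if np.abs(resid).max() > 1e-10 * scale:
        raise SolverError("tridiagonal solve residual exceeds 1e-10")
    return x


def source_terms(
    grid: TrumpetGrid, C: np.ndarray, params: ExchangeParams
) -> np.ndarray:
    """Net per-length volumetric source at each node (ppb cm^2 / s).

    Positive means release into the gas phase; at the local equilibrium
    concentration the corresponding term vanishes.
    """
    C = np.asarray(C, dtype=float)
    return grid.w_aw * (params.J_aw - params.D_aw * C) + grid.w_alv * (
        params.J_A - params.D_A * C
    )


def _operator_coefficients(
    grid: TrumpetGrid,
    params: ExchangeParams,
    flow: float,
    numerics: NumericsConfig,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Coefficients of the spatial operator L and the source split.

    Returns (lower, diag, upper, src_const, sink) such that the semi-discrete
    system is ``cap dC/dt = L C + src_const - sink * C`` with L tridiagonal.
    Zero-gradient (reflected ghost) boundaries at both ends; a Dirichlet mouth
    row is applied later during assembly.
    """
    n = grid.n_nodes
    dz = grid.dz
    lower = np.zeros(n)
    diag = np.zeros(n)
    upper = np.zeros(n)

    # advection, first-order upwind by flow sign; reflected ghost nodes make
    # the inflow-side boundary term vanish
    if flow > 0.0:
        a = flow / dz
        lower[1:] += a
        diag[1:] -= a
    elif flow < 0.0:
        a = -flow / dz
        upper[:-1] += a
        diag[:-1] -= a

    if numerics.axial_diffusion_enabled and params.D_gas > 0.0:
        face = 0.5 * (grid.A_aw[:-1] + grid.A_aw[1:])  # area at i+1/2
        k = params.D_gas / dz**2
        upper[:-1] += k * face
        diag[:-1] -= k * face
        lower[1:] += k * face
        diag[1:] -= k * face

    src_const = grid.w_aw * params.J_aw + grid.w_alv * params.J_A
    sink = grid.w_aw * params.D_aw + grid.w_alv * params.D_A
    return lower, diag, upper, src_const, sink


def assemble_system(
    grid: TrumpetGrid,
    params: ExchangeParams,
    state: LungState,
    flow: float,
    dt: float,
    numerics: NumericsConfig | None = None,
    mouth_dirichlet: float | None = None,
) -> TridiagonalSystem:
    """Assemble the backward-Euler system for one time step.

    ``mouth_dirichlet`` pins the mouth node to a concentration (inhalation);
    ``None`` leaves the zero-gradient reflection condition in place
    (breath-hold and exhalation).  The distal end is always zero-gradient.
    """
    numerics = numerics or NumericsConfig()
    cap = grid.capacity
    if np.any(cap <= 0):
        raise SolverError("zero effective capacity on the grid")
    lower, diag, upper, src_const, sink = _operator_coefficients(
        grid, params, flow, numerics
    )
    m_diag = cap / dt + sink - diag
    m_lower = -lower
    m_upper = -upper
    rhs = cap / dt * state.C + src_const
    if mouth_dirichlet is not None:
        m_diag[0] = 1.0
        m_upper[0] = 0.0
        rhs[0] = mouth_dirichlet
    return TridiagonalSystem(lower=m_lower, diag=m_diag, upper=m_upper, rhs=rhs)


def _finalize(C: np.ndarray, numerics: NumericsConfig) -> np.ndarray:
    low = C.min()
    if not np.isfinite(low):
        raise SolverError("non-finite concentration after implicit solve")
    if numerics.nonnegativity_clip and low < 0.0:
        if low < numerics.clip_floor:
            raise SolverError(
                f"negative concentration {low:.3e} ppb below the clip floor; "
                "this indicates a solver defect"
            )
        np.clip(C, 0.0, None, out=C)
    return C


def step(
    grid: TrumpetGrid,
    params: ExchangeParams,
    state: LungState,
    flow: float,
    dt: float,
    numerics: NumericsConfig | None = None,
    mouth_dirichlet: float | None = None,
) -> LungState:
    """Advance the state by one implicit Euler step (assemble + solve)."""
    numerics = numerics or NumericsConfig()
    system = assemble_system(
        grid, params, state, flow, dt, numerics, mouth_dirichlet
    )
    C = solve_tridiagonal(system)
    return LungState(t=state.t + dt, C=_finalize(C, numerics))


class PhaseStepper:
    """Pre-factorized stepper for a breathing phase with constant flow.

    Within a phase the implicit matrix is constant, so it is assembled and
    LU-factorized once; each step is a sparse triangular solve.  Produces
    results identical to :func:`step` at machine precision.
    """

    def __init__(
        self,
        grid: TrumpetGrid,
        params: ExchangeParams,
        flow: float,
        dt: float,
        numerics: NumericsConfig | None = None,
        mouth_dirichlet: float | None = None,
    ) -> None:
        numerics = numerics or NumericsConfig()
        self.numerics = numerics
        self.dt = dt
        self.mouth_dirichlet = mouth_dirichlet
        cap = grid.capacity
        if np.any(cap <= 0):
            raise SolverError("zero effective capacity on the grid")
        lower, diag, upper, src_const, sink = _operator_coefficients(
            grid, params, flow, numerics
        )
        m_diag = cap / dt + sink - diag
        m_lower = -lower
        m_upper = -upper
        self._cap_over_dt = cap / dt
        self._src = src_const.copy()
        if mouth_dirichlet is not None:
            m_diag[0] = 1.0
            m_upper[0] = 0.0
        matrix = diags(
            [m_lower[1:], m_diag, m_upper[:-1]], offsets=[-1, 0, 1], format="csc"
        )
        self._lu = splu(csc_matrix(matrix))

    def __call__(self, state: LungState) -> LungState:
        rhs = self._cap_over_dt * state.C + self._src
        if self.mouth_dirichlet is not None:
            rhs[0] = self.mouth_dirichlet
        C = self._lu.solve(rhs)
        return LungState(t=state.t + self.dt, C=_finalize(C, self.numerics))


def disable_axial_diffusion(numerics: NumericsConfig) -> NumericsConfig:
    """Copy of the numerics settings with the diffusion term switched off."""
    return replace(numerics, axial_diffusion_enabled=False)
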