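"""Breathing-maneuver engine: drive the solver through a full breath.

A maneuver is one inhalation at constant flow, an optional breath-hold, and
one exhalation at constant flow.  Phase-specific boundary conditions follow
the model description: the mouth node is held at the inhaled ambient
concentration during inhalation and switches to a zero-gradient condition
during breath-hold and exhalation; the distal (alveolar-end) node is
zero-gradient at all times.  The respiratory tract starts CO-free by default,
so a single cycle from zero is the reference simulation; a preconditioning
mode repeats cycles until the end-tidal value settles.

The mouth-node concentration recorded at every time step of the exhalation
forms the expirogram.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .morphometry import TrumpetGrid
from .physiology import ExchangeParams
from .solver import (
    LungState,
    NumericsConfig,
    PhaseStepper,
    disable_axial_diffusion,
    step,
)

__all__ = [
    "BreathManeuver",
    "Expirogram",
    "AxialSnapshot",
    "ManeuverError",
    "run_maneuver",
    "run_no_axial_diffusion",
    "run_species",
]

_FLOW_EPS = 1e-9


class ManeuverError(ValueError):
    """Invalid breathing-maneuver configuration."""


@dataclass(frozen=True)
class BreathManeuver:
    """One breathing cycle.

    Parameters
    ----------
    IFR, EFR : float
        Average inhalation / exhalation flow rates (ml/s), both positive.
    V_in, V_ex : float
        Inhaled / exhaled volumes (ml).
    t_hold : float
        Breath-hold duration between inhalation and exhalation (s).
    C_ambient : float
        Inhaled ambient concentration (ppb).
    flow_trace : pandas.DataFrame, optional
        Measured instantaneous flow (columns ``time_s``, ``flow_ml_s``;
        positive = inhalation).  When given it overrides the constant-flow
        phases; phase boundaries follow the sign of the interpolated flow.
    """

    IFR: float
    EFR: float
    V_in: float
    V_ex: float
    t_hold: float = 0.0
    C_ambient: float = 0.0
    flow_trace: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        for name in ("IFR", "EFR", "V_in", "V_ex"):
            if not np.isfinite(getattr(self, name)) or getattr(self, name) <= 0:
                raise ManeuverError(f"{name} must be strictly positive")
        if self.t_hold < 0:
            raise ManeuverError("t_hold must be non-negative")
        if self.C_ambient < 0:
            raise ManeuverError("C_ambient must be non-negative")
        if self.flow_trace is not None:
            for col in ("time_s", "flow_ml_s"):
                if col not in self.flow_trace.columns:
                    raise ManeuverError(f"flow trace missing column {col!r}")

    @property
    def t_inhale(self) -> float:
        return self.V_in / self.IFR

    @property
    def t_exhale(self) -> float:
        return self.V_ex / self.EFR


@dataclass
class Expirogram:
    """Mouth concentration versus time / exhaled volume for one exhalation."""

    time_s: np.ndarray
    volume_ml: np.ndarray
    co_ppb: np.ndarray
    flow_ml_s: np.ndarray | None = None
    maneuver: BreathManeuver | None = None
    params: ExchangeParams | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.volume_ml = np.asarray(self.volume_ml, dtype=float)
        self.co_ppb = np.asarray(self.co_ppb, dtype=float)
        if not (self.time_s.size == self.volume_ml.size == self.co_ppb.size):
            raise ManeuverError("expirogram arrays must have equal length")
        if self.time_s.size and np.any(np.diff(self.time_s) <= 0):
            raise ManeuverError("expirogram times must be strictly increasing")
        if self.time_s.size and np.any(np.diff(self.volume_ml) <= 0):
            raise ManeuverError("expirogram volumes must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return self.time_s.size

    @property
    def final_volume(self) -> float:
        return float(self.volume_ml[-1])

    def to_dataframe(self) -> pd.DataFrame:
        data = {
            "time_s": self.time_s,
            "volume_ml": self.volume_ml,
            "co_ppb": self.co_ppb,
        }
        if self.flow_ml_s is not None:
            data["flow_ml_s"] = self.flow_ml_s
        if "et_co2_pct" in self.metadata:
            data["co2_pct"] = np.full(self.n_samples, self.metadata["et_co2_pct"])
        return pd.DataFrame(data)


@dataclass
class AxialSnapshot:
    """Axial concentration field captured at one instant of the maneuver."""

    label: str
    z_cm: np.ndarray
    co_ppb: np.ndarray
    t: float

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"z_cm": self.z_cm, "co_ppb": self.co_ppb})


def _phase_steps(duration: float, dt: float, what: str) -> int:
    n = int(round(duration / dt))
    if n < 1:
        raise ManeuverError(
            f"{what} duration {duration:.4g} s is shorter than the time step {dt} s"
        )
    return n


def _collect_snapshots(
    collected: list[AxialSnapshot],
    requested: list[float],
    grid: TrumpetGrid,
    state: LungState,
    label: str,
    dt: float,
) -> None:
    while requested and requested[0] <= state.t + dt / 2:
        t_req = requested.pop(0)
        collected.append(
            AxialSnapshot(
                label=f"{label} t={t_req:.2f}s",
                z_cm=grid.z.copy(),
                co_ppb=state.C.copy(),
                t=state.t,
            )
        )


def _run_single_cycle(
    grid: TrumpetGrid,
    params: ExchangeParams,
    maneuver: BreathManeuver,
    numerics: NumericsConfig,
    snapshot_times: Sequence[float] | None,
    initial_state: LungState | None,
) -> tuple[Expirogram, list[AxialSnapshot], LungState]:
    dt = numerics.dt
    state = (
        initial_state.copy()
        if initial_state is not None
        else LungState(t=0.0, C=np.zeros(grid.n_nodes))
    )
    state.t = 0.0
    requested = sorted(snapshot_times) if snapshot_times else []
    snapshots: list[AxialSnapshot] = []

    if maneuver.flow_trace is not None:
        return _run_flow_trace(
            grid, params, maneuver, numerics, requested, snapshots, state
        )

    # inhalation: Dirichlet mouth at ambient, flow mouth -> distal
    n_in = _phase_steps(maneuver.t_inhale, dt, "inhalation")
    inhale = PhaseStepper(
        grid, params, maneuver.IFR, dt, numerics, mouth_dirichlet=maneuver.C_ambient
    )
    for _ in range(n_in):
        state = inhale(state)
        _collect_snapshots(snapshots, requested, grid, state, "inhale", dt)

    # breath-hold: zero flow, zero-gradient mouth
    if maneuver.t_hold > 0:
        n_hold = _phase_steps(maneuver.t_hold, dt, "breath-hold")
        hold = PhaseStepper(grid, params, 0.0, dt, numerics)
        for _ in range(n_hold):
            state = hold(state)
            _collect_snapshots(snapshots, requested, grid, state, "hold", dt)

    # exhalation: flow distal -> mouth, zero-gradient mouth, record expirogram
    n_ex = _phase_steps(maneuver.t_exhale, dt, "exhalation")
    exhale = PhaseStepper(grid, params, -maneuver.EFR, dt, numerics)
    times = np.arange(n_ex + 1) * dt
    conc = np.empty(n_ex + 1)
    conc[0] = state.C[0]
    for i in range(n_ex):
        state = exhale(state)
        conc[i + 1] = state.C[0]
        _collect_snapshots(snapshots, requested, grid, state, "exhale", dt)

    expirogram = Expirogram(
        time_s=times,
        volume_ml=times * maneuver.EFR,
        co_ppb=conc,
        flow_ml_s=np.full(n_ex + 1, maneuver.EFR),
        maneuver=maneuver,
        params=params,
        metadata={"axial_diffusion": numerics.axial_diffusion_enabled},
    )
    return expirogram, snapshots, state


def _run_flow_trace(
    grid: TrumpetGrid,
    params: ExchangeParams,
    maneuver: BreathManeuver,
    numerics: NumericsConfig,
    requested: list[float],
    snapshots: list[AxialSnapshot],
    state: LungState,
) -> tuple[Expirogram, list[AxialSnapshot], LungState]:
    """Variable-flow path: piecewise-linear measured flow, fresh assembly
    every step (the matrix changes with the flow)."""
    dt = numerics.dt
    trace_t = maneuver.flow_trace["time_s"].to_numpy(float)
    trace_q = maneuver.flow_trace["flow_ml_s"].to_numpy(float)
    t_end = trace_t[-1]
    n_steps = _phase_steps(t_end, dt, "flow trace")
    ex_t: list[float] = []
    ex_v: list[float] = []
    ex_c: list[float] = []
    ex_q: list[float] = []
    exhaled = 0.0
    t_ex_start = None
    for i in range(n_steps):
        t_next = (i + 1) * dt
        flow = float(np.interp(t_next, trace_t, trace_q))
        if flow > _FLOW_EPS:
            phase, dirichlet = "inhale", maneuver.C_ambient
        elif flow < -_FLOW_EPS:
            phase, dirichlet = "exhale", None
        else:
            phase, dirichlet = "hold", None
        state = step(grid, params, state, flow, dt, numerics, dirichlet)
        if phase == "exhale":
            if t_ex_start is None:
                t_ex_start = state.t - dt
            exhaled += -flow * dt
            ex_t.append(state.t - t_ex_start)
            ex_v.append(exhaled)
            ex_c.append(float(state.C[0]))
            ex_q.append(-flow)
        _collect_snapshots(snapshots, requested, grid, state, phase, dt)
    if not ex_t:
        raise ManeuverError("flow trace contains no exhalation (negative flow)")
    expirogram = Expirogram(
        time_s=np.array(ex_t),
        volume_ml=np.array(ex_v),
        co_ppb=np.array(ex_c),
        flow_ml_s=np.array(ex_q),
        maneuver=maneuver,
        params=params,
        metadata={
            "axial_diffusion": numerics.axial_diffusion_enabled,
            "flow_trace": True,
        },
    )
    return expirogram, snapshots, state


def run_maneuver(
    grid: TrumpetGrid,
    params: ExchangeParams,
    maneuver: BreathManeuver,
    numerics: NumericsConfig | None = None,
    snapshot_times: Sequence[float] | None = None,
    initial_state: LungState | None = None,
    precondition: bool | int = False,
) -> tuple[Expirogram, list[AxialSnapshot]]:
    """Run one complete breathing maneuver and record the expirogram.

    The simulation starts from a CO-free respiratory tract (or
    ``initial_state``).  With ``precondition`` truthy, whole cycles are
    repeated (up to ``int(precondition)`` or 10) until the end-tidal mouth
    concentration changes by less than 0.5% between cycles, and the last
    cycle is returned.
    """
    numerics = numerics or NumericsConfig()
    expirogram, snapshots, state = _run_single_cycle(
        grid, params, maneuver, numerics, snapshot_times, initial_state
    )
    if precondition:
        max_cycles = precondition if isinstance(precondition, int) and precondition > 1 else 10
        previous = float(expirogram.co_ppb[-1])
        for cycle in range(max_cycles - 1):
            expirogram, snapshots, state = _run_single_cycle(
                grid, params, maneuver, numerics, snapshot_times, state
            )
            current = float(expirogram.co_ppb[-1])
            if previous > 0 and abs(current - previous) / previous < 5e-3:
                break
            previous = current
    return expirogram, snapshots


def run_no_axial_diffusion(
    grid: TrumpetGrid,
    params: ExchangeParams,
    maneuver: BreathManeuver,
    numerics: NumericsConfig | None = None,
    snapshot_times: Sequence[float] | None = None,
    initial_state: LungState | None = None,
    precondition: bool | int = False,
) -> tuple[Expirogram, list[AxialSnapshot]]:
    """Identical maneuver with the gas-phase axial diffusion term disabled."""
    numerics = disable_axial_diffusion(numerics or NumericsConfig())
    return run_maneuver(
        grid, params, maneuver, numerics, snapshot_times, initial_state, precondition
    )


def run_species(
    grid: TrumpetGrid,
    species_params: ExchangeParams,
    maneuver: BreathManeuver,
    numerics: NumericsConfig | None = None,
    **kwargs,
) -> tuple[Expirogram, list[AxialSnapshot]]:
    """Run the maneuver for any species; the exchange parameters carry the
    species identity (fluxes, diffusing capacities, gas-phase diffusivity)."""
    return run_maneuver(grid, species_params, maneuver, numerics, **kwargs)
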