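"""Expirogram post-processing: phases, end-tidal values, flow-rate sweeps.

An expirogram divides into three phases: phase I is pure dead-space
(conducting-airway) gas, phase II the airway-alveolar transition, and phase
III the alveolar plateau.  The end-tidal concentration — the value usually
quoted by breath analyzers — is operationalized here as the mean over the
final 5% of exhaled volume.  The elimination rate is end-tidal concentration
times exhalation flow rate; with concentrations in ppb and flows in ml/s the
product is numerically the output in pl/s.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .maneuver import BreathManeuver, Expirogram, run_maneuver
from .morphometry import TrumpetGrid, conducting_airway_volume
from .physiology import ExchangeParams
from .solver import NumericsConfig

__all__ = [
    "ExpirogramSummary",
    "AnalysisError",
    "end_tidal",
    "elimination_rate",
    "segment_phases",
    "phase_iii_slope",
    "summarize",
    "flow_sweep",
    "sensitivity_study",
]


class AnalysisError(ValueError):
    """Invalid analysis input."""


@dataclass(frozen=True)
class ExpirogramSummary:
    """Scalar summaries of a single expirogram.

    ``phase_i_end`` / ``phase_ii_end`` are exhaled volumes (ml) bounding the
    phases; ``phase_iii_slope`` is in ppb/ml.  ``alveolar_equilibrium`` and
    ``airway_tissue_equilibrium`` are the J/D ratios of the parameters used.
    """

    end_tidal: float
    elimination_rate: float
    phase_i_end: float
    phase_ii_end: float
    phase_iii_slope: float
    alveolar_equilibrium: float | None = None
    airway_tissue_equilibrium: float | None = None


def end_tidal(expirogram: Expirogram, volume_fraction: float = 0.05) -> float:
    """Mean mouth concentration over the final ``volume_fraction`` of exhaled
    volume (ppb)."""
    if expirogram.n_samples == 0:
        raise AnalysisError("empty expirogram")
    if not 0 < volume_fraction <= 1:
        raise AnalysisError("volume_fraction must be in (0, 1]")
    v_final = expirogram.final_volume
    mask = expirogram.volume_ml >= (1.0 - volume_fraction) * v_final
    return float(expirogram.co_ppb[mask].mean())


def elimination_rate(end_tidal_ppb: float, EFR: float) -> float:
    """Elimination rate (pl/s) = end-tidal concentration x exhalation flow.

    1 ppb x 1 ml/s is 1e-9 cm^3/s of gas, i.e. exactly 1 pl/s, so the product
    needs no conversion factor.
    """
    if end_tidal_ppb < 0 or EFR < 0:
        raise AnalysisError("inputs must be non-negative")
    return end_tidal_ppb * EFR


def segment_phases(
    expirogram: Expirogram,
    grid: TrumpetGrid | None = None,
    dead_space_ml: float | None = None,
    plateau_threshold: float = 0.95,
) -> tuple[float, float]:
    """Locate the phase I/II and II/III boundaries (ml exhaled volume).

    Phase I ends at the anatomic dead-space volume (the conducting-airway
    volume of the geometry).  Phase II ends where the profile first reaches
    ``plateau_threshold`` of the plateau trend, a least-squares line fitted
    over the final third of exhaled volume.

    Raises
    ------
    AnalysisError
        If the exhaled volume does not exceed the dead space (phases II/III
        undefined).
    """
    if dead_space_ml is None:
        constants = grid.constants if grid is not None else None
        dead_space_ml = conducting_airway_volume(constants)
    v = expirogram.volume_ml
    c = expirogram.co_ppb
    if v[-1] <= dead_space_ml:
        raise AnalysisError(
            f"exhaled volume {v[-1]:.0f} ml does not exceed the dead space "
            f"{dead_space_ml:.0f} ml; phases II/III undefined"
        )
    slope, intercept = _plateau_trend(expirogram)
    trend = slope * v + intercept
    beyond = v > dead_space_ml
    reached = beyond & (c >= plateau_threshold * trend)
    if np.any(reached):
        phase_ii_end = float(v[np.argmax(reached)])
    else:  # profile never reaches the plateau trend; put the boundary at the end
        phase_ii_end = float(v[-1])
    return float(dead_space_ml), phase_ii_end


def _plateau_trend(expirogram: Expirogram) -> tuple[float, float]:
    """Least-squares line over the final third of exhaled volume."""
    v = expirogram.volume_ml
    c = expirogram.co_ppb
    mask = v >= (2.0 / 3.0) * v[-1]
    if mask.sum() < 2:
        raise AnalysisError("too few samples in the final third for a trend line")
    slope, intercept = np.polyfit(v[mask], c[mask], 1)
    return float(slope), float(intercept)


def phase_iii_slope(expirogram: Expirogram) -> float:
    """Slope of the alveolar plateau (ppb/ml), least squares over the final
    third of exhaled volume."""
    return _plateau_trend(expirogram)[0]


def summarize(
    expirogram: Expirogram,
    grid: TrumpetGrid | None = None,
    params: ExchangeParams | None = None,
    volume_fraction: float = 0.05,
) -> ExpirogramSummary:
    """Compute all scalar summaries for one expirogram."""
    params = params or expirogram.params
    et = end_tidal(expirogram, volume_fraction)
    efr = (
        expirogram.maneuver.EFR
        if expirogram.maneuver is not None
        else float(np.mean(expirogram.flow_ml_s))
        if expirogram.flow_ml_s is not None
        else np.nan
    )
    p1, p2 = segment_phases(expirogram, grid)
    return ExpirogramSummary(
        end_tidal=et,
        elimination_rate=elimination_rate(et, efr),
        phase_i_end=p1,
        phase_ii_end=p2,
        phase_iii_slope=phase_iii_slope(expirogram),
        alveolar_equilibrium=params.alveolar_equilibrium if params else None,
        airway_tissue_equilibrium=(
            params.airway_tissue_equilibrium if params else None
        ),
    )


def flow_sweep(
    grid: TrumpetGrid,
    params: ExchangeParams,
    EFR_values: Sequence[float],
    IFR: float = 127.0,
    V_in: float = 1400.0,
    V_ex: float = 1400.0,
    C_ambient: float = 130.0,
    t_hold: float = 0.0,
    numerics: NumericsConfig | None = None,
) -> pd.DataFrame:
    """End-tidal concentration and elimination rate versus exhalation flow.

    Runs one maneuver per EFR value with the inhalation flow and volumes held
    fixed.  Returns a DataFrame with columns ``efr_ml_s``, ``end_tidal_ppb``,
    ``elimination_rate_pl_s``, ``alveolar_equilibrium_ppb``.
    """
    if np.any(np.asarray(EFR_values, dtype=float) <= 0):
        raise AnalysisError("EFR values must be positive")
    rows = []
    for efr in EFR_values:
        maneuver = BreathManeuver(
            IFR=IFR, EFR=float(efr), V_in=V_in, V_ex=V_ex,
            t_hold=t_hold, C_ambient=C_ambient,
        )
        expirogram, _ = run_maneuver(grid, params, maneuver, numerics)
        et = end_tidal(expirogram)
        rows.append(
            {
                "efr_ml_s": float(efr),
                "end_tidal_ppb": et,
                "elimination_rate_pl_s": elimination_rate(et, float(efr)),
                "alveolar_equilibrium_ppb": params.alveolar_equilibrium,
            }
        )
    return pd.DataFrame(rows)


def sensitivity_study(
    grid: TrumpetGrid,
    base_params: ExchangeParams,
    perturbations: Mapping[str, Mapping[str, float]],
    maneuver: BreathManeuver,
    numerics: NumericsConfig | None = None,
    early_window_s: float = 0.2,
) -> dict[str, dict]:
    """Simulate a family of expirograms for separate parameter perturbations.

    ``perturbations`` maps a label to per-parameter multipliers, e.g.
    ``{"J_A +5%": {"J_A": 1.05}}``.  For each label the perturbed expirogram
    is returned along with scalar contrasts against the base run: change in
    end-tidal value, in phase III slope, and in the mean of the first
    ``early_window_s`` seconds of exhalation (the breath-hold-sensitive
    airway window).
    """
    base_exp, _ = run_maneuver(grid, base_params, maneuver, numerics)
    base_et = end_tidal(base_exp)
    base_slope = phase_iii_slope(base_exp)
    early = base_exp.time_s <= early_window_s
    base_early = float(base_exp.co_ppb[early].mean())

    results: dict[str, dict] = {
        "base": {
            "expirogram": base_exp,
            "end_tidal": base_et,
            "phase_iii_slope": base_slope,
            "early_mean": base_early,
        }
    }
    for label, multipliers in perturbations.items():
        perturbed = base_params.scaled(**multipliers)
        exp, _ = run_maneuver(grid, perturbed, maneuver, numerics)
        early = exp.time_s <= early_window_s
        results[label] = {
            "expirogram": exp,
            "end_tidal": end_tidal(exp),
            "phase_iii_slope": phase_iii_slope(exp),
            "early_mean": float(exp.co_ppb[early].mean()),
            "delta_end_tidal": end_tidal(exp) - base_et,
            "delta_phase_iii_slope": phase_iii_slope(exp) - base_slope,
            "delta_early_mean": float(exp.co_ppb[early].mean()) - base_early,
        }
    return results
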