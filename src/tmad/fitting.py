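"""Refine exchange parameters against measured (or synthetic) expirograms.

The default is a two-stage procedure: the airway parameters are fitted to
the earliest samples of a breath-hold exhalation (only the first ~0.2 s of
exhaled gas resided exclusively in the conducting airways, and breath-holding
is what makes that window sensitive to the airway flux), and the alveolar
parameters are then refined against the phase III plateau (its level and
slope).  A general bounded least-squares mode over any subset of the four
parameters, jointly across several maneuvers, is also provided.

All searches use bounded trust-region least squares on parameters normalized
by their starting values, with optional seeded multi-start.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares

from .maneuver import BreathManeuver, Expirogram, run_maneuver
from .morphometry import TrumpetGrid
from .physiology import ExchangeParams
from .solver import NumericsConfig

__all__ = ["FitResult", "FittingError", "fit_airway", "fit_alveolar",
           "least_squares_refine", "DEFAULT_BOUNDS"]

#: Default box bounds for the airway parameters (physiological plausibility).
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "J_aw": (0.0, 5000.0),
    "D_aw": (0.1, 20.0),
}

PARAM_NAMES = ("J_aw", "D_aw", "J_A", "D_A")


class FittingError(ValueError):
    """Invalid fitting configuration or data."""


@dataclass
class FitResult:
    """Outcome of a parameter fit.

    ``stage_residuals`` maps a stage label to the RMS misfit (ppb) over that
    stage's window.  ``diagnostics`` records convergence information and,
    for joint fits, an identifiability assessment.
    """

    params: ExchangeParams
    stage_residuals: dict = field(default_factory=dict)
    n_iterations: int = 0
    objective: float = np.nan
    windows: dict = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for label, value in self.stage_residuals.items():
            if value < 0:
                raise FittingError(f"negative residual for stage {label!r}")


def _simulate_at(
    times: np.ndarray,
    grid: TrumpetGrid,
    params: ExchangeParams,
    maneuver: BreathManeuver,
    numerics: NumericsConfig,
) -> np.ndarray:
    """Simulated mouth concentration interpolated at the measured times."""
    expirogram, _ = run_maneuver(grid, params, maneuver, numerics)
    return np.interp(times, expirogram.time_s, expirogram.co_ppb)


def _rms(residual: np.ndarray) -> float:
    return float(np.sqrt(np.mean(residual * residual)))


def _bounded_fit(residual_fn, x0, box, max_nfev=200):
    """Least-squares solve in start-normalized units."""
    scale = np.where(x0 > 0, x0, np.array([hi for _, hi in box]))
    lo = np.array([b[0] for b in box]) / scale
    hi = np.array([b[1] for b in box]) / scale
    u0 = np.clip(x0 / scale, lo, hi)
    result = least_squares(
        lambda u: residual_fn(u * scale),
        u0, bounds=(lo, hi), method="trf",
        diff_step=1e-3, xtol=1e-8, ftol=1e-8, gtol=None, max_nfev=max_nfev,
    )
    result.x = result.x * scale
    return result


def fit_airway(
    measured: Expirogram,
    grid: TrumpetGrid,
    maneuver: BreathManeuver,
    params: ExchangeParams,
    window: float = 0.2,
    fit_D_aw: bool = False,
    numerics: NumericsConfig | None = None,
    bounds: dict[str, tuple[float, float]] | None = None,
) -> FitResult:
    """Stage 1: airway parameters from the earliest breath-hold samples.

    Minimizes the RMS misfit over the first ``window`` seconds of exhalation,
    varying ``J_aw`` (and optionally ``D_aw``).  Refuses to run without a
    breath-hold, where the early window carries almost no airway information.
    """
    numerics = numerics or NumericsConfig()
    if maneuver.t_hold <= 0:
        raise FittingError(
            "airway fitting requires a breath-hold maneuver (t_hold > 0): "
            "without it the early-exhalation window is insensitive to the "
            "airway parameters"
        )
    mask = measured.time_s <= window
    if not np.any(mask):
        raise FittingError(f"no samples within the first {window} s of exhalation")
    times = measured.time_s[mask]
    target = measured.co_ppb[mask]
    bounds = {**DEFAULT_BOUNDS, **(bounds or {})}
    names = ["J_aw", "D_aw"] if fit_D_aw else ["J_aw"]
    box = [bounds[n] for n in names]
    x0 = np.array([getattr(params, n) for n in names])

    def residual(x: np.ndarray) -> np.ndarray:
        candidate = replace(params, **dict(zip(names, x)))
        return _simulate_at(times, grid, candidate, maneuver, numerics) - target

    result = _bounded_fit(residual, x0, box)
    fitted = replace(params, **dict(zip(names, result.x)))
    rms = _rms(result.fun)
    return FitResult(
        params=fitted,
        stage_residuals={"airway": rms},
        n_iterations=int(result.nfev),
        objective=rms,
        windows={"airway_window_s": window, "n_samples": int(mask.sum())},
        diagnostics={"success": bool(result.success), "free": names},
    )


def fit_alveolar(
    measured: Expirogram,
    grid: TrumpetGrid,
    maneuver: BreathManeuver,
    params: ExchangeParams,
    rel_bounds: float = 0.5,
    numerics: NumericsConfig | None = None,
    max_evaluations: int = 200,
) -> FitResult:
    """Stage 2: alveolar parameters from the phase III plateau.

    Minimizes the RMS misfit over the final third of exhaled volume (which
    captures both the plateau level and its slope), varying ``J_A`` and
    ``D_A`` within ``rel_bounds`` (default +-50%) of their starting values.
    """
    numerics = numerics or NumericsConfig()
    v = measured.volume_ml
    mask = v >= (2.0 / 3.0) * v[-1]
    if mask.sum() < 3:
        raise FittingError("expirogram has no usable phase III (too few samples)")
    times = measured.time_s[mask]
    target = measured.co_ppb[mask]
    names = ["J_A", "D_A"]
    x0 = np.array([params.J_A, params.D_A])
    box = [(x * (1 - rel_bounds), x * (1 + rel_bounds)) for x in x0]

    def residual(x: np.ndarray) -> np.ndarray:
        candidate = replace(params, **dict(zip(names, x)))
        return _simulate_at(times, grid, candidate, maneuver, numerics) - target

    result = _bounded_fit(residual, x0, box, max_nfev=max_evaluations)
    if not result.success and result.nfev >= max_evaluations:
        raise FittingError(
            f"alveolar fit did not converge within {max_evaluations} "
            f"evaluations; best RMS {_rms(result.fun):.3g} ppb at {result.x}"
        )
    fitted = replace(params, **dict(zip(names, result.x)))
    rms = _rms(result.fun)
    return FitResult(
        params=fitted,
        stage_residuals={"alveolar": rms},
        n_iterations=int(result.nfev),
        objective=rms,
        windows={"phase_iii_volume_fraction": 1.0 / 3.0, "n_samples": int(mask.sum())},
        diagnostics={"success": bool(result.success), "free": names},
    )


def least_squares_refine(
    measured: Expirogram | list[Expirogram],
    maneuvers: BreathManeuver | list[BreathManeuver],
    grid: TrumpetGrid,
    params: ExchangeParams,
    free: tuple[str, ...] = ("J_A", "D_A"),
    rel_bounds: float = 0.5,
    numerics: NumericsConfig | None = None,
    n_starts: int = 1,
    seed: int | None = None,
    volume_weighted: bool = False,
) -> FitResult:
    """Joint bounded least squares over selected parameters and maneuvers.

    The residual pools all samples of all expirograms, uniformly weighted in
    time (exhaled-volume weighted if requested).  ``n_starts > 1`` adds
    seeded random restarts within the bounds; the best solution wins.
    Identifiability diagnostics (normalized sensitivity condition number) are
    reported, and a warning is recorded when airway parameters are fitted
    without any breath-hold data.
    """
    numerics = numerics or NumericsConfig()
    expirograms = measured if isinstance(measured, list) else [measured]
    mans = maneuvers if isinstance(maneuvers, list) else [maneuvers]
    if len(expirograms) != len(mans) or not expirograms:
        raise FittingError("need one maneuver per expirogram (and at least one)")
    unknown = set(free) - set(PARAM_NAMES)
    if unknown:
        raise FittingError(f"unknown parameters in mask: {sorted(unknown)}")
    weights = []
    for exp in expirograms:
        if volume_weighted:
            v = exp.volume_ml
            dv = np.diff(v, prepend=v[0])
            if dv.size > 1:
                dv[0] = dv[1]
            weights.append(np.sqrt(dv / dv.mean()))
        else:
            weights.append(np.ones(exp.n_samples))

    def residual(x: np.ndarray) -> np.ndarray:
        candidate = replace(params, **dict(zip(free, x)))
        parts = []
        for exp, man, w in zip(expirograms, mans, weights):
            sim = _simulate_at(exp.time_s, grid, candidate, man, numerics)
            parts.append(w * (sim - exp.co_ppb))
        return np.concatenate(parts)

    if not free:
        rms = _rms(residual(np.array([])))
        return FitResult(
            params=params, stage_residuals={}, n_iterations=0, objective=rms,
            diagnostics={"note": "empty parameter mask; nothing fitted"},
        )

    x0 = np.array([getattr(params, n) for n in free])
    box = []
    for name, x in zip(free, x0):
        if name in DEFAULT_BOUNDS:
            box.append(DEFAULT_BOUNDS[name])
        else:
            box.append((x * (1 - rel_bounds), x * (1 + rel_bounds)))

    starts = [x0]
    if n_starts > 1:
        rng = np.random.default_rng(seed)
        for _ in range(n_starts - 1):
            starts.append(np.array([rng.uniform(lo, hi) for lo, hi in box]))
    best = None
    total_nfev = 0
    for start in starts:
        result = _bounded_fit(residual, start, box)
        total_nfev += int(result.nfev)
        if best is None or _rms(result.fun) < _rms(best.fun):
            best = result
    fitted = replace(params, **dict(zip(free, best.x)))
    rms = _rms(best.fun)

    diagnostics: dict = {"success": bool(best.success), "free": list(free),
                         "n_starts": len(starts)}
    cond = _sensitivity_condition(fitted, free, expirograms, mans, grid, numerics)
    diagnostics["sensitivity_condition_number"] = cond
    airway_free = {"J_aw", "D_aw"} & set(free)
    if airway_free and all(m.t_hold <= 0 for m in mans):
        diagnostics["warning"] = (
            "airway parameters fitted without breath-hold data: weak "
            "identifiability expected"
        )
    elif cond > 1e4:
        diagnostics["warning"] = (
            "ill-conditioned sensitivity matrix: parameter combination "
            "weakly identified by these data"
        )
    return FitResult(
        params=fitted,
        stage_residuals={"joint": rms},
        n_iterations=total_nfev,
        objective=rms,
        windows={"n_expirograms": len(expirograms)},
        diagnostics=diagnostics,
    )


def _sensitivity_condition(
    params: ExchangeParams,
    free: tuple[str, ...],
    expirograms: list[Expirogram],
    mans: list[BreathManeuver],
    grid: TrumpetGrid,
    numerics: NumericsConfig,
    rel_step: float = 1e-3,
) -> float:
    """Condition number of the normalized finite-difference sensitivity
    matrix d(sim)/d(log param), stacked over all samples of all traces."""
    columns = []
    for name in free:
        x = getattr(params, name)
        h = max(abs(x) * rel_step, 1e-12)
        plus = replace(params, **{name: x + h})
        minus = replace(params, **{name: max(x - h, 0.0)})
        col = []
        for exp, man in zip(expirograms, mans):
            sp = _simulate_at(exp.time_s, grid, plus, man, numerics)
            sm = _simulate_at(exp.time_s, grid, minus, man, numerics)
            col.append((sp - sm) / (2 * h) * max(abs(x), 1e-12))
        columns.append(np.concatenate(col))
    J = np.column_stack(columns)
    s = np.linalg.svd(J, compute_uv=False)
    if s[-1] <= 0:
        return np.inf
    return float(s[0] / s[-1])
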