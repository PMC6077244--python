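"""Model/Results interface over the trumpet gas-exchange machinery.

:class:`TMADModel` bundles a geometry, a breathing maneuver and starting
exchange parameters with (optionally) measured expirogram data;
``fit()`` refines the exchange parameters against the data and returns a
:class:`TMADResults` with the estimates, residuals, diagnostics and a
``summary()`` table.  ``simulate()`` produces model expirograms without data.

Example
-------
>>> model = TMADModel(maneuver=BreathManeuver(IFR=121, EFR=121, V_in=726,
...                                           V_ex=726, C_ambient=130))
>>> expirogram = model.simulate()          # healthy-population defaults
>>> fitted = TMADModel(data=expirogram, maneuver=model.maneuver).fit()
>>> print(fitted.summary())                # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import analysis, fitting
from .maneuver import BreathManeuver, Expirogram, run_maneuver
from .morphometry import AnatomicalConstants, GenerationTable, TrumpetGrid, build_grid
from .physiology import (
    ExchangeParams,
    TissueBloodParams,
    estimate_exchange_params,
)
from .solver import NumericsConfig

__all__ = ["TMADModel", "TMADResults"]


class TMADModel:
    """Trumpet model with axial diffusion, bound to data and a maneuver.

    Parameters
    ----------
    data : Expirogram or list of Expirogram, optional
        Measured (or synthetic) expirograms to fit against.
    maneuver : BreathManeuver or list, optional
        The breathing maneuver(s) behind the data (one per expirogram).
        Defaults to the maneuver attached to each expirogram.
    start_params : ExchangeParams, optional
        Starting exchange parameters; defaults to the healthy-population
        morphometric/Haldane estimate from ``tissue_blood``.
    tissue_blood : TissueBloodParams, optional
        Tissue/blood properties for the default parameter estimate.
    constants, generation_table, dz
        Geometry configuration; the grid is built once and reused.
    """

    def __init__(
        self,
        data: Expirogram | list[Expirogram] | None = None,
        maneuver: BreathManeuver | list[BreathManeuver] | None = None,
        start_params: ExchangeParams | None = None,
        tissue_blood: TissueBloodParams | None = None,
        constants: AnatomicalConstants | None = None,
        generation_table: GenerationTable | None = None,
        numerics: NumericsConfig | None = None,
        dz: float | None = None,
    ) -> None:
        self.numerics = numerics or NumericsConfig()
        if dz is not None:
            self.numerics = NumericsConfig(
                dz=dz, dt=self.numerics.dt,
                axial_diffusion_enabled=self.numerics.axial_diffusion_enabled,
            )
        self.constants = constants or AnatomicalConstants()
        self.grid: TrumpetGrid = build_grid(
            self.constants, generation_table, self.numerics.dz
        )
        self.tissue_blood = tissue_blood or TissueBloodParams()
        self.start_params = start_params or estimate_exchange_params(self.tissue_blood)
        self.data = data if isinstance(data, list) or data is None else [data]
        if maneuver is None and self.data is not None:
            maneuver = [d.maneuver for d in self.data]
            if any(m is None for m in maneuver):
                raise ValueError(
                    "expirograms carry no maneuver metadata; pass maneuver="
                )
        self.maneuvers = (
            maneuver if isinstance(maneuver, list) or maneuver is None else [maneuver]
        )

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        maneuver: BreathManeuver,
        **kwargs,
    ) -> "TMADModel":
        """Build from a measured trace with columns ``time_s``, ``co_ppb``
        and optionally ``flow_ml_s`` / ``volume_ml``."""
        t = df["time_s"].to_numpy(float)
        if "volume_ml" in df.columns:
            v = df["volume_ml"].to_numpy(float)
        else:
            v = t * maneuver.EFR
        expirogram = Expirogram(
            time_s=t,
            volume_ml=v,
            co_ppb=df["co_ppb"].to_numpy(float),
            flow_ml_s=df["flow_ml_s"].to_numpy(float)
            if "flow_ml_s" in df.columns else None,
            maneuver=maneuver,
        )
        return cls(data=expirogram, maneuver=maneuver, **kwargs)

    @property
    def maneuver(self) -> BreathManeuver | None:
        return self.maneuvers[0] if self.maneuvers else None

    def simulate(
        self,
        params: ExchangeParams | None = None,
        maneuver: BreathManeuver | None = None,
        snapshot_times=None,
        **kwargs,
    ):
        """Run the forward model; returns the expirogram (and snapshots if
        ``snapshot_times`` is given)."""
        maneuver = maneuver or self.maneuver
        if maneuver is None:
            raise ValueError("no maneuver configured")
        expirogram, snapshots = run_maneuver(
            self.grid, params or self.start_params, maneuver, self.numerics,
            snapshot_times=snapshot_times, **kwargs,
        )
        return (expirogram, snapshots) if snapshot_times else expirogram

    def fit(
        self,
        method: str = "two_stage",
        free: tuple[str, ...] = ("J_A", "D_A"),
        airway_window_s: float = 0.2,
        fit_D_aw: bool = False,
        seed: int | None = None,
        n_starts: int = 1,
    ) -> "TMADResults":
        """Fit the exchange parameters to the bound expirogram data.

        ``method="two_stage"`` follows the reference procedure: airway flux
        from the earliest breath-hold samples (skipped, with a diagnostic,
        when no breath-hold expirogram is available), then alveolar
        parameters from phase III.  A provisional alveolar fit precedes the
        airway stage, because breath-hold enrichment of the early window is
        dominated by alveolar CO and a poor alveolar baseline would otherwise
        bias the airway flux.  ``method="joint"`` runs the bounded
        least-squares refinement over ``free`` across all expirograms.
        """
        if not self.data:
            raise ValueError("no expirogram data bound to the model")
        if method not in ("two_stage", "joint"):
            raise ValueError(f"unknown fit method {method!r}")
        params = self.start_params
        stage_results: list[fitting.FitResult] = []
        if method == "two_stage":
            hold_idx = [
                i for i, m in enumerate(self.maneuvers) if m.t_hold > 0
            ]
            diagnostics = {}
            if hold_idx:
                i = hold_idx[0]
                provisional = fitting.fit_alveolar(
                    self.data[i], self.grid, self.maneuvers[i], params,
                    numerics=self.numerics,
                )
                params = provisional.params
                stage1 = fitting.fit_airway(
                    self.data[i], self.grid, self.maneuvers[i], params,
                    window=airway_window_s, fit_D_aw=fit_D_aw,
                    numerics=self.numerics,
                )
                params = stage1.params
                stage_results.append(stage1)
            else:
                diagnostics["airway_stage"] = (
                    "skipped: no breath-hold expirogram available"
                )
            stage2 = fitting.fit_alveolar(
                self.data[0], self.grid, self.maneuvers[0], params,
                numerics=self.numerics,
            )
            params = stage2.params
            stage_results.append(stage2)
            result = fitting.FitResult(
                params=params,
                stage_residuals={
                    k: v for r in stage_results for k, v in r.stage_residuals.items()
                },
                n_iterations=sum(r.n_iterations for r in stage_results),
                objective=stage_results[-1].objective,
                windows={
                    k: v for r in stage_results for k, v in r.windows.items()
                },
                diagnostics={
                    **diagnostics,
                    **{k: v for r in stage_results for k, v in r.diagnostics.items()},
                },
            )
        else:
            result = fitting.least_squares_refine(
                self.data, self.maneuvers, self.grid, params,
                free=free, numerics=self.numerics, n_starts=n_starts, seed=seed,
            )
        return TMADResults(model=self, fit_result=result)


@dataclass
class TMADResults:
    """Fit results: estimates, residuals, diagnostics, summary table."""

    model: TMADModel
    fit_result: fitting.FitResult
    _fitted_expirograms: list[Expirogram] | None = field(default=None, repr=False)

    @property
    def params(self) -> ExchangeParams:
        return self.fit_result.params

    @property
    def fitted_expirograms(self) -> list[Expirogram]:
        """Model expirograms at the fitted parameters, one per data trace."""
        if self._fitted_expirograms is None:
            self._fitted_expirograms = [
                run_maneuver(self.model.grid, self.params, m, self.model.numerics)[0]
                for m in self.model.maneuvers
            ]
        return self._fitted_expirograms

    @property
    def resid(self) -> list[np.ndarray]:
        """Per-trace residuals (measured - fitted) at the measured times."""
        out = []
        for data, sim in zip(self.model.data, self.fitted_expirograms):
            out.append(
                data.co_ppb - np.interp(data.time_s, sim.time_s, sim.co_ppb)
            )
        return out

    @property
    def rms_resid(self) -> float:
        r = np.concatenate(self.resid)
        return float(np.sqrt(np.mean(r * r)))

    def summary(self) -> str:
        p = self.params
        start = self.model.start_params
        lines = [
            "Trumpet model with axial diffusion — fit results",
            "=" * 58,
            f"{'parameter':<12}{'estimate':>14}{'start':>14}  unit",
            "-" * 58,
            f"{'J_aw':<12}{p.J_aw:>14.4g}{start.J_aw:>14.4g}  pl/s",
            f"{'D_aw':<12}{p.D_aw:>14.4g}{start.D_aw:>14.4g}  pl.s-1.ppb-1",
            f"{'J_A':<12}{p.J_A:>14.4g}{start.J_A:>14.4g}  pl/s",
            f"{'D_A':<12}{p.D_A:>14.4g}{start.D_A:>14.4g}  pl.s-1.ppb-1",
            "-" * 58,
            f"alveolar equilibrium J_A/D_A   : {p.alveolar_equilibrium:10.1f} ppb",
            f"airway tissue equil. J_aw/D_aw : {p.airway_tissue_equilibrium:10.1f} ppb",
            f"residual RMS                   : {self.rms_resid:10.2f} ppb",
            f"iterations                     : {self.fit_result.n_iterations:6d}",
        ]
        for label, value in self.fit_result.stage_residuals.items():
            lines.append(f"stage {label:<18} RMS     : {value:10.2f} ppb")
        for key, value in self.fit_result.diagnostics.items():
            if key == "sensitivity_condition_number":
                lines.append(f"sensitivity condition number   : {value:10.3g}")
            elif key == "warning":
                lines.append(f"warning: {value}")
        return "\n".join(lines)

    def end_tidal(self, index: int = 0) -> float:
        return analysis.end_tidal(self.fitted_expirograms[index])

    def plot(self, index: int = 0, ax=None):
        """Measured samples and fitted curve versus exhaled volume."""
        from .plotting import plot_fit

        return plot_fit(self, index=index, ax=ax)
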