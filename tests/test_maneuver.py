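import numpy as np
import pandas as pd
import pytest

from tmad.maneuver import (
    BreathManeuver,
    Expirogram,
    ManeuverError,
    run_maneuver,
    run_no_axial_diffusion,
    run_species,
)
from tmad.morphometry import build_grid
from tmad.physiology import ExchangeParams
from tmad.solver import LungState, NumericsConfig

from conftest import end_tidal_mean

ZERO = ExchangeParams(J_aw=0.0, D_aw=0.0, J_A=0.0, D_A=0.0)


class TestBreathManeuver:
    def test_phase_durations(self):
        m = BreathManeuver(IFR=150.0, EFR=100.0, V_in=750.0, V_ex=800.0)
        assert m.t_inhale == pytest.approx(5.0)
        assert m.t_exhale == pytest.approx(8.0)

    @pytest.mark.parametrize("kwargs", [
        {"IFR": 0.0}, {"EFR": -5.0}, {"V_in": 0.0}, {"t_hold": -1.0},
        {"C_ambient": -10.0},
    ])
    def test_invalid_inputs_rejected(self, kwargs):
        base = dict(IFR=100.0, EFR=100.0, V_in=700.0, V_ex=700.0)
        base.update(kwargs)
        with pytest.raises(ManeuverError):
            BreathManeuver(**base)

    def test_expirogram_monotonicity_enforced(self):
        with pytest.raises(ManeuverError, match="increasing"):
            Expirogram(
                time_s=np.array([0.0, 1.0, 0.5]),
                volume_ml=np.array([0.0, 100.0, 200.0]),
                co_ppb=np.zeros(3),
            )


class TestRunManeuver:
    def test_zero_sources_zero_ambient_gives_zero_output(self, grid):
        m = BreathManeuver(IFR=121.0, EFR=121.0, V_in=726.0, V_ex=726.0)
        expirogram, _ = run_maneuver(grid, ZERO, m)
        assert np.allclose(expirogram.co_ppb, 0.0)

    def test_final_volume_matches_requested(self, grid, row_b_params,
                                            row_b_maneuver):
        expirogram, _ = run_maneuver(grid, row_b_params, row_b_maneuver)
        assert expirogram.final_volume == pytest.approx(
            row_b_maneuver.V_ex, abs=row_b_maneuver.EFR * 0.01 + 1e-9
        )

    def test_flat_profile_at_common_equilibrium(self, grid):
        """With ambient equal to both reservoir equilibria the expirogram is
        flat at that value to 0.1%."""
        C_eq = 2000.0
        params = ExchangeParams(
            J_aw=1.6 * C_eq, D_aw=1.6, J_A=7400.0 * C_eq, D_A=7400.0
        )
        m = BreathManeuver(IFR=121.0, EFR=121.0, V_in=726.0, V_ex=726.0,
                           C_ambient=C_eq)
        initial = LungState(0.0, np.full(grid.n_nodes, C_eq))
        expirogram, _ = run_maneuver(grid, params, m, initial_state=initial)
        assert np.abs(expirogram.co_ppb / C_eq - 1.0).max() < 1e-3

    def test_end_tidal_below_alveolar_equilibrium(self, grid, row_b_params):
        for efr in (10.0, 61.0, 204.0):
            m = BreathManeuver(IFR=121.0, EFR=efr, V_in=726.0, V_ex=726.0,
                               C_ambient=130.0)
            expirogram, _ = run_maneuver(grid, row_b_params, m)
            assert end_tidal_mean(expirogram) < row_b_params.alveolar_equilibrium

    def test_breath_hold_raises_early_exhalation(self, grid, row_b_params,
                                                 row_b_maneuver):
        """20 s of breath-holding enriches airway gas from the alveoli, so
        the first 0.2 s of exhaled CO rise steeply (phase I elevation)."""
        hold = BreathManeuver(IFR=121.0, EFR=121.0, V_in=726.0, V_ex=726.0,
                              C_ambient=130.0, t_hold=20.0)
        plain, _ = run_maneuver(grid, row_b_params, row_b_maneuver)
        held, _ = run_maneuver(grid, row_b_params, hold)
        n = 21  # first 0.2 s at dt = 0.01
        assert held.co_ppb[:n].mean() > plain.co_ppb[:n].mean()
        assert np.all(held.co_ppb[:n] >= plain.co_ppb[:n])

    def test_phase_shorter_than_timestep_rejected(self, grid, row_b_params):
        m = BreathManeuver(IFR=121.0, EFR=121.0, V_in=726.0, V_ex=726.0,
                           t_hold=0.001)
        with pytest.raises(ManeuverError, match="shorter than"):
            run_maneuver(grid, row_b_params, m)

    def test_snapshots_recorded_with_phase_labels(self, grid, row_b_params):
        m = BreathManeuver(IFR=121.0, EFR=121.0, V_in=726.0, V_ex=726.0,
                           t_hold=2.0, C_ambient=130.0)
        _, snaps = run_maneuver(grid, row_b_params, m,
                                snapshot_times=[1.0, 6.5, 9.0])
        assert len(snaps) == 3
        assert snaps[0].label.startswith("inhale")
        assert snaps[1].label.startswith("hold")
        assert snaps[2].label.startswith("exhale")
        assert snaps[0].co_ppb.size == grid.n_nodes

    def test_precondition_converges_to_cyclic_state(self, grid, row_b_params,
                                                    row_b_maneuver):
        single, _ = run_maneuver(grid, row_b_params, row_b_maneuver)
        cyclic, _ = run_maneuver(grid, row_b_params, row_b_maneuver,
                                 precondition=True)
        # repeated breathing can only move end-tidal toward the alveolar level
        assert end_tidal_mean(cyclic) >= end_tidal_mean(single) - 1e-9
        assert end_tidal_mean(cyclic) < row_b_params.alveolar_equilibrium


class TestAxialDiffusionVariant:
    def test_differs_in_phase_three(self, grid, row_b_params, row_b_maneuver):
        """Switching off gas-phase axial diffusion changes the alveolar
        plateau; matching data again would need different parameters."""
        with_ad, _ = run_maneuver(grid, row_b_params, row_b_maneuver)
        without, _ = run_no_axial_diffusion(grid, row_b_params, row_b_maneuver)
        tail = with_ad.volume_ml >= 0.8 * with_ad.final_volume
        assert not np.allclose(
            with_ad.co_ppb[tail], without.co_ppb[tail], rtol=5e-3
        )

    def test_zero_sources_still_zero(self, grid):
        m = BreathManeuver(IFR=121.0, EFR=121.0, V_in=726.0, V_ex=726.0)
        expirogram, _ = run_no_axial_diffusion(grid, ZERO, m)
        assert np.allclose(expirogram.co_ppb, 0.0)

    def test_equivalent_to_zero_diffusivity(self, grid, row_b_params,
                                            row_b_maneuver):
        from dataclasses import replace

        without, _ = run_no_axial_diffusion(grid, row_b_params, row_b_maneuver)
        zero_d, _ = run_maneuver(
            grid, replace(row_b_params, D_gas=0.0), row_b_maneuver
        )
        assert np.allclose(without.co_ppb, zero_d.co_ppb, rtol=1e-12)


class TestSpecies:
    def test_nitric_oxide_breath_hold_phase_one_peak(self, grid):
        """After 20 s breath-holding, exhaled NO peaks in phase I (airway
        gas enriched from airway tissue) before falling to the low alveolar
        plateau."""
        no = ExchangeParams.no_healthy()
        m = BreathManeuver(IFR=200.0, EFR=200.0, V_in=1400.0, V_ex=1400.0,
                           t_hold=20.0, C_ambient=0.0)
        expirogram, _ = run_species(grid, no, m)
        dead_space = 130.0  # ml, conducting airways
        phase1 = expirogram.volume_ml <= dead_space
        plateau = end_tidal_mean(expirogram)
        assert expirogram.co_ppb[phase1].max() > 3 * plateau
        assert expirogram.co_ppb.argmax() < phase1.sum()

    def test_nitric_oxide_plateau_below_alveolar_equilibrium(self, grid):
        no = ExchangeParams.no_healthy()
        m = BreathManeuver(IFR=200.0, EFR=200.0, V_in=1400.0, V_ex=1400.0,
                           C_ambient=0.0)
        expirogram, _ = run_species(grid, no, m)
        assert end_tidal_mean(expirogram) < no.alveolar_equilibrium

    def test_co_parameters_identical_to_run_maneuver(self, grid, row_b_params,
                                                     row_b_maneuver):
        a, _ = run_maneuver(grid, row_b_params, row_b_maneuver)
        b, _ = run_species(grid, row_b_params, row_b_maneuver)
        assert np.array_equal(a.co_ppb, b.co_ppb)


class TestNumericalRefinement:
    def test_time_step_refinement(self, grid, row_b_params, row_b_maneuver):
        coarse, _ = run_maneuver(grid, row_b_params, row_b_maneuver,
                                 NumericsConfig(dt=0.01))
        fine, _ = run_maneuver(grid, row_b_params, row_b_maneuver,
                               NumericsConfig(dt=0.005))
        assert abs(
            end_tidal_mean(fine) / end_tidal_mean(coarse) - 1.0
        ) < 0.005

    def test_grid_refinement(self, grid, row_b_params, row_b_maneuver):
        fine_grid = build_grid(dz=0.05)
        coarse, _ = run_maneuver(grid, row_b_params, row_b_maneuver)
        fine, _ = run_maneuver(fine_grid, row_b_params, row_b_maneuver,
                               NumericsConfig(dz=0.05))
        assert abs(
            end_tidal_mean(fine) / end_tidal_mean(coarse) - 1.0
        ) < 0.01


class TestFlowTrace:
    def test_constant_trace_matches_constant_flow_phases(self, grid,
                                                         row_b_params):
        """A measured trace encoding the same square inhale/exhale profile
        reproduces the constant-flow engine closely."""
        m_const = BreathManeuver(IFR=121.0, EFR=121.0, V_in=726.0,
                                 V_ex=726.0, C_ambient=130.0)
        t_in = m_const.t_inhale
        trace = pd.DataFrame({
            "time_s": [0.0, t_in, t_in + 1e-6, 2 * t_in],
            "flow_ml_s": [121.0, 121.0, -121.0, -121.0],
        })
        m_trace = BreathManeuver(IFR=121.0, EFR=121.0, V_in=726.0,
                                 V_ex=726.0, C_ambient=130.0,
                                 flow_trace=trace)
        const, _ = run_maneuver(grid, row_b_params, m_const)
        traced, _ = run_maneuver(grid, row_b_params, m_trace)
        et_const = end_tidal_mean(const)
        et_traced = end_tidal_mean(traced)
        assert et_traced == pytest.approx(et_const, rel=0.01)

    def test_trace_without_exhalation_rejected(self, grid, row_b_params):
        trace = pd.DataFrame({"time_s": [0.0, 2.0], "flow_ml_s": [100.0, 100.0]})
        m = BreathManeuver(IFR=100.0, EFR=100.0, V_in=700.0, V_ex=700.0,
                           flow_trace=trace)
        with pytest.raises(ManeuverError, match="no exhalation"):
            run_maneuver(grid, row_b_params, m)
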