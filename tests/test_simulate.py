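"""Trajectory simulation: integrator accuracy, dosing, comparison models
and the concentration–occupancy hysteresis diagnostics."""

import numpy as np
import pytest

from pktopd.model import MOUSE_PD, MOUSE_PK, MOUSE_TO, pk_closed_form
from pktopd.simulate import (
    AltTOParams,
    DoseRegimen,
    cycle_extrema,
    hysteresis_curve,
    simulate,
    simulate_alt_to,
    simulate_qd,
)
from conftest import rk4_system

GRID_STUDY = np.array([0.0, 2.0, 4.0, 6.0, 8.0, 10.0, 24.0])
DOSES = (0.3, 1.0, 3.0, 10.0)


class TestRegimen:
    def test_rejects_decreasing_times(self):
        with pytest.raises(ValueError, match="increasing"):
            DoseRegimen(1.0, (0.0, 24.0, 24.0))

    def test_rejects_negative_dose(self):
        with pytest.raises(ValueError, match="dose"):
            DoseRegimen(-1.0)


class TestSingleDose:
    def test_zero_dose_is_flat_baseline(self):
        traj = simulate(DoseRegimen(0.0), MOUSE_PK, MOUSE_TO, MOUSE_PD,
                        grid=GRID_STUDY)
        assert np.all(traj.cp == 0.0)
        assert np.all(traj.to == 0.0)
        assert np.allclose(traj.tracer, MOUSE_TO.bltr)
        assert np.allclose(traj.dserine, MOUSE_PD.bl, rtol=1e-9)

    @pytest.mark.parametrize("dose", DOSES)
    def test_plasma_ode_matches_closed_form(self, dose):
        traj = simulate(DoseRegimen(dose), MOUSE_PK, MOUSE_TO, MOUSE_PD,
                        grid=np.linspace(0, 24, 97))
        ref = pk_closed_form(dose, MOUSE_PK, traj.time)
        assert np.max(np.abs(traj.cp - ref) / ref.max()) < 1e-6

    def test_occupancy_peak_lags_plasma_peak(self):
        traj = simulate(DoseRegimen(0.3), MOUSE_PK, MOUSE_TO, MOUSE_PD,
                        grid=GRID_STUDY)
        obs = traj.time > 0
        t_obs = traj.time[obs]
        assert t_obs[np.argmax(traj.cp[obs])] == 2.0  # earliest sample
        assert t_obs[np.argmax(traj.to[obs])] in (4.0, 6.0)

    def test_tracer_minimum_pinned_by_rk4(self):
        traj = simulate(DoseRegimen(3.0), MOUSE_PK, MOUSE_TO, MOUSE_PD)
        t_ref, y_ref = rk4_system(3.0, 24.0, dt=0.001)
        ref_min = MOUSE_TO.bltr * (1.0 - np.max(y_ref[:, 1]))
        assert np.min(traj.tracer) == pytest.approx(ref_min, rel=1e-4)

    def test_tracer_is_affine_map_of_occupancy(self):
        traj = simulate(DoseRegimen(1.0), MOUSE_PK, MOUSE_TO, MOUSE_PD,
                        grid=GRID_STUDY)
        assert np.allclose(traj.tracer, MOUSE_TO.bltr * (1 - traj.to),
                           rtol=1e-12)

    def test_plasma_dose_proportionality_but_occupancy_saturation(self):
        grid = np.linspace(0, 24, 49)
        lo = simulate(DoseRegimen(0.3), MOUSE_PK, MOUSE_TO, MOUSE_PD, grid=grid)
        hi = simulate(DoseRegimen(10.0), MOUSE_PK, MOUSE_TO, MOUSE_PD, grid=grid)
        ratio = 10.0 / 0.3
        assert np.allclose(hi.cp, ratio * lo.cp, rtol=1e-6)
        # occupancy saturates at BRmax: far less than dose-proportional
        assert np.max(hi.to) < ratio * np.max(lo.to) / 10
        assert np.max(hi.to) <= MOUSE_TO.brmax + 1e-9


class TestMultipleDosing:
    def test_plasma_superposition_of_boluses(self):
        grid = np.linspace(0, 48, 97)
        both = simulate(DoseRegimen(1.0, (0.0, 24.0)), MOUSE_PK, MOUSE_TO,
                        MOUSE_PD, grid=grid)
        expected = pk_closed_form(1.0, MOUSE_PK, grid)
        late = grid >= 24.0
        expected[late] += pk_closed_form(1.0, MOUSE_PK, grid[late] - 24.0)
        assert np.max(np.abs(both.cp - expected)) < 1e-8 * expected.max()

    def test_single_day_qd_equals_single_dose(self):
        qd = simulate_qd(1.0, 1, MOUSE_PK, MOUSE_TO, MOUSE_PD, grid_step=0.1)
        single = simulate(DoseRegimen(1.0), MOUSE_PK, MOUSE_TO, MOUSE_PD,
                          grid=qd.time)
        assert np.allclose(qd.cp, single.cp, rtol=1e-9, atol=1e-12)
        assert np.allclose(qd.to, single.to, rtol=1e-8, atol=1e-10)

    @pytest.mark.parametrize("dose", (0.3, 10.0))
    def test_steady_state_within_a_few_days(self, dose):
        """Troughs of every layer change by <5% between day 3 and day 7 —
        no accumulation under once-daily dosing."""
        traj = simulate_qd(dose, 7, MOUSE_PK, MOUSE_TO, MOUSE_PD,
                           grid_step=0.05)
        cyc = cycle_extrema(traj)
        for series in ("cp", "to", "dserine"):
            d3 = cyc[f"{series}_trough"].iloc[2]
            d7 = cyc[f"{series}_trough"].iloc[6]
            assert abs(d7 - d3) / d7 < 0.05


class TestComparisonModels:
    def test_direct_model_half_saturation(self):
        alt = AltTOParams(model="direct_emax", ec50=5.0, brmax=0.987,
                          bltr=21.6)
        traj = simulate_alt_to(DoseRegimen(1.0), MOUSE_PK, alt,
                               grid=np.linspace(0, 24, 200))
        idx = np.argmin(np.abs(traj.cp - 5.0))
        assert traj.to[idx] == pytest.approx(0.987 / 2, rel=5e-3)

    def test_direct_model_peak_coincides_with_plasma_peak(self):
        alt = AltTOParams(model="direct_emax", ec50=3.0, brmax=0.9, bltr=21.6)
        traj = simulate_alt_to(DoseRegimen(1.0), MOUSE_PK, alt)
        assert np.argmax(traj.to) == np.argmax(traj.cp)

    def test_fast_effect_compartment_limits_to_direct(self):
        grid = np.linspace(0.5, 24, 100)
        direct = simulate_alt_to(
            DoseRegimen(1.0), MOUSE_PK,
            AltTOParams(model="direct_emax", ec50=3.0, brmax=0.9, bltr=21.6),
            grid=grid,
        )
        fast = simulate_alt_to(
            DoseRegimen(1.0), MOUSE_PK,
            AltTOParams(model="effect_compartment", ec50=3.0, brmax=0.9,
                        bltr=21.6, ke0=1e3),
            grid=grid,
        )
        assert np.max(np.abs(fast.to - direct.to)) < 1e-3

    def test_effect_compartment_lags_plasma(self):
        alt = AltTOParams(model="effect_compartment", ec50=3.0, brmax=0.9,
                          bltr=21.6, ke0=0.3)
        traj = simulate_alt_to(DoseRegimen(1.0), MOUSE_PK, alt)
        assert traj.time[np.argmax(traj.to)] > traj.time[np.argmax(traj.cp)]

    def test_missing_ke0_rejected(self):
        with pytest.raises(ValueError, match="ke0"):
            AltTOParams(model="effect_compartment", ec50=3.0, brmax=0.9,
                        bltr=21.6)


class TestHysteresis:
    def test_binding_kinetics_loop_is_anticlockwise(self):
        traj = simulate(DoseRegimen(0.3), MOUSE_PK, MOUSE_TO, MOUSE_PD)
        res = hysteresis_curve(traj)
        assert res.orientation == "anticlockwise"
        assert res.signed_area > 0

    def test_direct_model_loop_degenerate(self):
        alt = AltTOParams(model="direct_emax", ec50=3.0, brmax=0.9, bltr=21.6)
        traj = simulate_alt_to(DoseRegimen(0.3), MOUSE_PK, alt)
        res = hysteresis_curve(traj)
        assert res.orientation == "degenerate"
        assert res.signed_area == 0.0

    def test_fast_dissociation_shrinks_the_loop(self):
        # Koff >> 1 equilibrates binding: loop area vanishes with the lag
        from pktopd.model import TOParams
        slow = simulate(DoseRegimen(0.3), MOUSE_PK, MOUSE_TO, MOUSE_PD)
        fast_to = TOParams(kon=MOUSE_TO.kon * 500, koff=MOUSE_TO.koff * 500,
                           brmax=MOUSE_TO.brmax, bltr=MOUSE_TO.bltr)
        fast = simulate(DoseRegimen(0.3), MOUSE_PK, fast_to, MOUSE_PD)
        a_slow = abs(hysteresis_curve(slow).signed_area)
        a_fast = abs(hysteresis_curve(fast).signed_area)
        assert a_fast < 0.02 * a_slow

    def test_too_few_points_rejected(self):
        traj = simulate(DoseRegimen(0.3), MOUSE_PK, MOUSE_TO, MOUSE_PD,
                        grid=np.array([0.0, 24.0]))
        with pytest.raises(ValueError, match="3 points"):
            hysteresis_curve(traj)


def test_trajectory_tidy_export_round_trips(tmp_path):
    traj = simulate(DoseRegimen(1.0), MOUSE_PK, MOUSE_TO, MOUSE_PD,
                    grid=GRID_STUDY)
    frame = traj.to_frame()
    assert list(frame.columns) == [
        "time_h", "cp_ng_ml", "to_frac", "tracer_ng_g", "dserine_nmol_g",
    ]
    path = tmp_path / "traj.csv"
    frame.to_csv(path, index=False)
    import pandas as pd
    back = pd.read_csv(path)
    assert np.allclose(back["to_frac"], traj.to)
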