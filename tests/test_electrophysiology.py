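import numpy as np
import pytest

from emdsim.config import CellConfig, NumericsConfig
from emdsim.electrophysiology import (
    CalciumTransient,
    MembraneParams,
    MonodomainResult,
    NoWaveError,
    StimulusEvent,
    calcium_from_potential,
    calibrate_membrane,
    integrate_calcium,
    integrate_monodomain,
    make_fiber_state,
    measure_cv,
    membrane_rhs,
    release_drive,
)

CELL = CellConfig()
P = MembraneParams()


class TestMembrane:
    def test_rest_is_equilibrium(self):
        dv, dr = membrane_rhs(0.0, 0.0, 0.0, P, CELL)
        assert dv == 0.0 and dr == 0.0

    def test_subthreshold_decays(self):
        dv, _ = membrane_rhs(P.a_ap - 0.01, 0.0, 0.0, P, CELL)
        assert dv < 0

    def test_suprathreshold_regenerates(self):
        # the cubic -k v (v - a)(v - 1) is positive on (a, 1)
        dv, _ = membrane_rhs(P.a_ap + 0.01, 0.0, 0.0, P, CELL)
        assert dv > 0


class TestMonodomain:
    def test_rest_stays_at_rest(self):
        state = make_fiber_state(0.5, 0.01)
        res = integrate_monodomain(state, [], CELL, P, 0.01, 500.0,
                                   sample_dt=10.0)
        assert np.max(np.abs(res.v)) < 1e-12

    def test_midpoint_stimulus_activates_symmetrically(self):
        state = make_fiber_state(1.0, 0.005)
        mid = state.midpoint_index
        stim = StimulusEvent(node_index=mid, t_on=0.2, amplitude=90.0)
        res = integrate_monodomain(state, [stim], CELL, P, 0.005, 8.0)
        act = res.activation_times
        assert np.isfinite(act).all()
        # mirror nodes activate within one time step of each other
        left = act[mid - 1 :: -1]
        right = act[mid + 1 :]
        n = min(len(left), len(right))
        assert np.max(np.abs(left[:n] - right[:n])) < 0.005 + 1e-12

    def test_divergence_raises(self):
        state = make_fiber_state(0.5, 0.05)
        stim = StimulusEvent(node_index=state.midpoint_index, t_on=0.0,
                             amplitude=90.0)
        # grossly unstable reaction step (dt >> membrane time scale)
        with pytest.raises(RuntimeError, match="dx"):
            integrate_monodomain(state, [stim], CELL, P, 5.0, 100.0)


class TestMeasureCV:
    def test_synthetic_traveling_pulse(self):
        # v(s, t) = f(s - c t) with c = 2 cm/ms -> 20 m/s
        c = 2.0
        grid = np.linspace(0, 4.0, 201)
        times = np.arange(0.0, 2.0, 0.01)
        v = 1.0 / (1.0 + np.exp(-((c * times[:, None] - grid[None, :]) / 0.05)))
        res = MonodomainResult(times=times, v=v, grid=grid,
                               activation_times=np.full(len(grid), np.nan),
                               stim_node=0)
        assert measure_cv(res) == pytest.approx(20.0, rel=1e-3)

    def test_no_wave_raises(self):
        grid = np.linspace(0, 1.0, 51)
        res = MonodomainResult(times=np.arange(0.0, 1.0, 0.1),
                               v=np.zeros((10, 51)), grid=grid,
                               activation_times=np.full(51, np.nan),
                               stim_node=25)
        with pytest.raises(NoWaveError):
            measure_cv(res)


class TestCalibration:
    def test_rejects_nonpositive_target(self):
        with pytest.raises(ValueError):
            calibrate_membrane(0.0, CELL)

    def test_time_scale_inverse_to_target(self):
        num = NumericsConfig()
        p35 = calibrate_membrane(3.5, CELL, num)
        p70 = calibrate_membrane(7.0, CELL, num)
        assert p70.t_scale == pytest.approx(p35.t_scale / 2.0, rel=0.05)


class TestCalcium:
    CT = CalciumTransient()

    def test_zero_potential_zero_calcium(self):
        times = np.arange(0.0, 50.0, 0.1)
        ca = calcium_from_potential(np.zeros_like(times), times, self.CT)
        assert np.all(ca == 0.0)

    def test_pulse_matches_closed_form(self):
        # unit pulse of width w: ca(w) = k tau (1 - exp(-w / tau)) * (1 - thr)
        w = 10.0
        times = np.arange(0.0, 250.0, 0.01)
        v = np.where(times < w, 1.0, 0.0)
        ca = calcium_from_potential(v, times, self.CT)
        drive = 1.0 - self.CT.v_thresh
        expected = (self.CT.k_rel * drive * self.CT.tau_ca
                    * (1.0 - np.exp(-w / self.CT.tau_ca)))
        i_end = int(round(w / 0.01))
        assert ca[i_end] == pytest.approx(expected, rel=1e-2)
        # afterwards pure exponential decay back below 1% of peak
        assert ca[-1] < 0.01 * ca.max()
        assert np.all(ca >= 0.0)

    def test_release_gate_is_stereotyped(self):
        ct = CalciumTransient(rel_duration=8.0)
        times = np.arange(0.0, 40.0, 0.1)
        # two traces crossing threshold at the same instant but with very
        # different suprathreshold durations must yield identical drives
        v_short = np.where((times >= 5) & (times < 7), 1.0, 0.0)
        v_long = np.where((times >= 5) & (times < 25), 0.9, 0.0)
        d1 = release_drive(v_short, times, ct)
        d2 = release_drive(v_long, times, ct)
        assert np.array_equal(d1, d2)
        assert d1.sum() * 0.1 == pytest.approx(8.0, abs=0.2)

    def test_integrate_calcium_nonnegative_and_decaying(self):
        times = np.arange(0.0, 300.0, 0.1)
        drive = np.where(times < 8.0, 1.0, 0.0)
        ca = integrate_calcium(drive, times, self.CT)
        assert np.all(ca >= 0.0)
        assert ca[-1] < 0.01 * ca.max()
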