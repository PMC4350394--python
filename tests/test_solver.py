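"""Time stepping: fixed points, determinism, 1D pulse benchmarks,
temporal convergence."""

import numpy as np
import pytest

import sdsim as sd
from sdsim.model import (RDParameters, RDState, assemble_laplace_beltrami,
                         rest_state, uniform_rest_state)
from sdsim.solver import (SimulationConfig, Solver1D, Stepper, pulse_speed_1d,
                          run_simulation, segment_cog)

# Reference 1D pulse speed for (eps=0.04, beta=0.9, D=1, k=0), computed
# once from a fine-grid oracle run (resolution 0.0625, dt 0.0125); the
# default-resolution benchmark must agree within 1%.
PULSE_SPEED_ORACLE = 1.30373


@pytest.fixture(scope="module")
def small_sheet():
    return sd.make_flat_sheet((40, 20), 1.0, "periodic")


class TestFixedPoint:
    def test_rest_state_held_1000_steps(self, small_sheet):
        p = RDParameters(beta=0.9, k=0.0)
        st = uniform_rest_state(p, small_sheet.n_dofs)
        cfg = SimulationConfig(dt=0.05, n_steps=1000, snapshot_stride=1000)
        _, final = run_simulation(st, p, small_sheet, cfg)
        assert np.abs(final.u - st.u).max() < 1e-8
        assert np.abs(final.v - st.v).max() < 1e-8

    def test_zero_steps_returns_initial_only(self, small_sheet):
        p = RDParameters()
        st = uniform_rest_state(p, small_sheet.n_dofs)
        cfg = SimulationConfig(dt=0.05, n_steps=0)
        series, final = run_simulation(st, p, small_sheet, cfg)
        assert len(series) == 1
        np.testing.assert_array_equal(series.states[0].u, st.u)


class TestDeterminism:
    def test_bitwise_identical_runs(self, small_sheet):
        p = RDParameters.preset("bump-study")
        rng = np.random.default_rng(3)
        u0, v0 = rest_state(p)
        u = u0 + 0.1 * rng.standard_normal(small_sheet.n_dofs)
        v = np.full(small_sheet.n_dofs, v0)
        cfg = SimulationConfig(dt=0.05, n_steps=200, snapshot_stride=50)
        s1, f1 = run_simulation(RDState(u.copy(), v.copy()), p, small_sheet,
                                cfg)
        s2, f2 = run_simulation(RDState(u.copy(), v.copy()), p, small_sheet,
                                cfg)
        np.testing.assert_array_equal(f1.u, f2.u)
        np.testing.assert_array_equal(f1.v, f2.v)
        for a, b in zip(s1.states, s2.states):
            np.testing.assert_array_equal(a.u, b.u)


class TestSubthresholdStability:
    def test_small_perturbation_decays(self, small_sheet):
        # beta = 1.2: the uniform state is a stable focus, so the decay is
        # oscillatory; the envelope must shrink and u must stay subthreshold
        p = RDParameters(beta=1.2, k=0.0)
        op = assemble_laplace_beltrami(small_sheet)
        u0, v0 = rest_state(p)
        u = np.full(small_sheet.n_dofs, u0)
        u[small_sheet.n_dofs // 2] += 0.3
        st = RDState(u, np.full(small_sheet.n_dofs, v0))
        stepper = Stepper(p, op, SimulationConfig(dt=0.05, n_steps=1))
        devs = []
        for i in range(800):
            st = stepper.step(st)
            devs.append(np.abs(st.u - u0).max())
            assert st.u.max() < 0.0
        assert devs[-1] < 0.05 * devs[0]
        assert max(devs[-100:]) < max(devs[:100])


class TestPulse1D:
    def test_speed_matches_fine_grid_oracle(self):
        p = RDParameters(beta=0.9, k=0.0)
        r = pulse_speed_1d(p)
        assert r.propagated
        assert r.speed == pytest.approx(PULSE_SPEED_ORACLE, rel=0.01)

    def test_sqrt_D_scaling(self):
        r1 = pulse_speed_1d(RDParameters(beta=0.9, k=0.0, D=1.0))
        r4 = pulse_speed_1d(RDParameters(beta=0.9, k=0.0, D=4.0))
        assert r4.speed / r1.speed == pytest.approx(2.0, rel=0.02)

    def test_speed_constant_after_transient(self):
        r = pulse_speed_1d(RDParameters(beta=0.9, k=0.0))
        resid = r.front_positions - np.polyval(
            np.polyfit(r.front_times, r.front_positions, 1), r.front_times)
        drift = np.ptp(resid) / (r.speed * np.ptp(r.front_times))
        assert drift < 0.01

    def test_above_boundary_no_propagation(self):
        r = pulse_speed_1d(RDParameters(beta=1.8, k=0.0))
        assert not r.propagated and r.speed is None


class TestTemporalConvergence:
    def test_order_at_least_1p8(self):
        # Richardson on a smooth developed pulse; grid fixed, dt halved
        p = RDParameters(beta=1.2, k=0.0)
        base = Solver1D(p, length=200.0, resolution=0.25, dt=0.05)
        st = base.initial_pulse((40.0, 50.0))
        for _ in range(400):
            st = base.step(st)
        finals = {}
        for dt in (0.1, 0.05, 0.025):
            s = Solver1D(p, length=200.0, resolution=0.25, dt=dt)
            x = RDState(st.u.copy(), st.v.copy())
            for _ in range(int(round(5.0 / dt))):
                x = s.step(x)
            finals[dt] = x.u
        e1 = np.linalg.norm(finals[0.1] - finals[0.05])
        e2 = np.linalg.norm(finals[0.05] - finals[0.025])
        assert np.log2(e1 / e2) >= 1.8


class TestSeriesContainer:
    def test_snapshot_times_strictly_increasing(self, small_sheet):
        p = RDParameters.preset("bump-study")
        st = uniform_rest_state(p, small_sheet.n_dofs)
        cfg = SimulationConfig(dt=0.05, n_steps=100, snapshot_stride=20)
        series, _ = run_simulation(st, p, small_sheet, cfg)
        assert np.all(np.diff(series.times) > 0)
        assert len(series) == 6

    def test_save_container(self, small_sheet, tmp_path):
        p = RDParameters.preset("bump-study")
        st = uniform_rest_state(p, small_sheet.n_dofs)
        cfg = SimulationConfig(dt=0.05, n_steps=20, snapshot_stride=10)
        series, _ = run_simulation(st, p, small_sheet, cfg)
        out = tmp_path / "series.npz"
        series.save(out)
        data = np.load(out)
        assert data["u"].shape == (3, small_sheet.n_dofs)
        np.testing.assert_allclose(data["times"], series.times)

    def test_dt_guard(self):
        with pytest.raises(ValueError):
            SimulationConfig(dt=0.5)
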