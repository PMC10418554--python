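import math

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.optimize import fsolve

from pulmo1d.network import VesselSegment, build_network
from pulmo1d.solver import (
    FluidProperties,
    InflowWaveform,
    SimulationConfig,
    junction_coupling,
    lax_wendroff_cycle,
    simulate_to_periodic,
    uniform_walls,
    velocity_profile,
    windkessel_outlet_step,
)
from pulmo1d.units import MMHG
from pulmo1d.wall import WallModel, Windkessel3, nominal_windkessels


class TestVelocityProfile:
    def test_no_slip(self):
        assert velocity_profile(10.0, 0.3, 0.3, gamma=9.0) == pytest.approx(0.0)

    def test_centerline(self):
        assert velocity_profile(9.0, 0.0, 0.3, gamma=9.0) == pytest.approx(11.0)

    @pytest.mark.parametrize("gamma", [2.0, 5.0, 9.0])
    def test_cross_sectional_average(self, gamma):
        radius, u_bar = 0.4, 12.0
        integral, _ = quad(
            lambda r: velocity_profile(u_bar, r, radius, gamma) * r, 0.0, radius
        )
        assert 2.0 / radius**2 * integral == pytest.approx(u_bar, rel=1e-9)

    def test_outside_lumen(self):
        with pytest.raises(ValueError):
            velocity_profile(10.0, 0.4, 0.3)


class TestInflowWaveform:
    def test_requires_periodicity(self):
        q = np.linspace(0.0, 1.0, 32)
        with pytest.raises(ValueError, match="periodic"):
            InflowWaveform(q, 0.5)

    def test_fourier_interpolation_hits_samples(self):
        t = np.linspace(0.0, 0.5, 65)
        q = 3.0 + np.sin(2 * np.pi * t / 0.5) + 0.5 * np.cos(4 * np.pi * t / 0.5)
        wf = InflowWaveform(q, 0.5)
        np.testing.assert_allclose(wf.at(t[:-1]), q[:-1], atol=1e-10)

    def test_mean_and_stroke_volume(self):
        wf = InflowWaveform(np.full(33, 30.0), 0.5)
        assert wf.mean == pytest.approx(30.0)
        assert wf.stroke_volume == pytest.approx(15.0)


def _single_vessel(radius=0.3, length=2.0):
    return build_network([VesselSegment(id="v", length=length, radius=radius)])


class TestEquilibrium:
    def test_zero_inflow_diastolic_rest_is_fixed_point(self):
        net = _single_vessel()
        p_dia = 10.0 * MMHG
        walls = uniform_walls(net, 1.0e5, p_dia)
        wk = {"v": Windkessel3(Rp=100.0, Rd=500.0, C=1e-5, Pout=p_dia)}
        inflow = InflowWaveform(np.zeros(33), 0.2)
        cfg = SimulationConfig(cycle_length=0.2, dx_target=0.2)
        sol = lax_wendroff_cycle(net, walls, wk, inflow, FluidProperties(), cfg)
        seg = sol.segments["v"]
        adia = walls["v"].area_dia
        np.testing.assert_allclose(seg.A, adia, rtol=1e-13)
        np.testing.assert_allclose(seg.Q, 0.0, atol=1e-12)

    def test_zero_inflow_converges_in_two_cycles(self):
        net = _single_vessel()
        p_dia = 10.0 * MMHG
        walls = uniform_walls(net, 1.0e5, p_dia)
        wk = {"v": Windkessel3(Rp=100.0, Rd=500.0, C=1e-5, Pout=p_dia)}
        inflow = InflowWaveform(np.zeros(33), 0.2)
        cfg = SimulationConfig(cycle_length=0.2, dx_target=0.2)
        sol = simulate_to_periodic(net, walls, wk, inflow, FluidProperties(), cfg)
        assert sol.report.converged
        assert sol.report.n_cycles == 2


def _steady_solution(gamma, f=3.0e6, q0=10.0):
    net = _single_vessel()
    p_dia = 10.0 * MMHG
    walls = uniform_walls(net, f, p_dia)
    props = FluidProperties(gamma=gamma)
    wk = {
        "v": Windkessel3(
            Rp=0.05 * MMHG, Rd=0.3 * MMHG, C=0.5 / MMHG / 20.0, Pout=p_dia
        )
    }
    inflow = InflowWaveform(np.full(64, q0), 0.2)
    cfg = SimulationConfig(cycle_length=0.2, dx_target=0.2, periodicity_tol=1e-6)
    return simulate_to_periodic(net, walls, wk, inflow, props, cfg), props, q0


class TestSteadyOracles:
    @pytest.mark.parametrize("gamma", [9.0, 2.0])
    def test_steady_drop_matches_momentum_balance(self, gamma):
        sol, props, q0 = _steady_solution(gamma)
        seg = sol.segments["v"]
        drop = seg.P[0, -1] - seg.P[-1, -1]
        area = float(seg.A[:, -1].mean())
        analytic = 2.0 * math.pi * props.mu * (gamma + 2.0) * q0 * 2.0 / area**2
        assert drop == pytest.approx(analytic, rel=0.01)

    def test_gamma2_is_poiseuille(self):
        sol, props, q0 = _steady_solution(2.0)
        seg = sol.segments["v"]
        drop = seg.P[0, -1] - seg.P[-1, -1]
        area = float(seg.A[:, -1].mean())
        assert drop == pytest.approx(8.0 * math.pi * props.mu * q0 * 2.0 / area**2, rel=0.01)


class TestPulseWaveSpeed:
    def test_small_amplitude_speed(self):
        net = build_network([VesselSegment(id="v", length=40.0, radius=0.5)])
        f = 1.0e5
        p_dia = 10.0 * MMHG
        walls = uniform_walls(net, f, p_dia)
        props = FluidProperties(gamma=9.0)
        c_theory = math.sqrt(2.0 * f / (3.0 * props.rho))
        tau = 0.015

        def pulse(t):
            return math.sin(math.pi * t / tau) ** 2 if t < tau else 0.0

        inflow = InflowWaveform.from_function(pulse, 0.5, n=2048)
        wk = {"v": Windkessel3(Rp=1e3, Rd=1e5, C=1e-6, Pout=p_dia)}
        cfg = SimulationConfig(cycle_length=0.5, dx_target=0.1)
        sol = lax_wendroff_cycle(net, walls, wk, inflow, props, cfg)
        seg = sol.segments["v"]

        def arrival(i):
            q = seg.Q[i]
            k = int(np.argmax(q))
            d = 0.5 * (q[k - 1] - q[k + 1]) / (q[k - 1] - 2 * q[k] + q[k + 1])
            return sol.t[k] + d * (sol.t[1] - sol.t[0])

        i1 = int(np.argmin(np.abs(seg.x - 10.0)))
        i2 = int(np.argmin(np.abs(seg.x - 30.0)))
        speed = (seg.x[i2] - seg.x[i1]) / (arrival(i2) - arrival(i1))
        assert speed == pytest.approx(c_theory, rel=0.05)


class TestWindkesselOutlet:
    def test_steady_state_circuit_law(self):
        # Q = 10 mL/s, Rp = 0.1, Rd = 0.5 mmHg*s/mL, Pout = 5 mmHg -> 11 mmHg
        wk = Windkessel3(Rp=0.1 * MMHG, Rd=0.5 * MMHG, C=1.0 / MMHG, Pout=5.0 * MMHG)
        pc = wk.Pout
        dt = 1e-3
        for _ in range(30000):
            p, pc = windkessel_outlet_step(10.0, pc, wk, dt)
        assert p / MMHG == pytest.approx(11.0, rel=1e-9)

    def test_transient_time_constant(self):
        wk = Windkessel3(Rp=0.1 * MMHG, Rd=0.5 * MMHG, C=0.8 / MMHG, Pout=5.0 * MMHG)
        tau = wk.Rd * wk.C
        dt = tau / 500.0
        pc = wk.Pout
        trace = []
        n = int(round(3.0 * tau / dt))
        for _ in range(n):
            _, pc = windkessel_outlet_step(10.0, pc, wk, dt)
            trace.append(pc)
        trace = np.asarray(trace)
        p_inf = wk.Pout + 10.0 * wk.Rd
        t = dt * np.arange(1, n + 1)
        # log-linear fit of the relaxation
        mask = (trace < p_inf - 0.05 * (p_inf - wk.Pout))
        slope = np.polyfit(t[mask], np.log(p_inf - trace[mask]), 1)[0]
        assert -1.0 / slope == pytest.approx(tau, rel=0.02)

    def test_requires_positive_dt(self):
        wk = Windkessel3(Rp=1.0, Rd=1.0, C=1.0, Pout=0.0)
        with pytest.raises(ValueError):
            windkessel_outlet_step(1.0, 0.0, wk, 0.0)


class TestJunctionCoupling:
    def _walls(self, f1=1.0e5, f2=1.0e5):
        p_dia = 10.0 * MMHG
        wp = WallModel(stiffness=1.0e5, area_dia=1.0, p_dia=p_dia)
        w1 = WallModel(stiffness=f1, area_dia=0.6, p_dia=p_dia)
        w2 = WallModel(stiffness=f2, area_dia=0.6, p_dia=p_dia)
        return wp, w1, w2

    def test_symmetric_children_split_evenly(self):
        walls = self._walls()
        js = junction_coupling((1.05, 20.0), (0.6, 8.0), (0.6, 8.0), walls)
        assert js.child1[1] == pytest.approx(js.child2[1], rel=1e-12)
        assert js.parent[1] == pytest.approx(js.child1[1] + js.child2[1], rel=1e-12)
        assert js.parent[2] == pytest.approx(js.child1[2], rel=1e-10)

    def test_residuals_at_machine_precision(self):
        walls = self._walls()
        js = junction_coupling((1.02, 15.0), (0.63, 9.0), (0.58, 5.0), walls)
        assert js.flow_residual < 1e-10
        assert js.pressure_residual < 1e-10

    def test_asymmetric_stiffness_against_independent_solver(self):
        """Dual route: same physical system solved with scipy.fsolve."""
        rho = 1.03
        walls = self._walls(f1=4.0e5, f2=1.0e5)
        wp, w1, w2 = walls
        parent_state, c1_state, c2_state = (1.05, 20.0), (0.6, 8.0), (0.6, 8.0)

        def cw(a, w):
            return math.sqrt(2.0 * w.stiffness / (3.0 * rho) * math.sqrt(a / w.area_dia))

        def ptube(a, w):
            return (4.0 / 3.0) * w.stiffness * (math.sqrt(a / w.area_dia) - 1.0) + w.p_dia

        wp_inv = parent_state[1] / parent_state[0] + 4.0 * cw(parent_state[0], wp)
        w1_inv = c1_state[1] / c1_state[0] - 4.0 * cw(c1_state[0], w1)
        w2_inv = c2_state[1] / c2_state[0] - 4.0 * cw(c2_state[0], w2)

        def system(x):
            qp, ap, q1, a1, q2, a2 = x
            return [
                qp / ap + 4.0 * cw(ap, wp) - wp_inv,
                q1 / a1 - 4.0 * cw(a1, w1) - w1_inv,
                q2 / a2 - 4.0 * cw(a2, w2) - w2_inv,
                qp - q1 - q2,
                ptube(ap, wp) - ptube(a1, w1),
                ptube(ap, wp) - ptube(a2, w2),
            ]

        ref = fsolve(system, [20.0, 1.05, 8.0, 0.6, 8.0, 0.6], full_output=False)
        js = junction_coupling(parent_state, c1_state, c2_state, walls, rho=rho)
        got = [js.parent[1], js.parent[0], js.child1[1], js.child1[0],
               js.child2[1], js.child2[0]]
        np.testing.assert_allclose(got, ref, rtol=1e-8)
        # pressures equal, flows split unequally toward the softer daughter
        assert js.child1[2] == pytest.approx(js.child2[2], rel=1e-10)
        assert js.child1[1] != pytest.approx(js.child2[1], rel=1e-3)


@pytest.fixture(scope="module")
def toy_pulsatile(props):
    """Pulsatile 3-vessel tree run to periodicity."""
    net = build_network(
        [
            VesselSegment(id="0", name="MPA", length=3.0, radius=0.55,
                          children=("1", "2"), is_extralobar=True),
            VesselSegment(id="1", name="LPA", length=2.5, radius=0.42,
                          parent="0", is_extralobar=True),
            VesselSegment(id="2", name="RPA", length=2.5, radius=0.45,
                          parent="0", is_extralobar=True),
        ]
    )
    p_dia = 10.0 * MMHG
    walls = uniform_walls(net, 1.0e5, p_dia)
    wk = nominal_windkessels(net, 0.45 * MMHG, 0.8 / MMHG, props.mu, 5.0 * MMHG)
    t_sys = 0.2

    def q(t):
        return (math.pi * 15.0 / (2 * t_sys)) * math.sin(math.pi * t / t_sys) if t < t_sys else 0.0

    inflow = InflowWaveform.from_function(q, 0.5, n=512)

    def run(dx):
        cfg = SimulationConfig(cycle_length=0.5, dx_target=dx)
        return simulate_to_periodic(net, walls, wk, inflow, props, cfg)

    return run


class TestPeriodicSimulation:
    def test_converges_within_twenty_cycles(self, toy_pulsatile):
        sol = toy_pulsatile(0.25)
        assert sol.report.converged
        assert sol.report.n_cycles <= 20

    def test_junction_residuals_below_tolerance(self, toy_pulsatile):
        sol = toy_pulsatile(0.25)
        assert sol.report.max_flow_residual < 1e-10
        assert sol.report.max_pressure_residual < 1e-10

    def test_volume_conservation(self, toy_pulsatile):
        sol = toy_pulsatile(0.25)
        rep = sol.report
        stroke_volume = rep.volume_in
        imbalance = abs(rep.volume_in - rep.volume_out - rep.volume_stored)
        assert imbalance < 0.005 * stroke_volume

    def test_grid_convergence_of_systolic_pressure(self, toy_pulsatile):
        p_coarse = toy_pulsatile(0.25).extrema("0")[0]
        p_fine = toy_pulsatile(0.125).extrema("0")[0]
        assert abs(p_coarse - p_fine) / p_fine < 0.01

    def test_area_positive_and_fields_finite(self, toy_pulsatile):
        sol = toy_pulsatile(0.25)
        for seg in sol.segments.values():
            assert np.all(seg.A > 0)
            assert np.all(np.isfinite(seg.P))
            assert np.all(np.isfinite(seg.Q))

    def test_inflow_period_mismatch_rejected(self, toy_pulsatile, props):
        net = _single_vessel()
        walls = uniform_walls(net, 1.0e5, 10.0 * MMHG)
        wk = {"v": Windkessel3(Rp=100.0, Rd=500.0, C=1e-5, Pout=5.0 * MMHG)}
        inflow = InflowWaveform(np.zeros(33), 0.3)
        cfg = SimulationConfig(cycle_length=0.5)
        with pytest.raises(ValueError, match="period"):
            simulate_to_periodic(net, walls, wk, inflow, props, cfg)
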