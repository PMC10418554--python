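import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from pulmo1d.network import VesselSegment, build_network, poiseuille_resistance
from pulmo1d.units import MMHG
from pulmo1d.wall import (
    HemodynamicSummary,
    WallModel,
    Windkessel3,
    mean_pa_pressure,
    nominal_windkessels,
    nominal_windkessels_lung_split,
    parallel_resistance,
    stiffness_from_systole,
    total_compliance,
    total_compliance_from_decay,
    total_pvr,
    tube_law_area,
    tube_law_pressure,
)


class TestScalarFormulas:
    def test_mean_pa_pressure(self):
        assert mean_pa_pressure(30.0, 15.0) == pytest.approx(20.0)

    def test_mean_pa_pressure_identity(self):
        assert mean_pa_pressure(17.0, 17.0) == pytest.approx(17.0)

    def test_mean_pa_pressure_ordering(self):
        with pytest.raises(ValueError):
            mean_pa_pressure(51.0, 60.0)

    def test_total_pvr(self):
        assert total_pvr(20.0, 5.0, 25.0) == pytest.approx(0.6)

    def test_pvr_unit_conversion(self):
        assert 0.6 * MMHG == pytest.approx(799.932, rel=1e-6)

    def test_total_pvr_bad_gradient(self):
        with pytest.raises(ValueError):
            total_pvr(5.0, 20.0, 25.0)
        with pytest.raises(ValueError):
            total_pvr(20.0, 5.0, 0.0)


@pytest.fixture()
def wall():
    # Eh/r0 = 150 mmHg (CGS internally), Adia = 1 cm^2, Pdia = 10 mmHg
    return WallModel(stiffness=150.0 * MMHG, area_dia=1.0, p_dia=10.0 * MMHG)


class TestTubeLaw:
    def test_reference_state(self, wall):
        assert tube_law_pressure(wall.area_dia, wall) == pytest.approx(wall.p_dia)
        assert tube_law_area(wall.p_dia, wall) == pytest.approx(wall.area_dia)

    def test_printed_example(self, wall):
        # A = 1.21 -> P = (4/3)*150*(1.1-1) + 10 = 30 mmHg
        assert tube_law_pressure(1.21, wall) / MMHG == pytest.approx(30.0, rel=1e-12)
        assert tube_law_area(30.0 * MMHG, wall) == pytest.approx(1.21, rel=1e-12)

    def test_monotone_in_area(self, wall):
        areas = np.linspace(0.3, 3.0, 50)
        p = tube_law_pressure(areas, wall)
        assert np.all(np.diff(p) > 0)

    def test_round_trip_random(self, wall):
        rng = np.random.default_rng(7)
        pressures = rng.uniform(1.0, 80.0, 100) * MMHG
        back = tube_law_pressure(tube_law_area(pressures, wall), wall)
        np.testing.assert_allclose(back, pressures, rtol=1e-12)

    def test_collapse_regime(self, wall):
        with pytest.raises(ValueError, match="collapse"):
            tube_law_area(-300.0 * MMHG, wall)

    @given(
        stiffness=st.floats(10.0, 500.0),
        area_ratio=st.floats(1.001, 4.0),
        adia=st.floats(0.1, 5.0),
    )
    def test_inverse_property(self, stiffness, area_ratio, adia):
        w = WallModel(stiffness=stiffness * MMHG, area_dia=adia, p_dia=8.0 * MMHG)
        a = adia * area_ratio
        assert tube_law_area(tube_law_pressure(a, w), w) == pytest.approx(a, rel=1e-12)


class TestStiffnessFromSystole:
    def test_printed_example(self):
        assert stiffness_from_systole(30.0, 10.0, 1.21, 1.0) == pytest.approx(150.0)

    def test_forward_substitution(self):
        f = stiffness_from_systole(30.0, 10.0, 1.21, 1.0)
        w = WallModel(stiffness=f * MMHG, area_dia=1.0, p_dia=10.0 * MMHG)
        assert tube_law_pressure(1.21, w) / MMHG == pytest.approx(30.0, rel=1e-12)

    def test_vanishing_pulse_pressure_limit(self):
        f = stiffness_from_systole(10.0 + 1e-9, 10.0, 1.21, 1.0)
        assert f < 1e-7

    def test_no_distension(self):
        with pytest.raises(ValueError, match="distension"):
            stiffness_from_systole(30.0, 10.0, 1.0, 1.0)

    @given(
        stiffness=st.floats(20.0, 400.0),
        asys_ratio=st.floats(1.01, 3.0),
    )
    def test_round_trip_with_tube_law(self, stiffness, asys_ratio):
        w = WallModel(stiffness=stiffness * MMHG, area_dia=1.3, p_dia=9.0 * MMHG)
        a_sys = w.area_dia * asys_ratio
        p_sys = tube_law_pressure(a_sys, w) / MMHG
        est = stiffness_from_systole(p_sys, 9.0, a_sys, w.area_dia)
        assert est == pytest.approx(stiffness, rel=1e-10)


def _summary(p_sys=30.0, p_dia=15.0, t_dia=0.4):
    return HemodynamicSummary(
        p_sys=p_sys, p_dia=p_dia, a_sys=1.2, a_dia=1.0,
        p_wedge=5.0, q_mean=25.0, period=0.6, t_dia=t_dia,
    )


class TestComplianceFromDecay:
    def test_closed_form(self):
        c = total_compliance_from_decay(_summary(), 0.6)
        assert c == pytest.approx(0.4 / (0.6 * math.log(2.5)), rel=1e-12)
        assert c == pytest.approx(0.7276, abs=2e-4)

    def test_trace_fit_recovers_known_tau(self):
        r, c_true = 0.6, 0.9
        t = np.linspace(0.0, 0.4, 60)
        p = 5.0 + (30.0 - 5.0) * np.exp(-t / (r * c_true))
        c_fit = total_compliance_from_decay(_summary(), r, pressure_trace=(t, p))
        assert c_fit == pytest.approx(c_true, rel=0.01)

    def test_diastolic_below_wedge(self):
        with pytest.raises(ValueError):
            total_compliance_from_decay(_summary(p_dia=4.9), 0.6)


class TestParallelCombination:
    def test_two_equal_resistances(self):
        assert parallel_resistance([2.0, 2.0]) == pytest.approx(1.0)

    def test_compliances_sum(self):
        assert total_compliance([0.3, 0.7]) == pytest.approx(1.0)

    def test_single_element(self):
        assert parallel_resistance([3.5]) == pytest.approx(3.5)
        assert total_compliance([0.4]) == pytest.approx(0.4)

    def test_empty_list(self):
        with pytest.raises(ValueError):
            parallel_resistance([])
        with pytest.raises(ValueError):
            total_compliance([])


class TestNominalWindkessels:
    def test_single_terminal(self):
        net = build_network([VesselSegment(id="v", length=2.0, radius=0.3)])
        wk = nominal_windkessels(net, r_total=500.0, c_total=1e-3, mu=0.03, p_out=6000.0)
        w = wk["v"]
        assert w.Rp == pytest.approx(250.0, rel=1e-12)
        assert w.Rd == pytest.approx(250.0, rel=1e-12)
        assert w.C == pytest.approx(1e-3, rel=1e-12)
        assert w.Pout == 6000.0

    def test_two_identical_terminals(self, three_vessel_net):
        net = three_vessel_net.with_segments(
            [VesselSegment(id="2", name="RPA", length=2.5, radius=0.42,
                           parent="0", is_extralobar=True)]
        )
        wk = nominal_windkessels(net, 500.0, 1e-3, 0.03, 6000.0)
        for tid in ("1", "2"):
            assert wk[tid].Rp + wk[tid].Rd == pytest.approx(1000.0, rel=1e-12)
            assert wk[tid].C == pytest.approx(5e-4, rel=1e-12)

    def test_asymmetric_ratio_and_total(self, three_vessel_net):
        net = three_vessel_net
        mu = 0.03
        path = {
            tid: sum(poiseuille_resistance(s, mu) for s in net.path_to_root(tid))
            for tid in ("1", "2")
        }
        r_total = 480.0
        wk = nominal_windkessels(net, r_total, 1e-3, mu, 6000.0)
        rt = {tid: wk[tid].Rp + wk[tid].Rd for tid in ("1", "2")}
        # hand-solved kappa for the 2-outlet case
        kappa = r_total * (1.0 / path["1"] + 1.0 / path["2"])
        for tid in ("1", "2"):
            assert rt[tid] == pytest.approx(kappa * path[tid], rel=1e-12)
        assert rt["1"] / rt["2"] == pytest.approx(path["1"] / path["2"], rel=1e-12)
        assert parallel_resistance(list(rt.values())) == pytest.approx(r_total, rel=1e-10)

    @pytest.mark.parametrize("generations", [1, 2, 3])
    def test_conserves_totals(self, generations):
        from pulmo1d.synthetic import generate_tree

        net = generate_tree(generations, asymmetry=0.15)
        r_total, c_total = 613.0, 7.7e-4
        wk = nominal_windkessels(net, r_total, c_total, 0.03, 6000.0)
        rts = [w.Rp + w.Rd for w in wk.values()]
        assert parallel_resistance(rts) == pytest.approx(r_total, rel=1e-10)
        assert sum(w.C for w in wk.values()) == pytest.approx(c_total, rel=1e-10)

    def test_distal_heavy_terminals_get_larger_rt(self):
        from pulmo1d.synthetic import generate_tree

        net = generate_tree(2, asymmetry=0.2)
        mu = 0.03
        wk = nominal_windkessels(net, 500.0, 1e-3, mu, 6000.0)
        path = {
            tid: sum(poiseuille_resistance(s, mu) for s in net.path_to_root(tid))
            for tid in wk
        }
        order_by_path = sorted(wk, key=lambda t: path[t])
        rts = [wk[t].Rp + wk[t].Rd for t in order_by_path]
        assert all(a < b for a, b in zip(rts, rts[1:]))

    def test_lung_split_matches_measured_flows(self):
        from pulmo1d.synthetic import generate_tree

        net = generate_tree(2)
        r_total, c_total = 500.0, 1e-3
        wk = nominal_windkessels_lung_split(
            net, r_total, c_total, 0.03, 6000.0, q_left_mean=10.0, q_right_mean=20.0
        )
        lpa_id, rpa_id = net.root.children
        left = net.subtree_ids(lpa_id)
        r_left = parallel_resistance([w.Rp + w.Rd for t, w in wk.items() if t in left])
        r_right = parallel_resistance(
            [w.Rp + w.Rd for t, w in wk.items() if t not in left]
        )
        # lung resistances inversely proportional to lung flows
        assert r_left / r_right == pytest.approx(2.0, rel=1e-10)
        assert parallel_resistance([w.Rp + w.Rd for w in wk.values()]) == pytest.approx(
            r_total, rel=1e-10
        )
        assert sum(w.C for w in wk.values()) == pytest.approx(c_total, rel=1e-10)

    def test_nonpositive_totals_rejected(self, three_vessel_net):
        with pytest.raises(ValueError):
            nominal_windkessels(three_vessel_net, -1.0, 1e-3, 0.03, 0.0)


class TestTypes:
    def test_windkessel_positivity(self):
        with pytest.raises(ValueError):
            Windkessel3(Rp=-1.0, Rd=1.0, C=1.0, Pout=0.0)

    def test_wall_positivity(self):
        with pytest.raises(ValueError):
            WallModel(stiffness=0.0, area_dia=1.0, p_dia=0.0)

    def test_summary_invariants(self):
        with pytest.raises(ValueError):
            HemodynamicSummary(
                p_sys=10.0, p_dia=15.0, a_sys=1.2, a_dia=1.0,
                p_wedge=5.0, q_mean=25.0, period=0.6, t_dia=0.4,
            )
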