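import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coaflow import (
    AortaNetwork,
    Junction,
    Outlet,
    SolverError,
    VesselSegment,
    allocate_outlet_resistances,
    run_resistance_sweep,
    segment_flow_from_dp,
    solve_steady_network,
)
from coaflow.flow import (
    DegenerateSegmentError,
    InvalidParameterError,
    OutletResistanceSet,
    read_sweep_csv,
    solve_steady_network_bruteforce,
    write_sweep_csv,
)
from coaflow.geometry import segment_viscous_coefficient

from conftest import make_chain_network, random_chain_network


class TestAllocation:
    def test_equal_diameters_split_evenly(self):
        rs = allocate_outlet_resistances([1.0, 1.0, 1.0, 1.0], 9.6)
        assert all(r == pytest.approx(38.4) for r in rs.resistances.values())

    def test_inverse_diameter_allocation(self):
        rs = allocate_outlet_resistances([2.0, 1.0], 9.6, exponent=1.0)
        vals = sorted(rs.resistances.values())
        assert vals == [pytest.approx(14.4), pytest.approx(28.8)]

    @given(st.lists(st.floats(0.2, 3.0), min_size=2, max_size=6),
           st.floats(0.5, 20.0), st.sampled_from([1.0, 2.0, 3.0]))
    @settings(max_examples=50, deadline=None)
    def test_parallel_recombination(self, diameters, total, exponent):
        rs = allocate_outlet_resistances(diameters, total, exponent)
        parallel = 1.0 / sum(1.0 / r for r in rs.resistances.values())
        assert parallel == pytest.approx(total, rel=1e-10)

    def test_murray_exponent_shifts_flow_to_large_outlets(self):
        lit = allocate_outlet_resistances({"big": 2.0, "small": 1.0}, 9.6, 1.0)
        murray = allocate_outlet_resistances({"big": 2.0, "small": 1.0}, 9.6, 3.0)
        assert murray.resistances["big"] < lit.resistances["big"]

    def test_rejects_bad_inputs(self):
        with pytest.raises(InvalidParameterError):
            allocate_outlet_resistances([1.0, -1.0], 9.6)
        with pytest.raises(InvalidParameterError):
            allocate_outlet_resistances([1.0, 1.0], 0.0)

    def test_resistance_set_consistency_enforced(self):
        with pytest.raises(InvalidParameterError):
            OutletResistanceSet({"a": 10.0, "b": 10.0}, total_resistance=9.6)


class TestElementLaw:
    @pytest.mark.parametrize("f,s,dp,expected", [
        (1.0, 1.0, 2.0, 1.0),
        (2.0, 0.0, 4.0, 2.0),
        (1.0, 1.0, 0.0, 0.0),
        (0.0, 2.0, 8.0, 2.0),
    ])
    def test_closed_form_inversion(self, f, s, dp, expected):
        assert segment_flow_from_dp(f, s, dp) == pytest.approx(expected, rel=1e-12)

    def test_zero_loss_with_pressure_drop_is_degenerate(self):
        with pytest.raises(DegenerateSegmentError):
            segment_flow_from_dp(0.0, 0.0, 1.0)

    @given(f=st.one_of(st.just(0.0), st.floats(1e-4, 5.0)),
           s=st.one_of(st.just(0.0), st.floats(1e-4, 5.0)),
           m=st.one_of(st.just(0.0), st.floats(1e-4, 2.0)),
           q=st.floats(0.01, 50.0))
    @settings(max_examples=100, deadline=None)
    def test_inversion_round_trip(self, f, s, m, q):
        if f + s + m == 0:
            return
        dp = f * q + s * q * q + m * q**1.75
        back = segment_flow_from_dp(f, s, dp, m)
        assert back == pytest.approx(q, rel=1e-9)


def single_path_network(throat=0.25, ref=0.5):
    return make_chain_network(
        radii=(ref,) * 5, lesion_throat_radius=throat,
        outlet_diameters=(1.0, 1.0, 1.0, 1.0))


class TestSteadySolver:
    def test_ohm_law_analog(self, fluid):
        # wide, short, lossless-in-practice chain with a single effective outlet
        net = make_chain_network(radii=(20.0,) * 5, lengths=(0.1,) * 5,
                                 lesion_throat_radius=20.0)
        rs = OutletResistanceSet(
            {"out0": 1e14, "out1": 1e14, "out2": 1e14, "out3": 9.6},
            total_resistance=1.0 / (3 / 1e14 + 1 / 9.6))
        sol = solve_steady_network(net, fluid, 80.0, rs)
        assert sol.segment_flows["seg0"] == pytest.approx(80 / 9.6, rel=1e-9)

    def test_quadratic_single_path_matches_closed_form(self, fluid):
        # lesion engineered so (f_true, s_true) = (1, 1); terminal R = 3:
        # Q^2 + 4Q = 80 has the positive root (-4 + sqrt(336)) / 2
        r_ref = 20.0
        a_ref = math.pi * r_ref**2
        a_min = 1.0 / (math.sqrt(2.0 / fluid.density) + 1.0 / a_ref)
        r_min = math.sqrt(a_min / math.pi)
        L = math.pi * r_min**4 / (8 * fluid.viscosity)
        eps = 1e-8
        length = eps + L
        lesion = VesselSegment(
            "lesion", length,
            [(0.0, r_ref), (eps, r_min), (length, r_min)],
            is_lesion=True, lesion_start=0.0, lesion_end=length)
        wide = lambda i: VesselSegment(f"w{i}", 0.1, [(0.0, 20.0), (0.1, 20.0)])
        net = AortaNetwork(
            segments=[lesion, wide(1), wide(2), wide(3)],
            junctions=[
                Junction("lesion", "w1", "o0"),
                Junction("w1", "w2", "o1"),
                Junction("w2", "w3", "o2"),
                Junction("w3", None, "o3"),
            ],
            outlets=[Outlet("o0", 1.0), Outlet("o1", 1.0), Outlet("o2", 1.0),
                     Outlet("o3", 1.0)],
            inlet_segment="lesion", diaphragm_diameter=2 * r_ref,
        )
        rs = OutletResistanceSet(
            {"o0": 1e14, "o1": 1e14, "o2": 1e14, "o3": 3.0},
            total_resistance=1.0 / (3 / 1e14 + 1 / 3.0))
        sol = solve_steady_network(net, fluid, 80.0, rs)
        expected = (-4.0 + math.sqrt(336.0)) / 2.0
        assert sol.lesion_flow == pytest.approx(expected, abs=1e-10)

    def test_symmetric_outlets_get_equal_flow(self, fluid):
        # zero-loss connecting segments: equal-resistance outlets see the
        # same pressure and must split the flow exactly
        net = make_chain_network(radii=(20.0,) * 5, lengths=(0.1,) * 5,
                                 lesion_throat_radius=20.0,
                                 outlet_diameters=(1.0, 1.0, 1.0, 1.0))
        rs = allocate_outlet_resistances(
            {f"out{i}": 1.0 for i in range(4)}, 9.6)
        sol = solve_steady_network(net, fluid, 80.0, rs)
        flows = list(sol.outlet_flows.values())
        assert all(f == pytest.approx(flows[0], rel=1e-10) for f in flows)

    def test_linear_network_matches_circuit_closed_form(self, fluid):
        # no expansion loss anywhere: solution is the linear nodal circuit,
        # assembled independently here from the Poiseuille conductances
        net = make_chain_network(lesion_throat_radius=0.5)  # s_true = 0
        rs = allocate_outlet_resistances(
            {o.id: o.diameter for o in net.outlets}, 9.6)
        sol = solve_steady_network(net, fluid, 80.0, rs)

        f_seg = [segment_viscous_coefficient(net.segment(f"seg{i}"), fluid)
                 for i in range(5)]
        g = [1 / f for f in f_seg]
        og = [1 / rs.resistances[f"out{i}"] for i in range(3)] \
            + [0.0, 1 / rs.resistances["out3"]]
        A = np.zeros((5, 5))
        b = np.zeros(5)
        for i in range(5):
            A[i, i] = g[i] + og[i] + (g[i + 1] if i + 1 < 5 else 0.0)
            if i > 0:
                A[i, i - 1] = -g[i]
                A[i - 1, i] = -g[i]
        b[0] = g[0] * 80.0
        p = np.linalg.solve(A, b)
        q0 = g[0] * (80.0 - p[0])
        assert sol.segment_flows["seg0"] == pytest.approx(q0, rel=1e-12)
        for i in range(5):
            assert sol.node_pressures[f"seg{i}"] == pytest.approx(p[i], rel=1e-12)

    def test_newton_agrees_with_bruteforce_oracle(self, fluid):
        rng = np.random.default_rng(20240131)
        worst = 0.0
        for _ in range(100):
            net = random_chain_network(rng)
            rs = allocate_outlet_resistances(
                {o.id: o.diameter for o in net.outlets},
                float(rng.uniform(1.0, 12.0)))
            ip = float(rng.uniform(60.0, 100.0))
            newton = solve_steady_network(net, fluid, ip, rs)
            oracle = solve_steady_network_bruteforce(net, fluid, ip, rs)
            for sid, q in newton.segment_flows.items():
                ref = oracle.segment_flows[sid]
                worst = max(worst, abs(q - ref) / max(abs(ref), 1e-12))
        assert worst < 1e-8

    def test_mass_conservation(self, fluid):
        rng = np.random.default_rng(7)
        for _ in range(20):
            net = random_chain_network(rng)
            rs = allocate_outlet_resistances(
                {o.id: o.diameter for o in net.outlets}, 9.6)
            sol = solve_steady_network(net, fluid, 80.0, rs)
            assert max(sol.mass_residuals().values()) < 1e-8

    def test_inlet_pressure_must_exceed_reference(self, fluid, chain_network):
        rs = allocate_outlet_resistances(
            {o.id: o.diameter for o in chain_network.outlets}, 9.6,
            reference_pressure=50.0)
        with pytest.raises(InvalidParameterError):
            solve_steady_network(chain_network, fluid, 40.0, rs)


class TestResistanceSweep:
    def test_default_sweep_has_six_increasing_flows(self, fluid, chain_network):
        sweep = run_resistance_sweep(chain_network, fluid)
        assert len(sweep.points) == 6
        assert sorted(p.scale for p in sweep.points) == sorted(
            [1, 1 / 2, 1 / 3, 1 / 4, 1 / 5, 1 / 6])
        flows = sweep.flows
        assert np.all(np.diff(flows) > 0)
        assert np.all(np.diff(sweep.pressure_drops) > 0)

    def test_total_inlet_flow_decreases_with_resistance(self, fluid, chain_network):
        rs = allocate_outlet_resistances(
            {o.id: o.diameter for o in chain_network.outlets}, 9.6)
        q = [solve_steady_network(chain_network, fluid, 80.0,
                                  rs.scaled(s)).segment_flows["seg0"]
             for s in (1.0, 0.5, 0.25)]
        assert q[0] < q[1] < q[2]

    def test_near_lossless_lesion_gives_negligible_drop(self, fluid):
        net = make_chain_network(radii=(5.0,) * 5, lesion_throat_radius=5.0)
        sweep = run_resistance_sweep(net, fluid)
        assert np.all(sweep.pressure_drops < 1e-5)

    def test_halving_base_resistance_equals_half_scale(self, fluid, chain_network):
        full = run_resistance_sweep(chain_network, fluid,
                                    base_total_resistance=9.6,
                                    scales=(1.0, 0.5))
        half = run_resistance_sweep(chain_network, fluid,
                                    base_total_resistance=4.8,
                                    scales=(1.0,))
        assert half.points[0].flow == pytest.approx(full.points[1].flow, rel=1e-10)

    def test_rejects_bad_scales(self, fluid, chain_network):
        with pytest.raises(InvalidParameterError):
            run_resistance_sweep(chain_network, fluid, scales=(1.0, 1.0))
        with pytest.raises(InvalidParameterError):
            run_resistance_sweep(chain_network, fluid, scales=(0.0, 0.5))

    def test_sweep_csv_round_trip(self, tmp_path, fluid, chain_network):
        sweep = run_resistance_sweep(chain_network, fluid)
        path = tmp_path / "sweep.csv"
        write_sweep_csv({"p001": sweep}, path)
        back = read_sweep_csv(path)["p001"]
        assert np.array_equal(back.flows, sweep.flows)
        assert np.array_equal(back.pressure_drops, sweep.pressure_drops)
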