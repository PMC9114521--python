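"""Hydraulic network: duct resistance, Kirchhoff solves, port behaviour."""

import numpy as np
import networkx as nx
import pytest

from depstretch import (
    ChannelSegment,
    DeviceGeometry,
    HydraulicNetwork,
    build_device_network,
    free_port,
    occupy_port,
    port_pressure_differences,
    rect_duct_resistance,
    release_flow_fraction,
    solve_capture_mode,
    solve_flows,
)
from depstretch.hydraulics import Edge, NetworkError, UL_PER_H


class TestDuctResistance:
    def test_thin_slot_limit(self):
        # h << w: correction factor -> 1, R -> 12 mu L / (w h^3)
        seg = ChannelSegment(width=10000.0, height=10.0, length=100.0)
        R = rect_duct_resistance(seg)
        slot = 12 * 1e-3 * 100e-6 / (10000e-6 * (10e-6) ** 3)
        assert R == pytest.approx(slot, rel=0.01)

    def test_symmetric_in_width_and_height(self):
        a = rect_duct_resistance(ChannelSegment(25.0, 100.0, 50.0))
        b = rect_duct_resistance(ChannelSegment(100.0, 25.0, 50.0))
        assert a == b

    def test_square_duct_vs_high_order_series_oracle(self):
        seg = ChannelSegment(25.0, 25.0, 100.0)
        assert rect_duct_resistance(seg, k_max=99) == pytest.approx(
            rect_duct_resistance(seg, k_max=9999), rel=1e-6
        )

    def test_monotone_in_length_and_viscosity(self):
        r1 = rect_duct_resistance(ChannelSegment(100, 25, 50))
        r2 = rect_duct_resistance(ChannelSegment(100, 25, 100))
        r3 = rect_duct_resistance(ChannelSegment(100, 25, 50), viscosity=2e-3)
        assert r2 > r1 and r3 > r1


def loop_flow_oracle(network, boundary):
    """Independent mesh-current-style solve: unknowns are edge flows,
    constraints are node conservation plus zero pressure drop around each
    cycle of a cycle basis; solved by least squares."""
    edges = network.edges
    g = nx.MultiGraph()
    for i, e in enumerate(edges):
        g.add_edge(e.a, e.b, key=i)
    nodes = list(network.nodes)
    rows, rhs = [], []
    # conservation at every node except one pressure reference (redundant)
    p_nodes = [n for n, v in boundary.items() if v[0] == "pressure"]
    for n in nodes:
        if n in p_nodes:
            continue
        row = np.zeros(len(edges))
        for i, e in enumerate(edges):
            if e.a == n:
                row[i] -= 1
            if e.b == n:
                row[i] += 1
        q = boundary.get(n, (None, 0.0))
        rows.append(row)
        rhs.append(-q[1] if q[0] == "flow" else 0.0)
    # voltage law around each basis cycle
    basis = nx.cycle_basis(nx.Graph(g))
    for cyc in basis:
        row = np.zeros(len(edges))
        for u, v in zip(cyc, cyc[1:] + cyc[:1]):
            for i, e in enumerate(edges):
                R = e.effective_resistance(network.block_multiplier)
                if (e.a, e.b) == (u, v):
                    row[i] += R
                elif (e.b, e.a) == (u, v):
                    row[i] -= R
        rows.append(row)
        rhs.append(0.0)
    # pressure-difference constraints between reference nodes via a path
    if len(p_nodes) > 1:
        for other in p_nodes[1:]:
            path = nx.shortest_path(nx.Graph(g), p_nodes[0], other)
            row = np.zeros(len(edges))
            for u, v in zip(path[:-1], path[1:]):
                for i, e in enumerate(edges):
                    R = e.effective_resistance(network.block_multiplier)
                    if (e.a, e.b) == (u, v):
                        row[i] += R
                    elif (e.b, e.a) == (u, v):
                        row[i] -= R
            rows.append(row)
            rhs.append(
                boundary[p_nodes[0]][1] - boundary[other][1]
            )
    A = np.array(rows)
    b = np.array(rhs)
    scale = np.abs(A).max(axis=1)
    sol, *_ = np.linalg.lstsq(A / scale[:, None], b / scale, rcond=None)
    return sol


class TestSolveFlows:
    def test_single_edge_ohm_analogy(self):
        net = HydraulicNetwork(
            nodes=["A", "B"], edges=[Edge("A", "B", 2.5e12, "e")],
            boundary_nodes=("A", "B"),
        )
        sol = solve_flows(net, {"A": ("flow", 1e-12), "B": ("pressure", 0.0)})
        assert sol.pressures["A"] == pytest.approx(1e-12 * 2.5e12)
        assert sol.flows[0] == pytest.approx(1e-12)

    def test_equal_parallel_edges_split_evenly(self):
        net = HydraulicNetwork(
            nodes=["A", "B"],
            edges=[Edge("A", "B", 1e12, "e1"), Edge("A", "B", 1e12, "e2")],
            boundary_nodes=("A", "B"),
        )
        sol = solve_flows(net, {"A": ("flow", 2e-12), "B": ("pressure", 0.0)})
        assert sol.flows[0] == pytest.approx(1e-12)
        assert sol.flows[1] == pytest.approx(1e-12)

    def test_against_loop_flow_oracle(self, rng):
        """Nodal solve vs. independent cycle-basis formulation."""
        nodes = ["A", "B", "C", "D", "E"]
        edges = [
            Edge("A", "B", float(rng.uniform(1, 10)) * 1e12, f"e{i}")
            for i in range(1)
        ]
        pairs = [("A", "B"), ("B", "C"), ("C", "D"), ("D", "E"), ("B", "D"), ("A", "C"), ("C", "E")]
        edges = [
            Edge(a, b, float(rng.uniform(1, 10)) * 1e12, f"e{i}")
            for i, (a, b) in enumerate(pairs)
        ]
        net = HydraulicNetwork(nodes=nodes, edges=edges, boundary_nodes=("A", "E"))
        boundary = {"A": ("flow", 3e-12), "E": ("pressure", 0.0)}
        sol = solve_flows(net, boundary)
        oracle = loop_flow_oracle(net, boundary)
        assert np.allclose(sol.flows, oracle, rtol=1e-9, atol=1e-21)

    def test_kirchhoff_residual_small(self):
        net = build_device_network()
        boundary = {"CI": ("flow", 3 * UL_PER_H), "RO": ("pressure", 0.0),
                    "WO": ("pressure", 0.0)}
        sol = solve_flows(net, boundary)
        assert sol.kirchhoff_residual(boundary) < 1e-10

    def test_disconnected_component_reported(self):
        net = HydraulicNetwork(
            nodes=["A", "B", "C", "D"],
            edges=[Edge("A", "B", 1e12, "e1"), Edge("C", "D", 1e12, "e2")],
            boundary_nodes=("A", "C"),
        )
        with pytest.raises(NetworkError, match="disconnected"):
            solve_flows(net, {"A": ("flow", 1e-12), "C": ("pressure", 0.0)})

    def test_missing_pressure_reference_rejected(self):
        net = HydraulicNetwork(
            nodes=["A", "B"], edges=[Edge("A", "B", 1e12, "e")],
            boundary_nodes=("A", "B"),
        )
        with pytest.raises(NetworkError, match="pressure"):
            solve_flows(net, {"A": ("flow", 1e-12)})


class TestDeviceNetwork:
    def test_default_device_has_twenty_open_ports(self):
        net = build_device_network()
        ports = net.port_edges
        assert len(ports) == 20
        assert not any(p.blocked for p in ports)

    def test_connected_for_any_blocked_subset(self, rng):
        net = build_device_network()
        for _ in range(10):
            k = int(rng.integers(0, 21))
            blocked = rng.choice(20, size=k, replace=False)
            g = nx.Graph()
            sub = net.copy()
            for i in blocked:
                sub = occupy_port(sub, int(i))
            # graph with blocked ports removed entirely still connects
            for e in sub.edges:
                if not (e.is_port and e.blocked):
                    g.add_edge(e.a, e.b)
            g.add_nodes_from(sub.nodes)
            assert nx.has_path(g, "CI", "WO")
            assert nx.has_path(g, "CI", "RO")

    def test_blocking_all_ports_leaves_only_end_junctions(self):
        net = build_device_network()
        g = nx.Graph()
        for e in net.edges:
            if not e.is_port:
                g.add_edge(e.a, e.b)
        # bypass chains reach the main channel only through J_out
        g.remove_node("J_out")
        assert not nx.has_path(g, "T1", "M1")

    def test_zero_ports_is_a_configuration_error(self):
        with pytest.raises(NetworkError):
            DeviceGeometry(n_ports_per_side=0)


class TestPortPressures:
    def test_symmetric_two_port_toy_equal_dp(self):
        net = build_device_network(DeviceGeometry(n_ports_per_side=1))
        sol = solve_capture_mode(net)
        dps = port_pressure_differences(sol)
        top = dps[dps.side == "top"].dp_pa.to_numpy()
        bot = dps[dps.side == "bottom"].dp_pa.to_numpy()
        assert top == pytest.approx(bot, rel=1e-9)

    def test_default_device_dp_decreasing_and_in_range(self):
        sol = solve_capture_mode(build_device_network(), 3 * UL_PER_H)
        top = port_pressure_differences(sol).query("side == 'top'").dp_pa.to_numpy()
        assert np.all(np.diff(top) < 0)
        assert 0.1 <= top[0] <= 10.0

    def test_dp_linear_in_flow(self):
        net = build_device_network()
        d1 = port_pressure_differences(solve_capture_mode(net, 3 * UL_PER_H))
        d2 = port_pressure_differences(solve_capture_mode(net, 6 * UL_PER_H))
        assert d2.dp_pa.to_numpy() == pytest.approx(
            2 * d1.dp_pa.to_numpy(), rel=1e-9
        )


class TestReleaseMode:
    def test_outlet_fractions_sum_to_one(self):
        net = build_device_network()
        from depstretch.hydraulics import solve_release_mode, UL_PER_MIN

        q = 150 * UL_PER_MIN
        sol = solve_release_mode(net, q)
        out_ro = sol.edge_flow("ro_branch")  # J_in -> RO
        out_wo = sol.edge_flow("wo_branch")  # J_out -> WO
        assert (out_ro + out_wo) / q == pytest.approx(1.0, rel=1e-9)

    def test_capture_area_fraction_small(self):
        frac = release_flow_fraction(build_device_network())
        assert 0.0 < frac < 0.5  # waste-outlet short circuit dominates

    def test_blocking_waste_outlet_sends_everything_through(self):
        net = build_device_network()
        for e in net.edges:
            if e.label == "wo_branch":
                e.resistance *= 1e12
        frac = release_flow_fraction(net)
        assert frac == pytest.approx(1.0, rel=1e-6)


class TestOccupyPort:
    @pytest.mark.parametrize("port", [0, 5, 14])
    def test_blocking_raises_dp_at_same_side_ports(self, port):
        """A captured cell diverts flow to the empty ports: re-solving
        shows every same-side port gains pressure difference (far
        opposite-side ports can shed a few percent to the outlet split,
        so the gain is not universal)."""
        net = build_device_network()
        base = port_pressure_differences(solve_capture_mode(net))
        blocked = occupy_port(net, port)
        after = port_pressure_differences(solve_capture_mode(blocked), blocked)
        merged = base.merge(after, on=["position", "side"], suffixes=("_a", "_b"))
        side = "top" if port < 10 else "bottom"
        same = merged[merged.side == side]
        assert (same.dp_pa_b > same.dp_pa_a).all()
        # aggregate driving pressure over open ports still rises
        assert merged.dp_pa_b.sum() > merged.dp_pa_a.sum()
        assert (merged.dp_pa_b / merged.dp_pa_a).min() > 0.9

    def test_block_unblock_round_trip(self):
        net = build_device_network()
        sol_before = solve_capture_mode(net)
        restored = free_port(occupy_port(net, 5), 5)
        sol_after = solve_capture_mode(restored)
        assert sol_after.pressures["CI"] == pytest.approx(
            sol_before.pressures["CI"], rel=1e-12
        )

    def test_double_block_warns_and_is_noop(self):
        net = occupy_port(build_device_network(), 3)
        with pytest.warns(UserWarning, match="already blocked"):
            net2 = occupy_port(net, 3)
        assert net2.port_edges[3].blocked

    def test_blocking_all_ports_stops_port_flow(self):
        net = build_device_network()
        for i in range(20):
            net.port_edges[i].blocked = True
        boundary = {"CI": ("flow", 3 * UL_PER_H), "RO": ("pressure", 0.0),
                    "WO": ("pressure", 0.0)}
        sol = solve_flows(net, boundary)
        port_q = [abs(q) for e, q in zip(net.edges, sol.flows) if e.is_port]
        assert max(port_q) < 1e-5 * 3 * UL_PER_H  # only the 1e-6 leak
        out = sol.edge_flow("ro_branch") + sol.edge_flow("wo_branch")
        assert out == pytest.approx(3 * UL_PER_H, rel=1e-9)
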