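"""Lumped hydraulic-resistance model of the single-cell trap-array chip.

In the Stokes regime a rectangular microchannel behaves like a resistor:
pressure drop = R * volumetric flow, with

    R = 12 mu L / (w h^3 [1 - sum_{k odd} (192 h)/(k^5 pi^5 w)
                                       tanh(k pi w / (2 h))])

(h <= w after swapping; series truncated at k = 99 by default).  The chip
is then a resistor network: a main channel with capture ports bridging to
two bypass channels, and four boundary ports — cell inlet (CI), release
outlet (RO) beside it, and buffer inlet (BI) / waste outlet (WO) at the
far end.  Each capture port is a wide (18 μm) and a narrow (6 μm) segment
in series; a captured cell blocks its port (an "open circuit", modelled
as a large resistance multiplier), diverting flow to the empty ports.

The bypass channels dead-end at the upstream side and rejoin the main
channel at the downstream junction, so in forward (capture) flow each
port carries a pressure difference that decreases strictly from the port
nearest the inlet to the last one — the behaviour that lets the first
ports capture preferentially without crushing cells.  In release mode the
buffer inlet feeds mostly the adjacent waste outlet; only a small
fraction of the flow re-enters the capture area.

Solved by nodal analysis (Kirchhoff current law), the exact analogue of
resistive-circuit analysis.  All user-facing lengths in μm; resistances
Pa·s/m^3, flows m^3/s, pressures Pa.
"""

from __future__ import annotations

import copy
import math
import warnings
from dataclasses import dataclass, field as dc_field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "ChannelSegment",
    "Edge",
    "HydraulicNetwork",
    "FlowSolution",
    "DeviceGeometry",
    "rect_duct_resistance",
    "build_device_network",
    "solve_flows",
    "solve_capture_mode",
    "solve_release_mode",
    "port_pressure_differences",
    "release_flow_fraction",
    "occupy_port",
    "free_port",
    "WATER_VISCOSITY",
    "UL_PER_H",
    "UL_PER_MIN",
]

#: Dynamic viscosity of water at room temperature, Pa·s.
WATER_VISCOSITY = 1.0e-3

#: 1 μL/h in m^3/s.
UL_PER_H = 1e-9 / 3600.0
#: 1 μL/min in m^3/s.
UL_PER_MIN = 1e-9 / 60.0

#: Resistance multiplier for a blocked ("open circuit") port.
DEFAULT_BLOCK_MULTIPLIER = 1e6


class NetworkError(ValueError):
    """Raised for unsolvable or ill-configured networks."""


@dataclass(frozen=True)
class ChannelSegment:
    """A straight rectangular duct: width/height/length in μm."""

    width: float
    height: float
    length: float
    label: str = ""

    def __post_init__(self) -> None:
        if min(self.width, self.height, self.length) <= 0:
            raise ValueError(f"segment dimensions must be > 0: {self}")


def rect_duct_resistance(
    seg: ChannelSegment, viscosity: float = WATER_VISCOSITY, k_max: int = 99
) -> float:
    """Hydraulic resistance of a rectangular duct, Pa·s/m^3.

    Symmetric in (width, height); the series correction uses h <= w.
    ``k_max`` is the last odd term kept (99 suffices for ~1e-9 accuracy at
    aspect ratio 1; the worst case).
    """
    w = max(self_w := seg.width, self_h := seg.height) * 1e-6
    h = min(self_w, self_h) * 1e-6
    L = seg.length * 1e-6
    ks = np.arange(1, k_max + 1, 2, dtype=float)
    series = np.sum(
        192.0 * h / (ks**5 * math.pi**5 * w) * np.tanh(ks * math.pi * w / (2.0 * h))
    )
    return 12.0 * viscosity * L / (w * h**3 * (1.0 - series))


@dataclass
class Edge:
    """A resistive connection between two nodes.

    ``resistance`` in Pa·s/m^3; ``is_port`` marks capture-port edges,
    which carry an open/blocked state.
    """

    a: str
    b: str
    resistance: float
    label: str = ""
    is_port: bool = False
    blocked: bool = False

    def __post_init__(self) -> None:
        if not self.resistance > 0:
            raise ValueError(f"edge {self.label or (self.a, self.b)}: R must be > 0")

    def effective_resistance(self, block_multiplier: float) -> float:
        return self.resistance * (block_multiplier if self.blocked else 1.0)


@dataclass
class HydraulicNetwork:
    """Resistor-network representation of the device."""

    nodes: list[str]
    edges: list[Edge]
    boundary_nodes: tuple[str, ...] = ("CI", "RO", "BI", "WO")
    block_multiplier: float = DEFAULT_BLOCK_MULTIPLIER

    def __post_init__(self) -> None:
        names = set(self.nodes)
        for e in self.edges:
            if e.a not in names or e.b not in names:
                raise NetworkError(f"edge {e.label} references unknown node")

    @property
    def port_edges(self) -> list[Edge]:
        """Capture-port edges in device order (nearest CI first, top side
        ports 0..n-1 then bottom side n..2n-1)."""
        return [e for e in self.edges if e.is_port]

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for e in self.edges:
            g.add_edge(e.a, e.b)
        return g

    def copy(self) -> "HydraulicNetwork":
        return copy.deepcopy(self)


@dataclass
class FlowSolution:
    """Node pressures (Pa) and signed edge flows (m^3/s, a -> b)."""

    pressures: dict[str, float]
    flows: list[float]
    network: HydraulicNetwork = dc_field(repr=False, default=None)

    def edge_flow(self, label: str) -> float:
        for e, q in zip(self.network.edges, self.flows):
            if e.label == label:
                return q
        raise KeyError(label)

    def kirchhoff_residual(self, boundary: dict) -> float:
        """Max |net flow| at nodes without a boundary condition, plus the
        inflow/outflow imbalance, as a fraction of total boundary inflow."""
        net = {n: 0.0 for n in self.network.nodes}
        for e, q in zip(self.network.edges, self.flows):
            net[e.a] -= q
            net[e.b] += q
        total_in = sum(
            abs(v[1]) for v in boundary.values() if v[0] == "flow"
        ) or 1.0
        interior = [abs(v) for n, v in net.items() if n not in boundary]
        imbalance = abs(sum(net.values()))
        return (max(interior, default=0.0) + imbalance) / total_in


def solve_flows(network: HydraulicNetwork, boundary: dict) -> FlowSolution:
    """Nodal-analysis solve of the resistor network.

    ``boundary`` maps node -> ("flow", Q m^3/s into the node) or
    ("pressure", p Pa).  Nodes absent from ``boundary`` are interior
    (sealed): zero net flow.  At least one pressure reference is required.
    """
    for n in boundary:
        if n not in network.nodes:
            raise NetworkError(f"boundary node {n!r} not in network")
    p_fixed = {n: v[1] for n, v in boundary.items() if v[0] == "pressure"}
    q_fixed = {n: v[1] for n, v in boundary.items() if v[0] == "flow"}
    if not p_fixed:
        raise NetworkError("need at least one pressure-reference node")

    # connectivity check: every boundary node must reach the references
    g = network.graph()
    comps = list(nx.connected_components(g))
    active = set(boundary)
    for comp in comps:
        touched = active & comp
        if touched and not (set(p_fixed) & comp):
            raise NetworkError(
                f"nodes {sorted(touched)} disconnected from any pressure "
                f"reference (component {sorted(comp)[:6]}...)"
            )

    unknown = [n for n in network.nodes if n not in p_fixed]
    index = {n: i for i, n in enumerate(unknown)}
    m = len(unknown)
    A = np.zeros((m, m))
    b = np.zeros(m)
    for e in network.edges:
        gcond = 1.0 / e.effective_resistance(network.block_multiplier)
        for u, v in ((e.a, e.b), (e.b, e.a)):
            if u in index:
                i = index[u]
                A[i, i] += gcond
                if v in index:
                    A[i, index[v]] -= gcond
                else:
                    b[i] += gcond * p_fixed[v]
    for n, q in q_fixed.items():
        if n in index:
            b[index[n]] += q
        # a node with both flow and pressure fixed is contradictory
        else:
            raise NetworkError(f"node {n!r} has both flow and pressure fixed")

    try:
        p_sol = np.linalg.solve(A, b)
    except np.linalg.LinAlgError as exc:
        raise NetworkError(f"singular nodal system: {exc}") from exc

    pressures = dict(p_fixed)
    pressures.update({n: float(p_sol[index[n]]) for n in unknown})
    flows = [
        (pressures[e.a] - pressures[e.b])
        / e.effective_resistance(network.block_multiplier)
        for e in network.edges
    ]
    return FlowSolution(pressures=pressures, flows=flows, network=network)


@dataclass(frozen=True)
class DeviceGeometry:
    """Default trap-array geometry; all lengths in μm.

    Channel widths/height and port sizes follow the chip design (100 μm
    main and bypass channels, 25 μm height, 10 ports per side at 100 μm
    pitch, ports narrowing from 18 μm to a 6 μm mouth).  Segment lengths
    outside the trap region are not printed anywhere and are defaults.
    """

    main_width: float = 100.0
    bypass_width: float = 100.0
    height: float = 25.0
    pitch: float = 100.0
    n_ports_per_side: int = 10
    port_narrow_width: float = 6.0
    port_narrow_length: float = 10.0
    port_wide_width: float = 18.0
    port_wide_length: float = 10.0
    inlet_length: float = 500.0      # CI -> inlet junction
    ro_branch_length: float = 1000.0  # inlet junction -> RO
    entrance_length: float = 100.0   # inlet junction -> first port node
    exit_length: float = 100.0       # last port node -> outlet junction
    bypass_exit_length: float = 100.0
    wo_branch_length: float = 300.0  # outlet junction -> WO
    bi_branch_length: float = 300.0  # outlet junction -> BI
    viscosity: float = WATER_VISCOSITY

    def __post_init__(self) -> None:
        if self.n_ports_per_side < 1:
            raise NetworkError("need at least one port per side")
        for name in (
            "main_width", "bypass_width", "height", "pitch",
            "port_narrow_width", "port_narrow_length", "port_wide_width",
            "port_wide_length", "inlet_length", "ro_branch_length",
            "entrance_length", "exit_length", "bypass_exit_length",
            "wo_branch_length", "bi_branch_length", "viscosity",
        ):
            if not getattr(self, name) > 0:
                raise NetworkError(f"geometry field {name} must be > 0")


def build_device_network(geom: DeviceGeometry | None = None) -> HydraulicNetwork:
    """Assemble the ladder network of the trap-array device.

    Nodes: CI, RO, BI, WO boundaries; J_in / J_out junctions; main-channel
    nodes M1..Mn at the port positions; bypass nodes T1..Tn (top) and
    C1..Cn (bottom).  Port i bridges M_i to T_i and to C_i; bypasses
    dead-end upstream and rejoin at J_out.
    """
    geom = geom or DeviceGeometry()
    mu = geom.viscosity
    n = geom.n_ports_per_side

    def R(width, length, label=""):
        return rect_duct_resistance(
            ChannelSegment(width, geom.height, length, label), viscosity=mu
        )

    r_port = R(geom.port_wide_width, geom.port_wide_length) + R(
        geom.port_narrow_width, geom.port_narrow_length
    )

    nodes = ["CI", "RO", "BI", "WO", "J_in", "J_out"]
    nodes += [f"M{i}" for i in range(1, n + 1)]
    nodes += [f"T{i}" for i in range(1, n + 1)]
    nodes += [f"C{i}" for i in range(1, n + 1)]

    edges = [
        Edge("CI", "J_in", R(geom.main_width, geom.inlet_length), "inlet"),
        Edge("J_in", "RO", R(geom.main_width, geom.ro_branch_length), "ro_branch"),
        Edge("J_in", "M1", R(geom.main_width, geom.entrance_length), "main_0"),
    ]
    for i in range(1, n):
        edges.append(
            Edge(f"M{i}", f"M{i+1}", R(geom.main_width, geom.pitch), f"main_{i}")
        )
    edges.append(
        Edge(f"M{n}", "J_out", R(geom.main_width, geom.exit_length), "main_exit")
    )
    for side, prefix in (("top", "T"), ("bottom", "C")):
        for i in range(1, n):
            edges.append(
                Edge(
                    f"{prefix}{i}", f"{prefix}{i+1}",
                    R(geom.bypass_width, geom.pitch), f"bypass_{side}_{i}",
                )
            )
        edges.append(
            Edge(
                f"{prefix}{n}", "J_out",
                R(geom.bypass_width, geom.bypass_exit_length),
                f"bypass_{side}_exit",
            )
        )
    # port edges: top side 0..n-1 (nearest CI first), then bottom n..2n-1
    for prefix, side in (("T", "top"), ("C", "bottom")):
        for i in range(1, n + 1):
            edges.append(
                Edge(
                    f"M{i}", f"{prefix}{i}", r_port,
                    f"port_{side}_{i}", is_port=True,
                )
            )
    edges.append(Edge("J_out", "WO", R(geom.main_width, geom.wo_branch_length), "wo_branch"))
    edges.append(Edge("J_out", "BI", R(geom.main_width, geom.bi_branch_length), "bi_branch"))

    return HydraulicNetwork(nodes=nodes, edges=edges)


def solve_capture_mode(
    network: HydraulicNetwork, flow_m3s: float = 3.0 * UL_PER_H
) -> FlowSolution:
    """Forward capture flow: inflow at CI, RO and WO open at 0 Pa."""
    return solve_flows(
        network,
        {"CI": ("flow", flow_m3s), "RO": ("pressure", 0.0), "WO": ("pressure", 0.0)},
    )


def solve_release_mode(
    network: HydraulicNetwork, flow_m3s: float = 150.0 * UL_PER_MIN
) -> FlowSolution:
    """Reverse release flow: inflow at BI, RO and WO open at 0 Pa."""
    return solve_flows(
        network,
        {"BI": ("flow", flow_m3s), "RO": ("pressure", 0.0), "WO": ("pressure", 0.0)},
    )


def port_pressure_differences(
    sol: FlowSolution, network: HydraulicNetwork | None = None
) -> pd.DataFrame:
    """Pressure difference across each open capture port.

    One row per open port, ordered from the port nearest CI to the last,
    top side then bottom: columns position (1-based), side, dp_pa (main
    minus bypass side).  In forward capture flow with all ports open the
    per-position sequence decreases strictly along the channel.
    """
    network = network or sol.network
    rows = []
    for e in network.port_edges:
        if e.blocked:
            continue
        _, side, pos = e.label.split("_")
        rows.append(
            {
                "position": int(pos),
                "side": side,
                "dp_pa": sol.pressures[e.a] - sol.pressures[e.b],
            }
        )
    return pd.DataFrame(rows).sort_values(["side", "position"], ascending=[False, True]).reset_index(drop=True)


def release_flow_fraction(
    network: HydraulicNetwork, flow_m3s: float = 150.0 * UL_PER_MIN
) -> float:
    """Fraction of the buffer-inlet flow that re-enters the capture area.

    Solves release mode (inflow BI, outlets RO and WO) and measures the
    flow leaving the outlet junction into the trap region (main channel
    and both bypasses) relative to the BI inflow.  The waste outlet sits
    next to the buffer inlet, so this fraction is well below one.
    """
    sol = solve_release_mode(network, flow_m3s)
    into_capture = 0.0
    for label, sign in (
        ("main_exit", -1.0),        # edge Mn -> J_out; negative flow = into trap
        ("bypass_top_exit", -1.0),
        ("bypass_bottom_exit", -1.0),
    ):
        into_capture += sign * sol.edge_flow(label)
    return into_capture / flow_m3s


def occupy_port(network: HydraulicNetwork, port_index: int) -> HydraulicNetwork:
    """Return a copy of the network with capture port ``port_index`` blocked.

    Index 0..(2n-1) over :attr:`HydraulicNetwork.port_edges`.  Blocking a
    port multiplies its resistance by the network's ``block_multiplier``
    (an effective open circuit; real cells seal imperfectly, so the
    multiplier is configurable).  Blocking an already-blocked port warns
    and returns an unchanged copy.
    """
    new = network.copy()
    ports = new.port_edges
    if not 0 <= port_index < len(ports):
        raise IndexError(f"port index {port_index} out of range 0..{len(ports)-1}")
    if ports[port_index].blocked:
        warnings.warn(f"port {port_index} already blocked; no-op", stacklevel=2)
        return new
    ports[port_index].blocked = True
    return new


def free_port(network: HydraulicNetwork, port_index: int) -> HydraulicNetwork:
    """Inverse of :func:`occupy_port`: unblock a port (copying)."""
    new = network.copy()
    ports = new.port_edges
    if not 0 <= port_index < len(ports):
        raise IndexError(f"port index {port_index} out of range 0..{len(ports)-1}")
    if not ports[port_index].blocked:
        warnings.warn(f"port {port_index} already open; no-op", stacklevel=2)
        return new
    ports[port_index].blocked = False
    return new
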