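"""The plate-rod network graph: junctions, terminals, max flow, weighted BV/TV.

Elements are nodes. A voxel is a junction voxel if it belongs to one element
and any of its 26 neighbors belongs to a different element, so junction
surfaces are two voxels thick (both sides marked). Every touching element
pair becomes an undirected edge. Artificial unbounded-capacity super-nodes
``s`` and ``t`` collect the elements on the proximal surface inside the
plunger footprint (sources) and on the distal surface (sink). The maximum
s-t flow then identifies the elements that participate in load transfer
between the platens, and the weighted bone volume fraction is the BV/TV
restricted to those load-bearing elements.

The graph is "unweighted" in the sense that element-element edges carry unit
capacity by default; ``capacity="area"`` uses the junction voxel count
instead for sensitivity studies.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .decompose import ElementMap, _shifted
from .volume import SpecimenMask

__all__ = [
    "JunctionSet",
    "LoadCase",
    "FlowResult",
    "find_junctions",
    "build_graph",
    "attach_terminals",
    "max_flow",
    "load_bearing",
    "weighted_bvtv",
]

_HALF_OFFSETS = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
]

SOURCE = "s"
SINK = "t"


@dataclass
class JunctionSet:
    """Per element pair (a < b): junction voxels (both sides) and their count."""

    voxels: dict[tuple[int, int], np.ndarray]  # pair -> (n, 3) voxel coordinates

    def count(self, a: int, b: int) -> int:
        key = (min(a, b), max(a, b))
        return len(self.voxels.get(key, ()))

    @property
    def pairs(self) -> list[tuple[int, int]]:
        return sorted(self.voxels)


@dataclass
class LoadCase:
    """Compression loading: plunger footprint, distal support, applied strain.

    ``plunger_diameter`` (mm) bounds the proximal source footprint; ``None``
    loads the full proximal surface. The distal sink defaults to the full
    distal surface; set ``distal_diameter`` for a symmetric plunger setup.
    """

    plunger_diameter: float | None = None  # mm
    distal_diameter: float | None = None  # mm
    strain: float = 0.01

    def __post_init__(self) -> None:
        if self.strain < 0:
            raise ValueError("applied strain must be >= 0")

    def footprint(self, shape, spacing: float, diameter: float | None) -> np.ndarray:
        """Boolean in-plane footprint (axes 0, 1), centered on the grid."""
        nx_, ny_ = shape[0], shape[1]
        if diameter is None:
            return np.ones((nx_, ny_), bool)
        r_vox = diameter * 1000.0 / spacing / 2.0
        cx, cy = nx_ / 2.0, ny_ / 2.0
        x = np.arange(nx_) + 0.5
        y = np.arange(ny_) + 0.5
        return (x[:, None] - cx) ** 2 + (y[None, :] - cy) ** 2 <= r_vox**2


@dataclass
class FlowResult:
    """Maximum-flow solution over the PR graph."""

    value: float
    edge_flows: dict[tuple, float]  # undirected net |flow| per edge
    throughput: dict[int, float]  # per element: sum of incident flows / 2
    load_bearing: set[int]
    mode: str  # "flow" | "reach"

    def __post_init__(self) -> None:
        self.load_bearing = {e for e in self.load_bearing if e not in (SOURCE, SINK)}


def find_junctions(em: ElementMap) -> JunctionSet:
    """Enumerate junction voxels for every touching element pair (both sides)."""
    lab = em.labels
    pair_voxels: dict[tuple[int, int], set] = {}
    for off in _HALF_OFFSETS:
        sh = _shifted(lab, off)
        touch = (lab > 0) & (sh > 0) & (lab != sh)
        if not touch.any():
            continue
        coords = np.argwhere(touch)
        a = lab[touch]
        b = sh[touch]
        for (x, y, z), la, lb in zip(coords, a, b):
            key = (int(min(la, lb)), int(max(la, lb)))
            s = pair_voxels.setdefault(key, set())
            s.add((int(x), int(y), int(z)))  # this side
            s.add((int(x + off[0]), int(y + off[1]), int(z + off[2])))  # partner side
    return JunctionSet(
        {k: np.array(sorted(v), np.int64) for k, v in sorted(pair_voxels.items())}
    )


def build_graph(
    em: ElementMap, j: JunctionSet, capacity: str = "unit", min_contact: int = 1
) -> nx.Graph:
    """Element nodes + one edge per touching pair, with the capacity model.

    ``capacity="unit"`` gives every element-element edge capacity 1 (the
    unweighted reading); ``"area"`` uses the junction voxel count.
    ``min_contact`` drops pairs whose two-sided junction surface is smaller
    than that many voxels: label regrowth around removed junction
    neighborhoods can put two elements in sub-strut-scale contact that the
    geometry does not support, and such contacts are not load paths.
    """
    if capacity not in ("unit", "area"):
        raise ValueError("capacity must be 'unit' or 'area'")
    g = nx.Graph()
    for _, row in em.table.iterrows():
        g.add_node(
            int(row["id"]),
            kind=row["type"],
            voxels=int(row["voxels"]),
        )
    for (a, b), vox in j.voxels.items():
        if len(vox) < min_contact:
            continue
        cap = 1.0 if capacity == "unit" else float(len(vox))
        g.add_edge(a, b, capacity=cap, junction_voxels=int(len(vox)))
    return g


def attach_terminals(
    g: nx.Graph, em: ElementMap, lc: LoadCase, mask: SpecimenMask | None = None
) -> nx.Graph:
    """Connect super-source s (proximal footprint) and super-sink t (distal).

    s connects with unbounded capacity to every element owning at least one
    foreground voxel in the proximal surface slice inside the plunger
    footprint; t likewise on the distal surface. Elements outside the plunger
    footprint are not sources — this is what produces convex/hourglass
    load-transfer patterns for small plungers.
    """
    g = g.copy()
    lab = em.labels
    fg = lab > 0
    if mask is not None:
        fg = fg & mask.data
    zs = np.where(fg.any(axis=(0, 1)))[0]
    g.add_node(SOURCE)
    g.add_node(SINK)
    if len(zs) == 0:
        return g
    z_min, z_max = int(zs[0]), int(zs[-1])
    prox_fp = lc.footprint(lab.shape, em.spacing, lc.plunger_diameter)
    dist_fp = lc.footprint(lab.shape, em.spacing, lc.distal_diameter)
    sources = np.unique(lab[:, :, z_min][prox_fp & fg[:, :, z_min]])
    sinks = np.unique(lab[:, :, z_max][dist_fp & fg[:, :, z_max]])
    # terminal edges are effectively unbounded: one more than the total
    # finite capacity can never be the bottleneck, yet keeps the flow value
    # finite even when one element touches both platens directly
    big = 1.0 + sum(d.get("capacity", 0.0) for _, _, d in g.edges(data=True))
    for e in sources:
        if int(e) in g:
            g.add_edge(SOURCE, int(e), capacity=big)
    for e in sinks:
        if int(e) in g:
            g.add_edge(SINK, int(e), capacity=big)
    return g


def max_flow(g: nx.Graph, mode: str = "flow") -> FlowResult:
    """Maximum s-t flow over the PR graph with terminals attached.

    Any max-flow algorithm is acceptable; the contract is the max-flow /
    min-cut value plus a feasible flow. ``mode`` controls how the
    load-bearing set is derived (see :func:`load_bearing`).
    """
    if SOURCE not in g or SINK not in g:
        raise ValueError("terminals s and t must be attached before max_flow")
    if g.degree(SOURCE) == 0 or g.degree(SINK) == 0:
        return FlowResult(0.0, {}, {n: 0.0 for n in g if n not in (SOURCE, SINK)}, set(), mode)
    value, flow = nx.maximum_flow(g, SOURCE, SINK)
    edge_flows: dict[tuple, float] = {}
    throughput: dict = {n: 0.0 for n in g}
    for u, v in g.edges():
        net = abs(flow[u][v] - flow[v][u])
        edge_flows[(u, v)] = net
        throughput[u] += net
        throughput[v] += net
    throughput = {
        n: t / 2.0 for n, t in throughput.items() if n not in (SOURCE, SINK)
    }
    if mode == "flow":
        lb = {n for n, t in throughput.items() if t > 1e-12}
    elif mode == "reach":
        lb = _reachable_both(g)
    else:
        raise ValueError("mode must be 'flow' or 'reach'")
    return FlowResult(float(value), edge_flows, throughput, lb, mode)


def _reachable_both(g: nx.Graph) -> set:
    """Elements lying on at least one simple s-t path.

    A node is on a simple s-t path iff it shares a cycle with the edge (s, t)
    in the graph augmented by that edge, i.e. belongs to the biconnected
    component containing both terminals. Dangling elements (reachable from s
    only back through the same cut) are excluded, parallel load paths are
    all included — independent of how a maximum flow happens to route.
    """
    if SOURCE not in g or SINK not in g:
        return set()
    ga = g.copy()
    ga.add_edge(SOURCE, SINK)
    for comp in nx.biconnected_components(ga):
        if SOURCE in comp and SINK in comp:
            return {n for n in comp if n not in (SOURCE, SINK)}
    return set()


def load_bearing(fr: FlowResult, g: nx.Graph | None = None) -> set[int]:
    """Element ids identified as load-bearing.

    Default ("flow") mode: elements with positive throughput in the computed
    maximum flow. "reach" mode: elements graph-connected to both terminals
    (unit-capacity flows can leave genuinely connected parallel elements at
    zero flow). The mode is recorded on the FlowResult.
    """
    return set(fr.load_bearing)


def weighted_bvtv(em: ElementMap, lb: set[int], m: SpecimenMask) -> float:
    """Connectivity-weighted bone volume fraction.

    Volume of the load-bearing elements over the total mask volume; by
    construction bounded above by the plain BV/TV.
    """
    tv = m.count()
    if tv == 0:
        raise ValueError("empty mask: weighted BV/TV undefined")
    if not lb:
        return 0.0
    bone = np.isin(em.labels, sorted(lb)) & m.data
    return float(np.count_nonzero(bone)) / tv
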