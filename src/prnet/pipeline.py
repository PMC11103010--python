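"""End-to-end plate-rod network analysis of one specimen volume."""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .decompose import ClassifiedSkeleton, DecomposeParams, ElementMap, decompose
from .prgraph import (
    FlowResult,
    LoadCase,
    attach_terminals,
    build_graph,
    find_junctions,
    max_flow,
    weighted_bvtv,
)
from .volume import (
    BinaryVolume,
    DensityVolume,
    PreprocessParams,
    SpecimenMask,
    bvtv,
    preprocess,
)

__all__ = ["PRNetworkResult", "run_pr_network"]


@dataclass
class PRNetworkResult:
    """Everything one pipeline run produces."""

    binary: BinaryVolume
    mask: SpecimenMask
    skeleton: ClassifiedSkeleton
    element_map: ElementMap
    graph: nx.Graph
    flow: FlowResult
    bvtv: float
    weighted_bvtv: float


def run_pr_network(
    v: DensityVolume | BinaryVolume,
    mask: SpecimenMask,
    load_case: LoadCase | None = None,
    preprocess_params: PreprocessParams | None = None,
    decompose_params: DecomposeParams | None = None,
    capacity: str = "unit",
    mode: str = "reach",
    min_contact: int = 8,
) -> PRNetworkResult:
    """Preprocess, decompose, build the network, run max flow, weight BV/TV.

    The pipeline defaults to ``mode="reach"`` for the load-bearing set (an
    element is load-bearing iff it lies on some source-sink path): volume
    weighting should not depend on how a unit-capacity maximum flow happens
    to route among parallel paths. ``mode="flow"`` restricts the set to
    elements with positive throughput in the computed flow.
    """
    load_case = load_case or LoadCase()
    if isinstance(v, DensityVolume):
        b = preprocess(v, preprocess_params)
    else:
        b = v
    # the TV mask defines the specimen region; clip stray foreground (noise)
    b = BinaryVolume(b.data & mask.data, b.spacing)
    mask.pair_check(b)
    em, cs = decompose(b, decompose_params)
    g = build_graph(em, find_junctions(em), capacity=capacity, min_contact=min_contact)
    gt = attach_terminals(g, em, load_case, mask)
    fr = max_flow(gt, mode=mode)
    plain = bvtv(b, mask)
    weighted = weighted_bvtv(em, fr.load_bearing, mask)
    return PRNetworkResult(b, mask, cs, em, g, fr, plain, weighted)
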