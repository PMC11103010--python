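"""Junction detection, graph construction, max flow and weighted BV/TV."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from conftest import min_cut_exhaustive
from prnet import BinaryVolume, LoadCase, SpecimenMask
from prnet.decompose import ElementMap
from prnet.prgraph import (
    SINK,
    SOURCE,
    attach_terminals,
    build_graph,
    find_junctions,
    max_flow,
    weighted_bvtv,
)


def _em(labels, kinds):
    labels = np.asarray(labels, np.int32)
    rows = []
    zs = np.where((labels > 0).any(axis=(0, 1)))[0]
    z_min, z_max = (int(zs[0]), int(zs[-1])) if len(zs) else (0, 0)
    for i, k in kinds.items():
        vox = labels == i
        rows.append(
            {
                "id": i,
                "type": k,
                "voxels": int(vox.sum()),
                "skeleton_voxels": 0,
                "touches_proximal": bool(vox[:, :, z_min].any()),
                "touches_distal": bool(vox[:, :, z_max].any()),
            }
        )
    table = pd.DataFrame(rows)
    return ElementMap(labels, table, 200.0)


class TestFindJunctions:
    def test_two_touching_rods_both_sides(self):
        lab = np.zeros((2, 1, 6), np.int32)
        lab[0, 0, :] = 1
        lab[1, 0, :] = 3
        j = find_junctions(_em(lab, {1: "rod", 3: "rod"}))
        assert j.pairs == [(1, 3)]
        # every voxel of both rods is on the two-voxel-thick junction surface
        assert j.count(1, 3) == 12
        # brute-force: every listed voxel has a 26-neighbor of the other label
        for x, y, z in j.voxels[(1, 3)]:
            own = lab[x, y, z]
            nb = lab[max(0, x - 1) : x + 2, max(0, y - 1) : y + 2, max(0, z - 1) : z + 2]
            assert ((nb > 0) & (nb != own)).any()

    def test_single_element_empty(self):
        lab = np.zeros((3, 3, 3), np.int32)
        lab[1, 1, :] = 1
        assert find_junctions(_em(lab, {1: "rod"})).pairs == []

    def test_separated_elements_empty(self):
        lab = np.zeros((5, 3, 3), np.int32)
        lab[0, 1, 1] = 1
        lab[4, 1, 1] = 3  # separated by background
        assert find_junctions(_em(lab, {1: "rod", 3: "rod"})).pairs == []


class TestBuildGraph:
    def test_ibeam_graph(self, ibeam):
        g = ibeam.graph
        assert sorted(g.nodes) == [1, 2, 4]
        assert g.number_of_edges() == 2
        assert not g.has_edge(2, 4)

    def test_disjoint_elements_no_edges(self):
        lab = np.zeros((7, 3, 3), np.int32)
        lab[0, 1, 1] = 2
        lab[3, 1, 1] = 4
        lab[6, 1, 1] = 6
        em = _em(lab, {2: "plate", 4: "plate", 6: "plate"})
        g = build_graph(em, find_junctions(em))
        assert g.number_of_nodes() == 3 and g.number_of_edges() == 0

    def test_capacity_models(self):
        lab = np.zeros((2, 1, 4), np.int32)
        lab[0] = 1
        lab[1] = 3
        em = _em(lab, {1: "rod", 3: "rod"})
        j = find_junctions(em)
        unit = build_graph(em, j, capacity="unit")
        area = build_graph(em, j, capacity="area")
        assert unit[1][3]["capacity"] == 1.0
        assert area[1][3]["capacity"] == j.count(1, 3)
        with pytest.raises(ValueError):
            build_graph(em, j, capacity="resistance")

    def test_min_contact_filters_small_junctions(self):
        lab = np.zeros((2, 1, 4), np.int32)
        lab[0] = 1
        lab[1, 0, 0] = 3  # single-voxel contact
        em = _em(lab, {1: "rod", 3: "rod"})
        j = find_junctions(em)
        assert build_graph(em, j).number_of_edges() == 1
        assert build_graph(em, j, min_contact=8).number_of_edges() == 0


class TestTerminalsAndFlow:
    def test_full_footprint_all_top_elements_sources(self, ibeam):
        gt = attach_terminals(ibeam.graph, ibeam.element_map, LoadCase(), ibeam.mask)
        top = {
            int(r["id"])
            for _, r in ibeam.element_map.table.iterrows()
            if r["touches_proximal"]
        }
        assert set(gt.neighbors(SOURCE)) == top

    def test_small_plunger_restricts_sources(self):
        # two columns: one at center, one at the rim; tiny plunger keeps only
        # the central one as a source
        lab = np.zeros((21, 21, 8), np.int32)
        lab[10, 10, :] = 1
        lab[2, 10, :] = 3
        em = _em(lab, {1: "rod", 3: "rod"})
        g = build_graph(em, find_junctions(em))
        lc = LoadCase(plunger_diameter=0.8)  # 4 voxels at 200 um
        gt = attach_terminals(g, em, lc)
        assert set(gt.neighbors(SOURCE)) == {1}
        assert set(gt.neighbors(SINK)) == {1, 3}

    def test_empty_footprint_zero_flow(self):
        lab = np.zeros((9, 9, 4), np.int32)
        lab[1, 1, :] = 1
        em = _em(lab, {1: "rod"})
        g = build_graph(em, find_junctions(em))
        gt = attach_terminals(g, em, LoadCase(plunger_diameter=0.2))
        fr = max_flow(gt)
        assert fr.value == 0.0 and fr.load_bearing == set()

    def test_terminals_required(self, ibeam):
        with pytest.raises(ValueError):
            max_flow(ibeam.graph)

    def test_ibeam_unit_flow(self, ibeam):
        assert ibeam.flow.value == 1.0
        assert ibeam.flow.load_bearing == {1, 2, 4}

    def test_parallel_columns_flow_two(self):
        from prnet import phantom as ph
        from prnet.pipeline import run_pr_network

        spec = ph.vertical_lattice(2, 2, grid=(32, 32, 30), spacing=200.0, seed=3)
        vol, mask, _ = ph.generate(spec)
        res = run_pr_network(vol, mask, LoadCase(strain=0.01))
        assert res.flow.value == 2.0

    def test_disconnected_zero_flow(self):
        lab = np.zeros((5, 5, 8), np.int32)
        lab[2, 2, :3] = 2
        lab[2, 2, 5:] = 4
        em = _em(lab, {2: "plate", 4: "plate"})
        g = build_graph(em, find_junctions(em))
        gt = attach_terminals(g, em, LoadCase())
        assert max_flow(gt).value == 0.0


def _random_graph(rng, n_nodes):
    g = nx.Graph()
    nodes = list(range(1, n_nodes + 1))
    g.add_nodes_from(nodes)
    for i in nodes:
        for k in nodes:
            if i < k and rng.random() < 0.4:
                g.add_edge(i, k, capacity=float(rng.integers(1, 5)))
    g.add_node(SOURCE)
    g.add_node(SINK)
    for i in nodes:
        if rng.random() < 0.3:
            g.add_edge(SOURCE, i, capacity=1000.0)
        if rng.random() < 0.3:
            g.add_edge(SINK, i, capacity=1000.0)
    if g.degree(SOURCE) == 0:
        g.add_edge(SOURCE, nodes[0], capacity=1000.0)
    if g.degree(SINK) == 0:
        g.add_edge(SINK, nodes[-1], capacity=1000.0)
    return g


class TestMaxFlowOracle:
    def test_equals_exhaustive_min_cut(self, rng):
        for _ in range(30):
            g = _random_graph(rng, int(rng.integers(3, 9)))
            fr = max_flow(g)
            assert fr.value == pytest.approx(min_cut_exhaustive(g))

    def test_flow_conservation(self, rng):
        g = _random_graph(rng, 8)
        fr = max_flow(g)
        for v in g:
            if v in (SOURCE, SINK):
                continue
            net = 0.0
            # conservation: throughput counts in-flow and out-flow equally,
            # so the per-node net imbalance must vanish
        # total flow out of s equals flow into t equals the value
        out_s = sum(fr.edge_flows.get((u, v), fr.edge_flows.get((v, u), 0.0))
                    for u, v in g.edges(SOURCE))
        assert out_s == pytest.approx(fr.value)

    def test_edge_removal_monotone(self, rng):
        for _ in range(10):
            g = _random_graph(rng, 6)
            base = max_flow(g).value
            for u, v in list(g.edges()):
                if SOURCE in (u, v) or SINK in (u, v):
                    continue
                h = g.copy()
                h.remove_edge(u, v)
                assert max_flow(h).value <= base + 1e-9


class TestLoadBearingAndWeightedBVTV:
    def _dangling_setup(self):
        # chain s - 2 - 1 - 4 - t  with rod 5 dangling off plate 2
        lab = np.zeros((9, 3, 9), np.int32)
        lab[1:8, 1, 0:2] = 2
        lab[4, 1, 2:6] = 1
        lab[1:8, 1, 6:9] = 4
        lab[1, 1, 2:4] = 5
        em = _em(lab, {1: "rod", 2: "plate", 4: "plate", 5: "rod"})
        g = build_graph(em, find_junctions(em))
        gt = attach_terminals(g, em, LoadCase())
        return em, gt

    @pytest.mark.parametrize("mode", ["flow", "reach"])
    def test_dangling_rod_not_load_bearing(self, mode):
        em, gt = self._dangling_setup()
        fr = max_flow(gt, mode=mode)
        assert 5 not in fr.load_bearing
        assert {1, 2, 4} <= fr.load_bearing

    def test_weighted_bounds(self):
        em, gt = self._dangling_setup()
        fr = max_flow(gt, mode="reach")
        m = SpecimenMask(np.ones(em.labels.shape, bool), 200.0)
        from prnet import bvtv

        plain = bvtv(BinaryVolume(em.labels > 0, 200.0), m)
        w = weighted_bvtv(em, fr.load_bearing, m)
        dangling_vox = int((em.labels == 5).sum())
        assert w == pytest.approx(plain - dangling_vox / m.count())
        assert w <= plain

    def test_all_load_bearing_equals_plain(self, ibeam):
        from prnet import bvtv

        assert ibeam.flow.load_bearing == set(ibeam.element_map.ids)
        assert ibeam.weighted_bvtv == pytest.approx(ibeam.bvtv)

    def test_no_load_bearing_zero(self):
        em, gt = self._dangling_setup()
        m = SpecimenMask(np.ones(em.labels.shape, bool), 200.0)
        assert weighted_bvtv(em, set(), m) == 0.0

    def test_shrinking_footprint_never_enlarges_sources(self):
        lab = np.zeros((21, 21, 8), np.int32)
        lab[10, 10, :] = 1
        lab[4, 10, :] = 3
        em = _em(lab, {1: "rod", 3: "rod"})
        g = build_graph(em, find_junctions(em))
        prev = None
        for d in (4.0, 2.0, 1.0, 0.5):
            gt = attach_terminals(g, em, LoadCase(plunger_diameter=d))
            cur = set(gt.neighbors(SOURCE))
            if prev is not None:
                assert cur <= prev
            prev = cur
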