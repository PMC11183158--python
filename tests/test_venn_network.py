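"""Bipartite membership networks: modes, layout, export."""

import math

import pytest

import vennkit as vk
from vennkit.errors import VennKitError


class TestBuildGraph:
    def test_shared_element_has_degree_two(self):
        coll = vk.SetCollection.from_sets({"A": ["x"], "B": ["x"]})
        g = vk.build_graph(coll, "all")
        assert g.degree("x") == 2

    def test_flower_like_drops_intermediate_degrees(self):
        coll = vk.SetCollection.from_sets(
            {"A": ["c", "u", "m"], "B": ["c", "m"], "C": ["c"]}
        )
        g = vk.build_graph(coll, "flower_like")
        assert "c" in g and "u" in g and "m" not in g

    def test_edge_count_is_total_membership_degree(self):
        coll = vk.generate_collection(5, 150, seed=1)
        g = vk.build_graph(coll, "all")
        assert g.number_of_edges() == sum(
            len(s) for s in coll.membership.values()
        )

    def test_flower_like_nodes_match_flower_values(self):
        coll = vk.generate_collection(4, 120, seed=2)
        g = vk.build_graph(coll, "flower_like")
        part = vk.exclusive_regions(coll)
        core_sig = vk.canonical_signature(coll.set_names, coll.set_names)
        expected = set(part.elements(core_sig))
        for name in coll.set_names:
            expected |= set(part.elements(name))
        elements = {n for n, d in g.nodes(data=True) if d["type"] == "element"}
        assert elements == expected

    def test_degree_n_and_degree_1_match_regions(self):
        coll = vk.generate_collection(3, 120, seed=3)
        g = vk.build_graph(coll, "all")
        part = vk.exclusive_regions(coll)
        n = coll.n_sets
        deg_n = {
            node for node, d in g.nodes(data=True)
            if d["type"] == "element" and g.degree(node) == n
        }
        core_sig = vk.canonical_signature(coll.set_names, coll.set_names)
        assert deg_n == set(part.elements(core_sig))
        deg_1 = {
            node for node, d in g.nodes(data=True)
            if d["type"] == "element" and g.degree(node) == 1
        }
        singles = set()
        for name in coll.set_names:
            singles |= set(part.elements(name))
        assert deg_1 == singles


class TestForceLayout:
    def test_two_nodes_distinct_positions(self):
        coll = vk.SetCollection.from_sets({"A": ["x"]})
        pos = vk.force_layout(vk.build_graph(coll))
        assert pos["A"] != pos["x"]

    def test_deterministic_for_fixed_seed(self):
        coll = vk.generate_collection(4, 60, seed=4)
        g = vk.build_graph(coll)
        assert vk.force_layout(g, seed=5) == vk.force_layout(g, seed=5)

    def test_no_coincident_coordinates(self):
        coll = vk.generate_collection(5, 120, seed=6)
        pos = vk.force_layout(vk.build_graph(coll), seed=0)
        assert len(set(pos.values())) == len(pos)

    def test_elements_cluster_near_their_own_sets(self):
        # two disjoint blocks: elements of A should sit nearer A than B
        coll = vk.SetCollection.from_sets(
            {"A": [f"a{i}" for i in range(12)], "B": [f"b{i}" for i in range(12)]}
        )
        g = vk.build_graph(coll)
        pos = vk.force_layout(g, seed=1)
        for i in range(12):
            da = math.dist(pos[f"a{i}"], pos["A"])
            db = math.dist(pos[f"a{i}"], pos["B"])
            assert da < db

    def test_empty_graph_rejected(self):
        import networkx as nx

        with pytest.raises(VennKitError):
            vk.force_layout(nx.Graph())


class TestExport:
    def test_two_node_graphml(self):
        coll = vk.SetCollection.from_sets({"A": ["x"]})
        g = vk.build_graph(coll)
        graphml, payload = vk.export_graph(g, vk.force_layout(g))
        assert graphml.count("<node ") == 2
        assert graphml.count("<edge ") == 1

    def test_json_roundtrip_preserves_edges_and_attrs(self):
        coll = vk.generate_collection(4, 80, seed=7)
        g = vk.build_graph(coll, colors=[(255, 0, 0)])
        pos = vk.force_layout(g, seed=2)
        _, payload = vk.export_graph(g, pos)
        g2, pos2 = vk.import_graph_json(payload)
        assert set(g2.edges()) == set(g.edges())
        assert pos2.keys() == pos.keys()
        assert g2.nodes[coll.set_names[0]]["type"] == "set"

    def test_set_nodes_carry_chosen_colors(self):
        colors = [(255, 192, 203), (0, 128, 0), (128, 0, 128), (0, 0, 255)]
        coll = vk.generate_collection(4, 40, seed=8)
        g = vk.build_graph(coll, colors=colors)
        hexes = [g.nodes[n]["color"] for n in coll.set_names]
        assert hexes == ["#ffc0cb", "#008000", "#800080", "#0000ff"]
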