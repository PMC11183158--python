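"""Bipartite set–element networks: construction, filtering, layout, export.

Each set is a parent node and every element connects to the sets containing
it, so an element's degree encodes its membership multiplicity (degree n =
shared by all sets, degree 1 = set-specific).  The ``flower_like`` display
mode keeps only those two extremes, mirroring the flower plot's core and
petals.  Layout is a seeded Fruchterman–Reingold embedding per connected
component with deterministic component packing; exports are GraphML and a
JSON node/link document carrying the same attributes.
"""

from __future__ import annotations

import json
import math
from typing import Mapping, Sequence

import networkx as nx

from .errors import VennKitError
from .io_formats import DEFAULT_PALETTE, interpolate_colors, rgb_to_hex
from .scene import RGB, CirclePrim, LinePrim, SceneGraph, Style, TextPrim
from .setcore import SetCollection

__all__ = [
    "build_graph",
    "force_layout",
    "export_graph",
    "import_graph_json",
    "network_scene",
]


def build_graph(
    collection: SetCollection,
    mode: str = "all",
    colors: Sequence[RGB] | None = None,
) -> nx.Graph:
    """Build the bipartite membership graph.

    ``mode="all"`` keeps every element; ``mode="flower_like"`` keeps only
    elements common to all sets (degree n) or specific to one set (degree 1).
    Set nodes carry ``type="set"`` and a color; element nodes ``type="element"``.
    """
    if mode not in ("all", "flower_like"):
        raise VennKitError(f"unknown mode {mode!r} (all | flower_like)")
    colors = interpolate_colors(
        list(colors) if colors else DEFAULT_PALETTE, collection.n_sets
    )
    g = nx.Graph()
    n = collection.n_sets
    for name, color in zip(collection.set_names, colors):
        g.add_node(name, type="set", color=rgb_to_hex(color))
    for elem, sets in collection.membership.items():
        deg = len(sets)
        if mode == "flower_like" and deg not in (1, n):
            continue
        g.add_node(elem, type="element")
        for name in sets:
            g.add_edge(elem, name)
    return g


def force_layout(
    graph: nx.Graph, iterations: int = 60, seed: int = 0
) -> dict[str, tuple[float, float]]:
    """Deterministic force-directed positions with components laid side by side.

    Within each connected component a seeded spring (Fruchterman–Reingold)
    embedding is computed; components are then packed left to right with
    spacing proportional to their size.  No two nodes share a coordinate.
    """
    if graph.number_of_nodes() == 0:
        raise VennKitError("graph is empty")
    positions: dict[str, tuple[float, float]] = {}
    x_cursor = 0.0
    components = sorted(nx.connected_components(graph), key=lambda c: (-len(c), sorted(c)[0]))
    for comp in components:
        sub = graph.subgraph(comp)
        radius = max(0.5, math.sqrt(len(comp)) / 2.0)
        if len(comp) == 1:
            local = {next(iter(comp)): (0.0, 0.0)}
        else:
            local = nx.spring_layout(sub, iterations=iterations, seed=seed, scale=radius)
        for node, (x, y) in local.items():
            positions[node] = (float(x) + x_cursor + radius, float(y))
        x_cursor += 2.0 * radius + 1.0
    # break exact coincidences deterministically
    seen: dict[tuple[float, float], int] = {}
    for node in sorted(positions):
        key = (round(positions[node][0], 9), round(positions[node][1], 9))
        bump = seen.get(key, 0)
        if bump:
            x, y = positions[node]
            positions[node] = (x + 1e-3 * bump, y + 1e-3 * bump)
        seen[key] = bump + 1
    return positions


def export_graph(
    graph: nx.Graph, positions: Mapping[str, tuple[float, float]]
) -> tuple[str, str]:
    """Serialize to (GraphML text, JSON text) with type/color/x/y per node."""
    g = graph.copy()
    for node, (x, y) in positions.items():
        g.nodes[node]["x"] = float(x)
        g.nodes[node]["y"] = float(y)
    graphml = "\n".join(nx.generate_graphml(g)) + "\n"
    payload = {
        "nodes": [
            {"id": node, **{k: v for k, v in data.items()}}
            for node, data in sorted(g.nodes(data=True))
        ],
        "links": [
            {"source": u, "target": v} for u, v in sorted(g.edges())
        ],
    }
    return graphml, json.dumps(payload, indent=2)


def import_graph_json(text: str) -> tuple[nx.Graph, dict[str, tuple[float, float]]]:
    """Rebuild a graph and its positions from the JSON export."""
    payload = json.loads(text)
    g = nx.Graph()
    positions: dict[str, tuple[float, float]] = {}
    for node in payload["nodes"]:
        attrs = dict(node)
        nid = attrs.pop("id")
        x, y = attrs.pop("x", None), attrs.pop("y", None)
        g.add_node(nid, **attrs)
        if x is not None:
            positions[nid] = (x, y)
    for link in payload["links"]:
        g.add_edge(link["source"], link["target"])
    return g, positions


def network_scene(
    graph: nx.Graph, positions: Mapping[str, tuple[float, float]]
) -> SceneGraph:
    """Simple node-link drawing: colored set hubs, small element dots."""
    scene = SceneGraph(metadata={"diagram": "venn-network",
                                 "nodes": graph.number_of_nodes()})
    edge_style = Style(stroke=(150, 150, 150), stroke_width=0.01)
    for u, v in sorted(graph.edges()):
        (x1, y1), (x2, y2) = positions[u], positions[v]
        scene.add(LinePrim(x1, y1, x2, y2, edge_style))
    for node in sorted(graph.nodes):
        x, y = positions[node]
        data = graph.nodes[node]
        if data.get("type") == "set":
            color = data.get("color", "#808080").lstrip("#")
            rgb = tuple(int(color[i : i + 2], 16) for i in (0, 2, 4))
            scene.add(
                CirclePrim(x, y, 0.18, Style(fill=rgb, stroke=(40, 40, 40),
                                             stroke_width=0.01)),
                TextPrim(x, y + 0.3, str(node), size=0.16),
            )
        else:
            scene.add(CirclePrim(x, y, 0.05,
                                 Style(fill=(120, 120, 120), stroke=None)))
    return scene
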