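"""Gene networks and their shortest-path ground metric.

A :class:`GeneNetwork` is a weighted undirected simple graph over gene
symbols.  Edge *strengths* (positive reals, default 1) express interaction
confidence or intensity; the ground metric used by the transport module
assigns each edge the length ``1 / strength`` and takes all-pairs
shortest-path distances within each connected component.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from .errors import ParseError, ValidationError


@dataclass(frozen=True)
class GeneNetwork:
    """Undirected weighted graph over gene symbols.

    ``nodes`` preserves first-appearance order; ``components`` is a stable
    partition (ordered by the earliest-appearing member, nodes in node order).
    """

    graph: nx.Graph
    nodes: tuple[str, ...]

    def __post_init__(self) -> None:
        if set(self.graph.nodes) != set(self.nodes):
            raise ValidationError("node order does not match graph node set")
        for u, v, data in self.graph.edges(data=True):
            if u == v:
                raise ValidationError(f"self-loop at node {u!r}")
            if data.get("strength", 1.0) <= 0:
                raise ValidationError(f"non-positive strength on edge {u!r}–{v!r}")

    @property
    def components(self) -> list[list[str]]:
        order = {n: i for i, n in enumerate(self.nodes)}
        comps = [sorted(c, key=order.__getitem__) for c in nx.connected_components(self.graph)]
        comps.sort(key=lambda c: order[c[0]])
        return comps

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def subnetwork(self, keep: Iterable[str]) -> "GeneNetwork":
        """Induced subgraph on ``keep`` (order inherited from this network)."""
        keep = set(keep)
        nodes = tuple(n for n in self.nodes if n in keep)
        if not nodes:
            raise ValidationError("subnetwork would be empty")
        return GeneNetwork(self.graph.subgraph(nodes).copy(), nodes)


@dataclass(frozen=True)
class GroundMetric:
    """Per-component all-pairs shortest-path distances.

    ``component_nodes[c]`` lists the nodes of component ``c`` in network
    order and ``matrices[c]`` is the corresponding symmetric distance matrix
    (finite, zero diagonal).
    """

    component_nodes: tuple[tuple[str, ...], ...]
    matrices: tuple[np.ndarray, ...]
    node_location: dict = field(repr=False)  # gene -> (component, position)

    @property
    def n_components(self) -> int:
        return len(self.matrices)


def from_edges(
    edges: Sequence[tuple],
    nodes: Sequence[str] | None = None,
) -> GeneNetwork:
    """Build a network from ``(a, b)`` or ``(a, b, strength)`` tuples.

    Repeated edges collapse keeping the maximum strength.  ``nodes`` may add
    isolated nodes and/or fix the node order; otherwise order is
    first-appearance order over the edge list.
    """
    g = nx.Graph()
    order: list[str] = []
    seen: set[str] = set()

    def note(n: str) -> None:
        if n not in seen:
            seen.add(n)
            order.append(n)

    if nodes is not None:
        for n in nodes:
            note(str(n))
            g.add_node(str(n))
    for row in edges:
        if len(row) == 2:
            a, b = row
            s = 1.0
        else:
            a, b, s = row
            s = float(s)
        a, b = str(a), str(b)
        if a == b:
            raise ValidationError(f"self-loop at node {a!r}")
        if s <= 0:
            raise ValidationError(f"non-positive strength on edge {a!r}–{b!r}")
        note(a)
        note(b)
        if g.has_edge(a, b):
            s = max(s, g[a][b]["strength"])
        g.add_edge(a, b, strength=s)
    return GeneNetwork(g, tuple(order))


def read_edge_list(path) -> GeneNetwork:
    """Read a SIF-like whitespace-delimited edge list.

    Each non-blank, non-comment line is ``gene_a gene_b [strength]``.
    """
    edges = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) not in (2, 3):
                raise ParseError(f"line {lineno}: expected 2 or 3 columns, got {len(parts)}")
            if len(parts) == 3:
                try:
                    strength = float(parts[2])
                except ValueError:
                    raise ParseError(
                        f"line {lineno}: strength {parts[2]!r} is not a number"
                    ) from None
                if not np.isfinite(strength) or strength <= 0:
                    raise ParseError(f"line {lineno}: strength must be a positive real")
                edges.append((parts[0], parts[1], strength))
            else:
                edges.append((parts[0], parts[1]))
    return from_edges(edges)


def write_edge_list(g: GeneNetwork, path) -> None:
    with open(path, "w") as fh:
        for u, v, data in g.graph.edges(data=True):
            fh.write(f"{u}\t{v}\t{data.get('strength', 1.0)!r}\n")


def write_graphml(g: GeneNetwork, path) -> None:
    nx.write_graphml(g.graph, path)


def ground_metric(g: GeneNetwork) -> GroundMetric:
    """Shortest-path distances per component with edge length ``1/strength``."""
    component_nodes = []
    matrices = []
    location: dict[str, tuple[int, int]] = {}
    for ci, comp in enumerate(g.components):
        index = {n: i for i, n in enumerate(comp)}
        n = len(comp)
        rows, cols, lengths = [], [], []
        for u, v, data in g.graph.subgraph(comp).edges(data=True):
            i, j = index[u], index[v]
            length = 1.0 / data.get("strength", 1.0)
            rows += [i, j]
            cols += [j, i]
            lengths += [length, length]
        adjacency = csr_matrix((lengths, (rows, cols)), shape=(n, n))
        dist = dijkstra(adjacency, directed=False)
        component_nodes.append(tuple(comp))
        matrices.append(dist)
        for name, i in index.items():
            location[name] = (ci, i)
    return GroundMetric(tuple(component_nodes), tuple(matrices), location)
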