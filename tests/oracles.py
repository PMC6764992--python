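"""Independent oracles used by the tests and the acceptance script.

These deliberately avoid the code paths they check: the EMD oracle runs the
pure-Python network-simplex solver in networkx on an integer-scaled
min-cost-flow formulation of the transportation problem, and the path-graph
oracle is the one-dimensional closed form.
"""

import networkx as nx
import numpy as np

MASS_SCALE = 10**9
COST_SCALE = 10**7


def emd_network_simplex_oracle(p, q, ground) -> float:
    """EMD via integer min-cost flow (networkx network simplex)."""

    def quantize(mass):
        mass = np.asarray(mass, dtype=float)
        mass = mass / mass.sum()
        scaled = mass * MASS_SCALE
        counts = np.floor(scaled).astype(np.int64)
        for idx in np.argsort(-(scaled - counts))[: MASS_SCALE - counts.sum()]:
            counts[idx] += 1
        return counts

    sp, sq = quantize(p), quantize(q)
    g = nx.DiGraph()
    n = len(sp)
    for i in range(n):
        g.add_node(("a", i), demand=-int(sp[i]))
        g.add_node(("b", i), demand=int(sq[i]))
    for i in range(n):
        for j in range(n):
            g.add_edge(("a", i), ("b", j), weight=int(round(ground[i, j] * COST_SCALE)))
    cost, _ = nx.network_simplex(g)
    return cost / (MASS_SCALE * COST_SCALE)


def path_cdf_closed_form(p, q) -> float:
    """1-Wasserstein on a unit-edge path: sum of |CDF differences|."""
    return float(np.abs(np.cumsum(np.asarray(p) - np.asarray(q))[:-1]).sum())


def random_connected_network(rng, n_nodes, edge_prob=0.5, weighted=False):
    """Random connected graph: a random spanning tree plus extra edges."""
    from wassermap.network import from_edges

    names = [f"v{i}" for i in range(n_nodes)]
    edges = []
    for i in range(1, n_nodes):
        j = int(rng.integers(0, i))
        edges.append((names[j], names[i]))
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if (names[i], names[j]) not in edges and rng.random() < edge_prob:
                edges.append((names[i], names[j]))
    if weighted:
        edges = [(a, b, float(rng.uniform(0.2, 5.0))) for a, b in edges]
    return from_edges(edges, nodes=names)
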