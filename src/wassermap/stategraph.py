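"""State-graph extraction and coherent-state calling.

The Mapper nerve's 1-skeleton is decomposed into maximal linear paths:
nodes of degree ≥ 3 are branch points, and every edge belongs to exactly one
path whose interior nodes have degree 2.  Paths are concatenated (largest
sample count first) to produce a display order of samples, within each node
sorted by filter value.  Coherent states are then called per sample group
from the normalized expression matrix: a gene is *activated* in a group when
its mean normalized value is ≥ 0.5 + δ, *inactivated* when ≤ 0.5 − δ, and
*equivocal* otherwise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .errors import ValidationError
from .expression import NORMALIZED, ExpressionMatrix
from .mapper import FilterValues, MapperComplex
from .transport import SampleDistanceMatrix

ACTIVATED = "activated"
INACTIVATED = "inactivated"
EQUIVOCAL = "equivocal"


@dataclass(frozen=True)
class StateGraph:
    """1-skeleton of a Mapper complex with its linear-path decomposition."""

    complex: MapperComplex
    branch_nodes: tuple[int, ...]
    paths: tuple[tuple[int, ...], ...]
    cycles: tuple[bool, ...]
    sample_order: tuple[int, ...] | None = None

    @property
    def n_paths(self) -> int:
        return len(self.paths)

    def path_samples(self, path_index: int) -> tuple[int, ...]:
        members: set[int] = set()
        for node in self.paths[path_index]:
            members.update(self.complex.nodes[node].members)
        return tuple(sorted(members))

    def with_order(self, order) -> "StateGraph":
        return replace(self, sample_order=tuple(int(i) for i in order))

    def to_json(self) -> str:
        payload = {
            "branch_nodes": list(self.branch_nodes),
            "paths": [list(p) for p in self.paths],
            "cycles": list(self.cycles),
            "sample_order": None if self.sample_order is None else list(self.sample_order),
            "complex": json.loads(self.complex.to_json()),
        }
        return json.dumps(payload, indent=1)


@dataclass(frozen=True)
class CoherentState:
    """A named sample group with per-gene activation calls."""

    name: str
    samples: tuple[str, ...]
    calls: pd.Series
    means: pd.Series


def decompose_paths(complex: MapperComplex) -> StateGraph:
    """Split the 1-skeleton into maximal linear paths.

    Breakpoints are nodes of degree ≥ 3; chains of degree-2 nodes between
    breakpoints (or degree-1 ends) form the paths.  A component with no
    breakpoint is either a simple path, a cycle (cut at its smallest node,
    recorded with a cycle flag and a closed traversal), or an isolated node.
    Paths are ordered by total sample count descending, ties by smallest
    node id, so the first path is the "core".
    """
    n = complex.n_nodes
    adj: dict[int, set[int]] = {i: set() for i in range(n)}
    for i, j in complex.edges:
        adj[i].add(j)
        adj[j].add(i)
    deg = {i: len(adj[i]) for i in range(n)}
    breakpoints = {i for i in range(n) if deg[i] >= 3}
    visited: set[frozenset] = set()
    raw: list[tuple[list[int], bool]] = []

    def walk(start: int, nxt: int) -> list[int]:
        path = [start, nxt]
        visited.add(frozenset((start, nxt)))
        while deg[path[-1]] == 2 and path[-1] not in breakpoints and path[-1] != start:
            u, prev = path[-1], path[-2]
            (follow,) = adj[u] - {prev}
            visited.add(frozenset((u, follow)))
            path.append(follow)
        return path

    for b in sorted(breakpoints):
        for nb in sorted(adj[b]):
            if frozenset((b, nb)) not in visited:
                raw.append((walk(b, nb), False))

    # breakpoint-free components: simple paths, cycles, isolated nodes
    leftover = [
        i for i in range(n)
        if i not in breakpoints
        and any(frozenset((i, j)) not in visited for j in adj[i])
    ]
    seen: set[int] = set()
    for i in sorted(leftover):
        if i in seen:
            continue
        comp = {i}
        stack = [i]
        while stack:
            u = stack.pop()
            for v in adj[u]:
                if v not in comp and v not in breakpoints:
                    comp.add(v)
                    stack.append(v)
        seen |= comp
        ends = sorted(u for u in comp if deg[u] == 1)
        if ends:
            path = walk(ends[0], min(adj[ends[0]]))
            raw.append((path, False))
        else:  # cycle: cut at the smallest node, smaller neighbour first
            start = min(comp)
            path = [start]
            visited.add(frozenset((start, min(adj[start]))))
            path.append(min(adj[start]))
            while path[-1] != start:
                u, prev = path[-1], path[-2]
                (follow,) = adj[u] - {prev}
                visited.add(frozenset((u, follow)))
                path.append(follow)
            raw.append((path, True))
    for i in range(n):
        if deg[i] == 0:
            raw.append(([i], False))

    def canonical(item):
        path, cyc = item
        if not cyc and path[0] > path[-1]:
            path = list(reversed(path))
        return path, cyc

    raw = [canonical(item) for item in raw]

    def sample_count(path: list[int]) -> int:
        members: set[int] = set()
        for node in path:
            members.update(complex.nodes[node].members)
        return len(members)

    raw.sort(key=lambda item: (-sample_count(item[0]), min(item[0]), tuple(item[0])))
    return StateGraph(
        complex=complex,
        branch_nodes=tuple(sorted(breakpoints)),
        paths=tuple(tuple(p) for p, _ in raw),
        cycles=tuple(c for _, c in raw),
    )


def order_samples(sg: StateGraph, f: FilterValues | np.ndarray) -> np.ndarray:
    """Display order: concatenated paths, within each node ascending filter.

    Samples appearing in several nodes are emitted at their first occurrence
    only, so every sample appears exactly once.
    """
    values = f.values if isinstance(f, FilterValues) else np.asarray(f, dtype=float)
    emitted: set[int] = set()
    order: list[int] = []
    for path in sg.paths:
        for node_pos, node in enumerate(path):
            if node_pos > 0 and node == path[0] and node_pos == len(path) - 1:
                continue  # closed traversal repeats its start node
            members = sg.complex.nodes[node].members
            for s in sorted(members, key=lambda i: (values[i], i)):
                if s not in emitted:
                    emitted.add(s)
                    order.append(s)
    return np.asarray(order, dtype=int)


def group_labels(sg: StateGraph, n_samples: int) -> np.ndarray:
    """Per-sample path assignment (first path containing the sample)."""
    labels = np.full(n_samples, -1, dtype=int)
    for k, path in enumerate(sg.paths):
        for node in path:
            for s in sg.complex.nodes[node].members:
                if labels[s] == -1:
                    labels[s] = k
    return labels


def group_by_paths(sg: StateGraph, sample_ids) -> dict[str, list[str]]:
    """Named sample groups, one per maximal path, for state calling."""
    sample_ids = list(sample_ids)
    labels = group_labels(sg, len(sample_ids))
    groups: dict[str, list[str]] = {}
    for k in range(sg.n_paths):
        members = [sample_ids[i] for i in np.flatnonzero(labels == k)]
        if members:
            groups[f"path_{k + 1}"] = members
    return groups


def heatmap_matrices(
    m: ExpressionMatrix,
    sg: StateGraph,
    D: SampleDistanceMatrix,
    embedding: np.ndarray,
    f: FilterValues | np.ndarray,
    covariates: pd.DataFrame | None = None,
) -> dict[str, pd.DataFrame]:
    """Display matrices with samples permuted to the state-graph order.

    Returns the normalized expression matrix, the Wasserstein distance
    matrix, the embedding Euclidean distance matrix, and (when discrete
    ``covariates`` are given) a genes × covariate-level point-biserial
    correlation matrix.
    """
    if m.scale != NORMALIZED:
        raise ValidationError("heatmap_matrices expects a normalized matrix")
    samples = list(m.samples)
    if list(D.samples) != samples:
        raise ValidationError("distance matrix samples do not match expression")
    embedding = np.atleast_2d(np.asarray(embedding, dtype=float))
    if embedding.shape[0] != len(samples):
        raise ValidationError("embedding rows do not match sample count")
    order = sg.sample_order
    if order is None:
        order = tuple(int(i) for i in order_samples(sg, f))
    if sorted(order) != list(range(len(samples))):
        raise ValidationError("sample order must be a permutation of all samples")
    order = list(order)
    ids = [samples[i] for i in order]
    out: dict[str, pd.DataFrame] = {}
    out["expression"] = m.data.iloc[:, order]
    out["wasserstein"] = pd.DataFrame(
        D.D[np.ix_(order, order)], index=ids, columns=ids
    )
    euc = squareform(pdist(embedding)) if len(samples) > 1 else np.zeros((1, 1))
    out["embedding_euclidean"] = pd.DataFrame(
        euc[np.ix_(order, order)], index=ids, columns=ids
    )
    if covariates is not None:
        if not set(samples) <= set(covariates.index):
            raise ValidationError("covariates missing some samples")
        cov = covariates.loc[samples]
        columns = {}
        x = m.values
        for name in cov.columns:
            col = cov[name]
            for level in sorted(col.dropna().unique(), key=str):
                ind = (col == level).to_numpy(dtype=float)
                if ind.std() == 0:
                    r = np.zeros(x.shape[0])
                else:
                    xc = x - x.mean(axis=1, keepdims=True)
                    ic = ind - ind.mean()
                    denom = x.std(axis=1) * ind.std() * x.shape[1]
                    with np.errstate(invalid="ignore", divide="ignore"):
                        r = np.where(denom > 0, xc @ ic / denom, 0.0)
                columns[f"{name}={level}"] = r
        out["covariate_correlation"] = pd.DataFrame(columns, index=m.genes)
    return out


def call_states(
    m: ExpressionMatrix,
    groups: dict,
    delta: float = 1.0 / 6.0,
) -> dict[str, CoherentState]:
    """Call activation states per group of samples.

    For each group and gene the mean normalized value v̄ yields
    ``activated`` if v̄ ≥ 0.5 + δ, ``inactivated`` if v̄ ≤ 0.5 − δ, else
    ``equivocal`` (boundaries inclusive).
    """
    if m.scale != NORMALIZED:
        raise ValidationError("call_states expects a normalized matrix")
    if not 0 < delta < 0.5:
        raise ValidationError("delta must lie in (0, 0.5)")
    known = set(m.samples)
    states: dict[str, CoherentState] = {}
    for name, members in groups.items():
        members = list(members)
        if not members:
            raise ValidationError(f"group {name!r} is empty")
        unknown = [s for s in members if s not in known]
        if unknown:
            raise ValidationError(f"group {name!r} has unknown samples: {unknown[:5]}")
        means = m.data[members].mean(axis=1)
        calls = pd.Series(
            np.where(
                means >= 0.5 + delta,
                ACTIVATED,
                np.where(means <= 0.5 - delta, INACTIVATED, EQUIVOCAL),
            ),
            index=m.data.index,
        )
        states[name] = CoherentState(name, tuple(members), calls, means)
    return states


def states_frame(states: dict[str, CoherentState]) -> pd.DataFrame:
    """Long-format table of state calls (state, gene, call, mean)."""
    rows = []
    for name, state in states.items():
        for gene in state.calls.index:
            rows.append(
                {
                    "state": name,
                    "gene": gene,
                    "call": state.calls[gene],
                    "mean": state.means[gene],
                }
            )
    return pd.DataFrame(rows, columns=["state", "gene", "call", "mean"])


def write_graphml(sg: StateGraph, path) -> None:
    import networkx as nx

    g = nx.Graph()
    for i, node in enumerate(sg.complex.nodes):
        g.add_node(
            i,
            bin=node.bin_index,
            size=len(node.members),
            mean_filter=node.mean_filter,
        )
    for (i, j), overlap in sg.complex.edges.items():
        g.add_edge(i, j, overlap=overlap)
    nx.write_graphml(g, path)


def render_heatmaps(matrices: dict[str, pd.DataFrame], outdir) -> list[str]:
    """Optional PNG rendering of the display matrices (thin display layer)."""
    import pathlib

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, frame in matrices.items():
        fig, ax = plt.subplots(figsize=(6, 4))
        im = ax.imshow(frame.to_numpy(dtype=float), aspect="auto", cmap="RdYlGn")
        ax.set_title(name)
        fig.colorbar(im, ax=ax)
        path = outdir / f"heatmap_{name}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(str(path))
    return written
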