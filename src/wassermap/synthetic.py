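"""Seeded synthetic expression data with planted coherent states.

The generator emulates the pipeline's intended input: a small gene network
and a non-negative (FPKM/TPM-like) expression matrix whose samples fall
into ``k`` planted states.  Each state assigns every gene a level —
``high``, ``low``, or ``mid`` — with positive target raw means; sample
values are the state means under multiplicative log-normal noise
``x = mean * exp(sigma_noise * z)``, which keeps values strictly positive
and right-skewed like real quantification data.

The default design places equal-magnitude activity blocks at the two ends
and the middle of a path network, so two of its states differ only in the
*network location* of their activity: their Euclidean separation matches
their within-state spread while the network Wasserstein metric separates
them clearly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ValidationError
from .expression import RAW, ExpressionMatrix
from .network import GeneNetwork, from_edges

HIGH, LOW, MID = "high", "low", "mid"


def _gene_names(n: int) -> list[str]:
    return [f"g{i + 1:02d}" for i in range(n)]


@dataclass(frozen=True)
class PlantedDesign:
    """Specification of a synthetic dataset.

    ``states`` maps state name → (gene → level); every gene must receive a
    level in every state.  ``high_mean``/``low_mean`` are the target raw
    means (``mid`` is their geometric mean, so its truncated z-score sits
    near 0.5).
    """

    topology: str = "path"
    n_genes: int = 14
    states: Mapping[str, Mapping[str, str]] | None = None
    samples_per_state: int = 30
    sigma_noise: float = 0.2
    seed: int = 7
    high_mean: float = 8.0
    low_mean: float = 0.5

    @property
    def mid_mean(self) -> float:
        return float(np.sqrt(self.high_mean * self.low_mean))

    @property
    def genes(self) -> list[str]:
        return _gene_names(self.n_genes)

    def level_mean(self, level: str) -> float:
        means = {HIGH: self.high_mean, LOW: self.low_mean, MID: self.mid_mean}
        if level not in means:
            raise ValidationError(f"unknown level {level!r}")
        mean = means[level]
        if mean <= 0:
            raise ValidationError("state means must be positive")
        return mean

    def resolved_states(self) -> dict[str, dict[str, str]]:
        states = self.states if self.states is not None else _default_states(self)
        for name, pattern in states.items():
            missing = [g for g in self.genes if g not in pattern]
            if missing:
                raise ValidationError(
                    f"state {name!r} assigns no level to genes {missing[:5]}"
                )
        return {name: dict(p) for name, p in states.items()}

    def state_means(self) -> pd.DataFrame:
        states = self.resolved_states()
        data = {
            name: [self.level_mean(pattern[g]) for g in self.genes]
            for name, pattern in states.items()
        }
        return pd.DataFrame(data, index=self.genes)


def _default_states(design: PlantedDesign) -> dict[str, dict[str, str]]:
    """Three states on a path: activity at the left end, middle, right end.

    Genes 5 and 10 (on the 14-gene default) are housekeeping-like: ``mid``
    in every state, hence equivocal everywhere.  States S1 and S2 have the
    same number of ``high`` genes at opposite ends — the pair separated
    only by network location.
    """
    if design.n_genes < 12:
        raise ValidationError("default states need at least 12 genes")
    genes = design.genes
    n = design.n_genes
    blocks = {
        "S1": set(range(0, 4)),
        "S3": set(range(n // 2 - 2, n // 2 + 2)),
        "S2": set(range(n - 4, n)),
    }
    housekeeping = {4, n - 5}
    states = {}
    for name in ("S1", "S2", "S3"):
        pattern = {}
        for i, g in enumerate(genes):
            if i in housekeeping:
                pattern[g] = MID
            elif i in blocks[name]:
                pattern[g] = HIGH
            else:
                pattern[g] = LOW
        states[name] = pattern
    return states


def default_design(**overrides) -> PlantedDesign:
    """The canonical 3-state × 30-sample design on a 14-gene path."""
    return PlantedDesign(**overrides)


def y_design(**overrides) -> PlantedDesign:
    """Variant whose *first* state is the middle-activity one.

    With :func:`interpolated_branch` (bridges from state 1 to states 2 and
    3) this yields arms running to both network ends, a point cloud whose
    correct state graph has exactly one branch node.
    """
    design = PlantedDesign(**overrides)
    if design.states is None:
        base = _default_states(design)
        states = {"S1": base["S3"], "S2": base["S1"], "S3": base["S2"]}
        design = replace(design, states=states)
    return design


def make_network(topology: str, n_genes: int, seed: int = 0) -> GeneNetwork:
    """Small named topologies over ``n_genes`` gene symbols.

    ``path``: a chain; ``star``: hub g01; ``two-community``: two cliques
    joined by one bridge edge; ``random-tree``: a uniformly random labelled
    tree (seeded).
    """
    genes = _gene_names(n_genes)
    if topology == "path":
        edges = [(genes[i], genes[i + 1]) for i in range(n_genes - 1)]
    elif topology == "star":
        edges = [(genes[0], genes[i]) for i in range(1, n_genes)]
    elif topology == "two-community":
        half = n_genes // 2
        edges = [
            (genes[i], genes[j])
            for block in (range(half), range(half, n_genes))
            for i in block
            for j in block
            if i < j
        ]
        edges.append((genes[half - 1], genes[half]))
    elif topology == "random-tree":
        tree = nx.random_labeled_tree(n_genes, seed=seed)
        edges = [(genes[u], genes[v]) for u, v in tree.edges]
    else:
        raise ValidationError(f"unknown topology {topology!r}")
    return from_edges(edges, nodes=genes)


def generate(
    design: PlantedDesign,
) -> tuple[ExpressionMatrix, GeneNetwork, pd.Series]:
    """Generate (expression matrix, network, true labels) for a design.

    Deterministic given ``design.seed``.  Labels are returned for
    evaluation only; the pipeline never consumes them.
    """
    network = make_network(design.topology, design.n_genes, design.seed)
    means = design.state_means()
    rng = np.random.default_rng(design.seed)
    columns: dict[str, np.ndarray] = {}
    labels: dict[str, str] = {}
    for name in means.columns:
        mu = means[name].to_numpy()
        for i in range(design.samples_per_state):
            z = rng.standard_normal(design.n_genes)
            sample_id = f"{name}_{i + 1:02d}"
            columns[sample_id] = mu * np.exp(design.sigma_noise * z)
            labels[sample_id] = name
    frame = pd.DataFrame(columns, index=design.genes)
    matrix = ExpressionMatrix(frame, scale=RAW)
    return matrix, network, pd.Series(labels, name="state")


def interpolated_branch(
    design: PlantedDesign, n_bridge: int
) -> tuple[ExpressionMatrix, GeneNetwork, pd.Series]:
    """Design plus bridge samples interpolating between state means.

    Adds ``n_bridge`` samples along convex combinations (in raw space) of
    the mean vectors of states 1–2 and of states 1–3, creating a Y-shaped
    point cloud.  Bridge labels are ``bridge_1_2`` / ``bridge_1_3``.
    """
    states = list(design.resolved_states())
    if len(states) < 2:
        raise ValidationError("interpolated_branch needs at least 2 states")
    matrix, network, labels = generate(design)
    if n_bridge == 0:
        return matrix, network, labels
    means = design.state_means()
    rng = np.random.default_rng(design.seed + 1)
    columns = {}
    extra_labels = {}
    arms = [(states[0], s) for s in states[1:3]]
    for a, b in arms:
        ia, ib = states.index(a) + 1, states.index(b) + 1
        for j in range(1, n_bridge + 1):
            w = j / (n_bridge + 1)
            mu = (1 - w) * means[a].to_numpy() + w * means[b].to_numpy()
            z = rng.standard_normal(design.n_genes)
            sample_id = f"bridge_{ia}_{ib}_{j:02d}"
            columns[sample_id] = mu * np.exp(design.sigma_noise * z)
            extra_labels[sample_id] = f"bridge_{ia}_{ib}"
    frame = pd.concat(
        [matrix.data, pd.DataFrame(columns, index=design.genes)], axis=1
    )
    all_labels = pd.concat([labels, pd.Series(extra_labels)])
    all_labels.name = "state"
    return ExpressionMatrix(frame, scale=RAW), network, all_labels


def write_labels(labels: pd.Series, path) -> None:
    labels.rename_axis("sample").to_frame().to_csv(path, sep="\t")
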