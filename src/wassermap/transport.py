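"""Network Wasserstein-1 (Earth Mover's) distances between expression samples.

Each sample's non-negative expression vector is interpreted, per connected
component of the gene network, as a probability distribution over nodes
(either by direct normalisation or as the invariant measure of an
expression-attracted random walk).  The distance between two samples is the
per-component 1-Wasserstein distance under the shortest-path ground metric,
amalgamated across components by the direct-sum (root-sum-of-squares)
formula::

    d(s, s') = sqrt( sum_c d_c(s, s')^2 )

The component EMD is the optimal value of the transportation linear program,
solved exactly with HiGHS.  A Hungarian-assignment route on uniformly
quantized mass is provided for cross-checking only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment, linprog
from scipy.sparse import coo_matrix
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import ValidationError
from .expression import RAW, ExpressionMatrix
from .network import GeneNetwork, GroundMetric, ground_metric

_MASS_TOL = 1e-9
_MASS_MISMATCH = 1e-6


@dataclass(frozen=True)
class NodeDistribution:
    """Per-component mass vectors for one sample.

    ``masses[c]`` sums to 1 for every non-empty component; a component may be
    flagged empty (no mass), in which case it is comparable only with
    components empty in the other sample.
    """

    masses: tuple[np.ndarray, ...]
    empty: tuple[bool, ...]

    def __post_init__(self) -> None:
        for m, e in zip(self.masses, self.empty):
            if e:
                continue
            if np.any(m < 0):
                raise ValidationError("negative mass in distribution")
            if abs(m.sum() - 1.0) > _MASS_TOL:
                raise ValidationError("component masses must sum to 1")


@dataclass(frozen=True)
class SampleDistanceMatrix:
    """Symmetric pairwise sample distances with zero diagonal."""

    samples: tuple[str, ...]
    D: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.samples)
        if self.D.shape != (n, n):
            raise ValidationError("distance matrix shape mismatch")
        if not np.allclose(self.D, self.D.T, atol=1e-12):
            raise ValidationError("distance matrix must be symmetric")
        if np.any(np.diag(self.D) != 0):
            raise ValidationError("distance matrix diagonal must be zero")

    def offdiag_squared(self) -> np.ndarray:
        iu = np.triu_indices(len(self.samples), k=1)
        return self.D[iu] ** 2


def _stationary(P: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix (left Perron vector)."""
    n = P.shape[0]
    A = np.vstack([P.T - np.eye(n), np.ones((1, n))])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def to_distribution(
    sample_values: np.ndarray,
    g: GeneNetwork,
    mode: str = "density",
    pseudocount: float = 0.0,
) -> NodeDistribution:
    """Turn one sample's per-gene values into per-component node distributions.

    ``density`` mode normalises ``x + pseudocount`` within each component.
    ``invariant_measure`` mode returns the stationary distribution of the
    lazy random walk whose transition probability from ``u`` to a neighbour
    ``v`` is proportional to ``x_v + pseudocount`` (the walk is attracted to
    expressed genes; laziness with self-loop probability 1/2 removes
    bipartite periodicity).
    """
    if mode not in ("density", "invariant_measure"):
        raise ValidationError(f"unknown distribution mode {mode!r}")
    if pseudocount < 0:
        raise ValidationError("pseudocount must be non-negative")
    values = np.asarray(sample_values, dtype=float)
    if values.shape != (g.n_nodes,):
        raise ValidationError(
            f"sample has {values.shape} values for {g.n_nodes} network nodes"
        )
    if np.any(values < 0):
        raise ValidationError("sample values must be non-negative")
    index = {n: i for i, n in enumerate(g.nodes)}
    masses: list[np.ndarray] = []
    empty: list[bool] = []
    for comp in g.components:
        x = values[[index[n] for n in comp]] + pseudocount
        if mode == "density":
            total = x.sum()
            if total <= 0:
                raise ValidationError(
                    "empty component distribution (zero total mass with "
                    "pseudocount 0); pass a positive pseudocount to proceed"
                )
            masses.append(x / total)
            empty.append(False)
        else:
            n = len(comp)
            if n == 1:
                masses.append(np.ones(1))
                empty.append(False)
                continue
            local = {m: i for i, m in enumerate(comp)}
            P = np.zeros((n, n))
            sub = g.graph.subgraph(comp)
            for u in comp:
                i = local[u]
                nbrs = [local[v] for v in sub.neighbors(u)]
                w = x[nbrs]
                total = w.sum()
                if total <= 0:
                    raise ValidationError(
                        "walk undefined: neighbourhood has zero total mass "
                        "with pseudocount 0"
                    )
                P[i, nbrs] = w / total
            P = 0.5 * np.eye(n) + 0.5 * P  # lazy walk
            masses.append(_stationary(P))
            empty.append(False)
    return NodeDistribution(tuple(masses), tuple(empty))


def emd_component(p: np.ndarray, q: np.ndarray, ground: np.ndarray) -> float:
    """Exact 1-Wasserstein distance between two mass vectors on one component.

    Solves the transportation linear program
    ``min <T, ground>  s.t.  T 1 = p,  T' 1 = q,  T >= 0``.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    ground = np.asarray(ground, dtype=float)
    n = ground.shape[0]
    if p.shape != (n,) or q.shape != (n,):
        raise ValidationError("mass vectors must match the ground matrix size")
    if np.any(p < 0) or np.any(q < 0):
        raise ValidationError("negative mass")
    if abs(p.sum() - q.sum()) > _MASS_MISMATCH:
        raise ValidationError(
            f"total mass mismatch: {p.sum()!r} vs {q.sum()!r}"
        )
    # Restrict to supports; mass shared in place never needs to move further
    # than the LP allows, and zero-mass rows/columns only pad the program.
    I = np.flatnonzero(p > 0)
    J = np.flatnonzero(q > 0)
    if len(I) == 0 or len(J) == 0:
        return 0.0
    if len(I) == 1 and len(J) == 1:
        return float(p[I[0]] * ground[I[0], J[0]])
    cost = ground[np.ix_(I, J)]
    ni, nj = len(I), len(J)
    row_idx = np.repeat(np.arange(ni), nj)
    col_idx = np.tile(np.arange(nj), ni) + ni
    data = np.ones(2 * ni * nj)
    rows = np.concatenate([row_idx, col_idx])
    cols = np.concatenate([np.arange(ni * nj), np.arange(ni * nj)])
    A_eq = coo_matrix((data, (rows, cols)), shape=(ni + nj, ni * nj))
    b_eq = np.concatenate([p[I], q[J]])
    res = linprog(cost.ravel(), A_eq=A_eq, b_eq=b_eq, method="highs")
    if not res.success:  # pragma: no cover - defensive
        raise RuntimeError(f"transportation LP failed: {res.message}")
    return float(max(res.fun, 0.0))


def emd_component_hungarian(
    p: np.ndarray, q: np.ndarray, ground: np.ndarray, resolution: int = 100
) -> float:
    """Approximate EMD by quantizing each distribution into ``resolution``
    equal atoms and solving the assignment problem (Hungarian algorithm).

    Converges to :func:`emd_component` as ``resolution`` grows; intended for
    cross-checks, not production use.
    """
    if resolution < 1:
        raise ValidationError("resolution must be >= 1")

    def atoms(mass: np.ndarray) -> np.ndarray:
        scaled = mass / mass.sum() * resolution
        counts = np.floor(scaled).astype(int)
        remainder = scaled - counts
        short = resolution - counts.sum()
        for idx in np.argsort(-remainder)[:short]:
            counts[idx] += 1
        return np.repeat(np.arange(len(mass)), counts)

    a = atoms(np.asarray(p, dtype=float))
    b = atoms(np.asarray(q, dtype=float))
    cost = ground[np.ix_(a, b)]
    r, c = linear_sum_assignment(cost)
    return float(cost[r, c].sum() / resolution)


def sample_distance(
    a: NodeDistribution, b: NodeDistribution, ground: GroundMetric
) -> float:
    """Direct-sum distance: root-sum-of-squares of per-component EMDs."""
    if len(a.masses) != len(b.masses) or len(a.masses) != ground.n_components:
        raise ValidationError("distributions are not on the same network")
    total = 0.0
    for ma, mb, ea, eb, G in zip(a.masses, b.masses, a.empty, b.empty, ground.matrices):
        if ea and eb:
            continue
        if ea != eb:
            raise ValidationError("incomparable supports: component empty in one sample")
        total += emd_component(ma, mb, G) ** 2
    return float(np.sqrt(total))


def distance_matrix(
    m: ExpressionMatrix,
    g: GeneNetwork,
    mode: str = "density",
    pseudocount: float = 0.0,
) -> SampleDistanceMatrix:
    """All pairwise direct-sum Wasserstein distances between samples of ``m``.

    ``m`` must be raw-scale and restricted to exactly the network's genes.
    """
    if m.scale != RAW:
        raise ValidationError("distance_matrix expects raw-scale values")
    if list(m.genes) != list(g.nodes):
        raise ValidationError(
            "matrix genes must equal network nodes in order; apply "
            "restrict_to_network and subnetwork first"
        )
    metric = ground_metric(g)
    values = m.values
    dists = []
    for j, sample in enumerate(m.samples):
        try:
            dists.append(to_distribution(values[:, j], g, mode, pseudocount))
        except ValidationError as exc:
            raise ValidationError(f"sample {sample!r}: {exc}") from exc
    n = m.n_samples
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = sample_distance(dists[i], dists[j], metric)
    return SampleDistanceMatrix(tuple(m.samples), D)


class WassersteinNetworkMetric(TransformerMixin, BaseEstimator):
    """Pairwise network Wasserstein distances as a scikit-learn transformer.

    Rows of ``X`` are samples, columns are genes aligned with
    ``network.nodes`` (a DataFrame is re-ordered by column name).
    ``fit_transform(X)`` yields the symmetric pairwise distance matrix;
    ``transform(Y)`` yields distances from new samples to the fitted ones.

    Parameters
    ----------
    network:
        The gene network supplying the ground metric.
    mode:
        ``"density"`` or ``"invariant_measure"`` node-distribution rule.
    pseudocount:
        Added to every gene value before normalisation (escape hatch for
        zero-mass components).
    """

    def __init__(self, network: GeneNetwork, *, mode: str = "density",
                 pseudocount: float = 0.0):
        self.network = network
        self.mode = mode
        self.pseudocount = pseudocount

    def _to_distributions(self, X) -> list[NodeDistribution]:
        import pandas as pd

        if isinstance(X, pd.DataFrame):
            missing = [n for n in self.network.nodes if n not in X.columns]
            if missing:
                raise ValidationError(f"samples lack network genes: {missing[:5]}")
            X = X.loc[:, list(self.network.nodes)].to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.network.n_nodes:
            raise ValidationError(
                f"X must be (n_samples, {self.network.n_nodes}); got {X.shape}"
            )
        return [
            to_distribution(row, self.network, self.mode, self.pseudocount)
            for row in X
        ]

    def fit(self, X, y=None):
        self.ground_ = ground_metric(self.network)
        self.distributions_ = self._to_distributions(X)
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "distributions_"):
            raise ValidationError("WassersteinNetworkMetric is not fitted")
        rows = self._to_distributions(X)
        out = np.zeros((len(rows), len(self.distributions_)))
        for i, a in enumerate(rows):
            for j, b in enumerate(self.distributions_):
                out[i, j] = sample_distance(a, b, self.ground_)
        return out

    def fit_transform(self, X, y=None) -> np.ndarray:
        self.fit(X)
        n = len(self.distributions_)
        D = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                D[i, j] = D[j, i] = sample_distance(
                    self.distributions_[i], self.distributions_[j], self.ground_
                )
        return D
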