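"""Diffusion-map embedding of a precomputed metric space.

The construction follows the density-invariant (α = 1) normalisation:

1. Gaussian kernel      ``W_ij = exp(-d_ij^2 / ε)``
2. Adapted kernel       ``W~ = D^-1 W D^-1`` with ``D_ii = Σ_j W_ij``
3. Markov operator      ``P = D~^-1 W~`` with ``D~_ii = Σ_j W~_ij``

The eigenvalues of ``P`` satisfy ``1 = λ1 ≥ |λ2| ≥ …`` with a constant
leading eigenvector; the per-sample entries of the next ``M`` eigenvectors
give the embedding Φ(s_i) = [φ1(i), …, φM(i)].  Numerically the spectrum is
obtained from the symmetric conjugate ``S = D~^1/2 P D~^-1/2``, which
guarantees real eigenvalues.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg
from sklearn.base import BaseEstimator

from .errors import ValidationError
from .transport import SampleDistanceMatrix


@dataclass(frozen=True)
class DiffusionEmbedding:
    """Spectral embedding result.

    ``eigenvalues`` are sorted by descending magnitude (signed values kept);
    ``eigenvectors`` holds the matching unit-norm eigenvectors as columns.
    ``coordinates`` is the (n_samples, M) embedding built from
    ``selected_indices`` (1-based over the *nontrivial* eigenvectors, i.e.
    after dropping the constant λ = 1 vector).
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    coordinates: np.ndarray
    selected_indices: tuple[int, ...]
    epsilon: float | None = None


def _as_distance_array(D) -> np.ndarray:
    if isinstance(D, SampleDistanceMatrix):
        return D.D
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValidationError("expected a square distance matrix")
    return D


def choose_epsilon(D, rule: str = "median", value: float | None = None) -> float:
    """Kernel scale ε.

    ``median`` rule: the median off-diagonal squared distance — a robust
    point inside the admissible range (any value between the minimum and
    maximum pairwise squared distance works in principle).  ``value`` rule:
    the user-supplied number, with a warning (not an error) when it falls
    outside that range.
    """
    D = _as_distance_array(D)
    n = D.shape[0]
    if n < 2:
        raise ValidationError("need at least 2 samples to choose epsilon")
    sq = D[np.triu_indices(n, k=1)] ** 2
    if np.all(sq == 0):
        raise ValidationError("degenerate metric: all pairwise distances are zero")
    if rule == "median":
        return float(np.median(sq))
    if rule == "value":
        if value is None or value <= 0:
            raise ValidationError("value rule requires a positive epsilon")
        if value < sq.min() or value > sq.max():
            warnings.warn(
                f"epsilon {value} lies outside the pairwise squared-distance "
                f"range [{sq.min()}, {sq.max()}]",
                stacklevel=2,
            )
        return float(value)
    raise ValidationError(f"unknown epsilon rule {rule!r}")


def kernel_matrix(D, epsilon: float) -> np.ndarray:
    """Gaussian kernel ``W_ij = exp(-D_ij^2 / ε)``."""
    if epsilon <= 0:
        raise ValidationError("epsilon must be positive")
    D = _as_distance_array(D)
    return np.exp(-(D**2) / epsilon)


def adapted_markov(W: np.ndarray) -> np.ndarray:
    """Row-stochastic diffusion operator with α = 1 normalisation.

    ``P = D~^-1 (D^-1 W D^-1)``; the first normalisation cancels the effect
    of sampling density, the second makes rows sum to one.
    """
    W = np.asarray(W, dtype=float)
    if W.shape[0] != W.shape[1]:
        raise ValidationError("kernel must be square")
    if not np.allclose(W, W.T, atol=1e-10):
        raise ValidationError("kernel must be symmetric")
    d = W.sum(axis=1)
    if np.any(d <= 0):
        raise ValidationError("kernel has a zero row sum")
    Wt = W / d[:, None] / d[None, :]
    dt = Wt.sum(axis=1)
    if np.any(dt <= 0):
        raise ValidationError("adapted kernel has a zero row sum")
    return Wt / dt[:, None]


def _markov_row_weights(W: np.ndarray) -> np.ndarray:
    d = W.sum(axis=1)
    Wt = W / d[:, None] / d[None, :]
    return Wt.sum(axis=1)


def embed(
    P: np.ndarray,
    n_components: int,
    selected_indices=None,
    *,
    row_weights: np.ndarray | None = None,
    include_trivial: bool = False,
    diffusion_time: float = 0.0,
    epsilon: float | None = None,
) -> DiffusionEmbedding:
    """Eigen-decompose the diffusion operator and build coordinates.

    ``row_weights`` (the adapted-kernel row sums D~) enables the symmetric
    conjugate eigensolver; without it a dense non-symmetric solve is used.
    ``selected_indices`` are 1-based over nontrivial eigenvectors (or over
    all eigenvectors when ``include_trivial`` is set) and override the
    default choice of the first ``n_components`` nontrivial ones.
    ``diffusion_time`` scales each coordinate by λ^t (t = 0 leaves the bare
    eigenvector entries).
    """
    P = np.asarray(P, dtype=float)
    n = P.shape[0]
    if P.shape != (n, n):
        raise ValidationError("P must be square")
    if not np.allclose(P.sum(axis=1), 1.0, atol=1e-8):
        raise ValidationError("P must be row-stochastic")
    if n_components >= n:
        raise ValidationError("n_components must be smaller than the sample count")

    if row_weights is not None:
        s = np.sqrt(np.asarray(row_weights, dtype=float))
        S = (s[:, None] * P) / s[None, :]
        S = (S + S.T) / 2.0
        lam, V = scipy.linalg.eigh(S)
        vecs = V / s[:, None]
    else:
        lam, V = scipy.linalg.eig(P)
        if np.max(np.abs(lam.imag)) > 1e-8:
            raise ValidationError("diffusion operator has complex spectrum")
        lam = lam.real
        vecs = V.real

    order = np.argsort(-np.abs(lam), kind="stable")
    lam = lam[order]
    vecs = vecs[:, order]
    # unit norm + deterministic sign: the entry of largest magnitude is positive
    for k in range(n):
        norm = np.linalg.norm(vecs[:, k])
        if norm > 0:
            vecs[:, k] /= norm
        pivot = np.argmax(np.abs(vecs[:, k]))
        if vecs[pivot, k] < 0:
            vecs[:, k] = -vecs[:, k]

    pool = np.arange(n) if include_trivial else np.arange(1, n)
    if selected_indices is None:
        chosen = pool[:n_components]
    else:
        chosen = []
        for idx in selected_indices:
            if idx < 1 or idx > len(pool):
                raise ValidationError(
                    f"eigenvector index {idx} out of range 1..{len(pool)}"
                )
            chosen.append(pool[idx - 1])
        chosen = np.asarray(chosen, dtype=int)
    coords = vecs[:, chosen].copy()
    if diffusion_time != 0:
        # negative eigenvalues require an integer diffusion time
        coords = coords * (lam[chosen] ** diffusion_time)
    return DiffusionEmbedding(
        eigenvalues=lam,
        eigenvectors=vecs,
        coordinates=coords,
        selected_indices=tuple(int(i) for i in chosen),
        epsilon=epsilon,
    )


class DiffusionMap(BaseEstimator):
    """Diffusion-map embedder over a precomputed distance matrix.

    Parameters
    ----------
    epsilon:
        ``"median"`` (default) or a positive float kernel scale.
    n_components:
        Embedding dimension M (nontrivial eigenvectors used by default).
    selected_indices:
        Optional explicit 1-based nontrivial eigenvector indices, e.g.
        ``(1, 2, 4)``.
    include_trivial:
        Count the constant λ = 1 eigenvector in the 1-based indexing.
    diffusion_time:
        Power t in the λ^t coordinate scaling (default 0: bare eigenvectors).

    Attributes (after ``fit``)
    --------------------------
    ``epsilon_``, ``kernel_``, ``markov_``, ``eigenvalues_``,
    ``eigenvectors_``, ``embedding_``.
    """

    def __init__(self, *, epsilon="median", n_components: int = 2,
                 selected_indices=None, include_trivial: bool = False,
                 diffusion_time: float = 0.0):
        self.epsilon = epsilon
        self.n_components = n_components
        self.selected_indices = selected_indices
        self.include_trivial = include_trivial
        self.diffusion_time = diffusion_time

    def fit(self, D, y=None):
        D = _as_distance_array(D)
        if self.epsilon == "median":
            eps = choose_epsilon(D, "median")
        else:
            eps = choose_epsilon(D, "value", float(self.epsilon))
        W = kernel_matrix(D, eps)
        P = adapted_markov(W)
        result = embed(
            P,
            self.n_components,
            self.selected_indices,
            row_weights=_markov_row_weights(W),
            include_trivial=self.include_trivial,
            diffusion_time=self.diffusion_time,
            epsilon=eps,
        )
        self.epsilon_ = eps
        self.kernel_ = W
        self.markov_ = P
        self.eigenvalues_ = result.eigenvalues
        self.eigenvectors_ = result.eigenvectors
        self.embedding_ = result.coordinates
        self.result_ = result
        return self

    def fit_transform(self, D, y=None) -> np.ndarray:
        return self.fit(D).embedding_
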