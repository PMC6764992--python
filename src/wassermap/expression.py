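"""Expression matrices: I/O, truncated z-score normalisation, network restriction.

The central container is :class:`ExpressionMatrix`, a thin validated wrapper
around a genes × samples :class:`pandas.DataFrame`.  Two value scales exist:

* ``raw`` — non-negative quantification values (FPKM/TPM-like).  This is the
  scale consumed by the transport metric, which interprets each sample as a
  mass distribution over network nodes and therefore requires non-negativity.
* ``normalized`` — per-gene truncated translated z-scores
  ``x ↦ (x − μ)/(3σ) + 0.5`` clamped to [0, 1], used for heatmap display and
  activation-state calling only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

if TYPE_CHECKING:  # pragma: no cover
    from .network import GeneNetwork

logger = logging.getLogger(__name__)

RAW = "raw"
NORMALIZED = "normalized"


def _first_duplicate(values) -> str | None:
    seen = set()
    for v in values:
        if v in seen:
            return str(v)
        seen.add(v)
    return None


@dataclass(frozen=True)
class ExpressionMatrix:
    """A genes × samples quantification matrix with a declared value scale.

    Parameters
    ----------
    data:
        DataFrame indexed by gene symbol with sample identifiers as columns.
    scale:
        ``"raw"`` (values ≥ 0) or ``"normalized"`` (values in [0, 1]).
    """

    data: pd.DataFrame
    scale: str = RAW

    def __post_init__(self) -> None:
        if self.scale not in (RAW, NORMALIZED):
            raise ValidationError(f"unknown scale {self.scale!r}")
        dup = _first_duplicate(self.data.index)
        if dup is not None:
            raise ValidationError(f"duplicate gene symbol: {dup}")
        dup = _first_duplicate(self.data.columns)
        if dup is not None:
            raise ValidationError(f"duplicate sample identifier: {dup}")
        for g in self.data.index:
            if not isinstance(g, str) or not g:
                raise ValidationError(f"invalid gene symbol: {g!r}")
        values = self.data.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.number):
            raise ValidationError("expression values must be numeric")
        if values.size:
            if not np.all(np.isfinite(values)):
                raise ValidationError("expression values must be finite")
            if self.scale == RAW and values.min() < 0:
                raise ValidationError("raw expression values must be non-negative")
            if self.scale == NORMALIZED and (
                values.min() < 0 or values.max() > 1
            ):
                raise ValidationError("normalized values must lie in [0, 1]")

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


def read_expression(path, delimiter: str = "\t") -> ExpressionMatrix:
    """Read a delimited genes × samples matrix.

    The first row is a header of sample identifiers (the first column-header
    cell is ignored); the first column holds gene symbols.  Cells must parse
    as finite non-negative numbers; parse failures report their location.
    """
    raw = pd.read_csv(path, sep=delimiter, index_col=0, header=0, dtype=str)
    raw.index = raw.index.astype(str)
    raw.columns = raw.columns.astype(str)
    parsed = np.empty(raw.shape, dtype=float)
    arr = raw.to_numpy()
    for i in range(raw.shape[0]):
        for j in range(raw.shape[1]):
            cell = arr[i, j]
            try:
                value = float(cell)
            except (TypeError, ValueError):
                raise ParseError(
                    f"non-numeric cell {cell!r} at gene {raw.index[i]!r}, "
                    f"sample {raw.columns[j]!r}"
                ) from None
            if not np.isfinite(value):
                raise ParseError(
                    f"non-finite cell at gene {raw.index[i]!r}, "
                    f"sample {raw.columns[j]!r}"
                )
            if value < 0:
                raise ParseError(
                    f"negative value {value} at gene {raw.index[i]!r}, "
                    f"sample {raw.columns[j]!r}"
                )
            parsed[i, j] = value
    frame = pd.DataFrame(parsed, index=raw.index, columns=raw.columns)
    return ExpressionMatrix(frame, scale=RAW)


def write_expression(m: ExpressionMatrix, path, delimiter: str = "\t") -> None:
    """Write a matrix in the same layout :func:`read_expression` accepts.

    Numbers are serialised with full ``repr`` precision so a read → write →
    read round-trip is bit-exact.
    """
    frame = m.data.copy()
    frame.index.name = "gene"
    with open(path, "w") as fh:
        fh.write("gene" + delimiter + delimiter.join(map(str, frame.columns)) + "\n")
        for gene, row in zip(frame.index, frame.to_numpy()):
            fh.write(
                str(gene) + delimiter + delimiter.join(repr(float(v)) for v in row) + "\n"
            )


def normalize_zscore(m: ExpressionMatrix) -> ExpressionMatrix:
    """Per-gene truncated translated z-score: ``(x − μ)/(3σ) + 0.5``, clamped.

    μ and σ are the per-gene mean and *population* (1/n) standard deviation.
    Values are hard-clamped to [0, 1]; genes with σ = 0 carry no contrast and
    map to the constant 0.5.
    """
    if m.scale != RAW:
        raise ValidationError("normalize_zscore expects a raw-scale matrix")
    if m.data.size == 0:
        raise ValidationError("cannot normalize an empty matrix")
    x = m.values
    mu = x.mean(axis=1, keepdims=True)
    sigma = x.std(axis=1, keepdims=True)  # ddof=0, population convention
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (x - mu) / (3.0 * sigma) + 0.5
    z = np.where(sigma == 0, 0.5, z)
    z = np.clip(z, 0.0, 1.0)
    frame = pd.DataFrame(z, index=m.data.index, columns=m.data.columns)
    return ExpressionMatrix(frame, scale=NORMALIZED)


def restrict_to_network(m: ExpressionMatrix, g: "GeneNetwork") -> ExpressionMatrix:
    """Keep only the genes present in both the matrix and the network.

    Rows are re-ordered to the network's node order; counts of dropped
    (matrix-only) and missing (network-only) genes are logged.
    """
    matrix_genes = set(m.genes)
    shared = [n for n in g.nodes if n in matrix_genes]
    if not shared:
        raise ValidationError("no genes shared between matrix and network")
    dropped = len(matrix_genes) - len(shared)
    missing = len(g.nodes) - len(shared)
    logger.info(
        "restrict_to_network: kept %d genes; dropped %d matrix-only; "
        "%d network genes unmeasured",
        len(shared), dropped, missing,
    )
    return replace(m, data=m.data.loc[shared])
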