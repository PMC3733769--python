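"""Escoufier Rv coefficients between landmark blocks and correlation networks.

Each landmark contributes a two-variable block (its x and y coordinates
across specimens).  The Rv coefficient between two blocks is the squared
cosine between their configuration (cross-product) matrices,

    Rv(X, Y) = tr(Sxy Syx) / sqrt(tr(Sxx^2) tr(Syy^2)),   S.. = Xc' Yc,

with Xc, Yc the column-centered (N, 2) blocks — a matrix-level
generalization of the squared Pearson correlation, bounded in [0, 1] and
invariant to rotation, translation and positive scaling of either block
(hence invariant under Procrustes superimposition).

The full pairwise Rv matrix is thresholded into a weighted undirected
graph: an edge i–j carries weight Rv_ij when Rv_ij strictly exceeds the
threshold, and is absent otherwise; with no threshold the network is the
complete weighted graph.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterator, Optional

import numpy as np
import pandas as pd

from .errors import StructureError, UndefinedCorrelationError
from .procrustes import AlignedDataset

_VAR_TOL = 1e-300


def rv_coefficient(block_i: np.ndarray, block_j: np.ndarray) -> float:
    """Rv coefficient between two (N, 2) coordinate blocks.

    Blocks are column-centered (per coordinate, across the N specimens)
    before the cross-products are formed; Rv is defined on covariance
    structure.  Symmetric in its arguments; raises
    :class:`UndefinedCorrelationError` on a zero-variance block.
    """
    x = np.asarray(block_i, dtype=float)
    y = np.asarray(block_j, dtype=float)
    if x.ndim != 2 or y.ndim != 2 or x.shape[1] != 2 or y.shape[1] != 2:
        raise StructureError("blocks must be (N, 2) arrays")
    if x.shape[0] != y.shape[0]:
        raise StructureError(
            f"blocks must share N: {x.shape[0]} != {y.shape[0]}"
        )
    if x.shape[0] < 3:
        raise StructureError("Rv needs at least 3 observations")
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    sxx = xc.T @ xc
    syy = yc.T @ yc
    sxy = xc.T @ yc
    denom_x = float(np.trace(sxx @ sxx))
    denom_y = float(np.trace(syy @ syy))
    if denom_x < _VAR_TOL or denom_y < _VAR_TOL:
        raise UndefinedCorrelationError("zero-variance block; Rv is undefined")
    num = float(np.trace(sxy @ sxy.T))
    rv = num / np.sqrt(denom_x * denom_y)
    # Cauchy-Schwarz bounds; clip pure round-off excursions only
    return float(min(max(rv, 0.0), 1.0))


@dataclass(frozen=True)
class RvMatrix:
    """Symmetric matrix of pairwise landmark-block Rv coefficients."""

    labels: tuple[str, ...]
    values: np.ndarray
    n_specimens: int = 0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "labels", tuple(self.labels))
        k = len(self.labels)
        if v.shape != (k, k):
            raise StructureError(f"values must be ({k}, {k}), got {v.shape}")
        if not np.allclose(v, v.T, atol=1e-12):
            raise StructureError("Rv matrix must be symmetric")
        if np.any(v < 0.0) or np.any(v > 1.0):
            raise ValueError("Rv values must lie in [0, 1]")
        if not np.allclose(np.diag(v), 1.0, atol=1e-12):
            raise StructureError("Rv matrix must have unit diagonal")

    @property
    def k(self) -> int:
        return len(self.labels)

    def value(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.values[i, j])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def rv_matrix(aligned: AlignedDataset, use: str = "specimen_means") -> RvMatrix:
    """All-pairs Rv matrix over the measurement points of an aligned dataset.

    ``use="specimen_means"`` (default) averages digitization replicates
    within each specimen before correlating, so the coefficients target
    between-individual variation; ``use="all_replicates"`` treats every
    digitization as an observation.
    """
    if use == "specimen_means":
        data = aligned.specimen_means()
    elif use == "all_replicates":
        data = aligned
    else:
        raise StructureError(f"unknown use mode {use!r}")
    n = data.coords.shape[0]
    if n < 3:
        raise StructureError("Rv matrix needs at least 3 effective observations")
    k = data.n_landmarks
    values = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            try:
                r = rv_coefficient(data.coords[:, i, :], data.coords[:, j, :])
            except UndefinedCorrelationError as exc:
                raise UndefinedCorrelationError(
                    f"Rv undefined for pair ({data.labels[i]}, {data.labels[j]}): {exc}"
                ) from exc
            values[i, j] = values[j, i] = r
    return RvMatrix(labels=data.labels, values=values, n_specimens=n)


@dataclass(frozen=True)
class CorrelationNetwork:
    """Weighted undirected graph of retained Rv coefficients.

    ``weights[i, j]`` equals the Rv coefficient where the edge is retained
    and 0 otherwise; the diagonal is zero.  The node set always equals the
    full label set — isolated nodes are permitted and meaningful.
    """

    labels: tuple[str, ...]
    weights: np.ndarray
    threshold: Optional[float] = None

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "labels", tuple(self.labels))
        k = len(self.labels)
        if w.shape != (k, k):
            raise StructureError(f"weights must be ({k}, {k}), got {w.shape}")
        if not np.allclose(w, w.T, atol=1e-12):
            raise StructureError("weight matrix must be symmetric")
        if np.any(np.diag(w) != 0.0):
            raise StructureError("weight matrix must have zero diagonal")
        if np.any(w < 0.0) or np.any(w > 1.0):
            raise ValueError("edge weights must lie in [0, 1]")

    @property
    def k(self) -> int:
        return len(self.labels)

    @property
    def n_edges(self) -> int:
        iu = np.triu_indices(self.k, 1)
        return int(np.count_nonzero(self.weights[iu]))

    @property
    def total_weight(self) -> float:
        iu = np.triu_indices(self.k, 1)
        return float(self.weights[iu].sum())

    def edges(self) -> Iterator[tuple[str, str, float]]:
        for i in range(self.k):
            for j in range(i + 1, self.k):
                w = self.weights[i, j]
                if w != 0.0:
                    yield self.labels[i], self.labels[j], float(w)

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        if self.threshold is not None:
            g.graph["threshold"] = float(self.threshold)
        g.add_nodes_from(self.labels)
        g.add_weighted_edges_from(self.edges())
        return g

    @classmethod
    def from_networkx(cls, g) -> "CorrelationNetwork":
        labels = tuple(g.nodes())
        k = len(labels)
        idx = {l: i for i, l in enumerate(labels)}
        w = np.zeros((k, k))
        for u, v, data in g.edges(data=True):
            w[idx[u], idx[v]] = w[idx[v], idx[u]] = float(data.get("weight", 1.0))
        tau = g.graph.get("threshold")
        return cls(labels, w, None if tau is None else float(tau))


def threshold_network(
    rv: RvMatrix, tau: Optional[float] = None
) -> CorrelationNetwork:
    """Build the correlation network by strict thresholding.

    An edge i-j is retained with weight Rv_ij iff ``Rv_ij > tau`` (strict:
    links must lie *above* the threshold level).  ``tau=None`` keeps every
    pair, yielding the complete weighted graph.  ``tau >= 1`` produces an
    edgeless network and emits a warning.
    """
    if tau is not None:
        tau = float(tau)
        if tau < 0.0:
            raise ValueError("threshold must be in [0, 1] or None")
        if tau >= 1.0:
            warnings.warn(
                f"threshold {tau} retains no edges (Rv <= 1)", stacklevel=2
            )
    w = rv.values.copy()
    np.fill_diagonal(w, 0.0)
    if tau is not None:
        w[w <= tau] = 0.0
    return CorrelationNetwork(labels=rv.labels, weights=w, threshold=tau)
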