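"""Weighted graphs and local clustering-coefficient features.

Correlation matrices become complete weighted undirected graphs: edge weight
is the absolute correlation rescaled so the strongest edge has weight 1, and
the diagonal is zeroed.  From each graph the per-node weighted local
clustering coefficient is extracted; the feature vector of a subject is the
concatenation of the 90 low-order (averaged-network) coefficients and the
300 high-order (cluster-network) coefficients — 390 features in total at the
study settings.

Two coefficient variants are provided.  The default, ``mode="triangle"``, is
the geometric-mean (Onnela-type) form

    c_i = 2 / (|N_i| (|N_i| - 1)) * sum_{j<h; j,h in N_i} (w_ij w_ih w_jh)^(1/3)

which lies in [0, 1] for weights in [0, 1] and measures how strongly a node's
neighbours interconnect.  ``mode="literal"`` evaluates
2 * sum_{j in N_i} w_ij^(1/3) / (|N_i| (|N_i| - 1)) instead, a weighted-degree
surrogate kept for comparison with formulations that drop the triangle
product.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DimensionError


@dataclass
class WeightedGraph:
    """Symmetric nonnegative weight matrix with zero diagonal."""

    weights: np.ndarray

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


@dataclass
class FeatureVector:
    subject_id: str
    label: str
    names: list[str]
    values: np.ndarray


def to_weighted_graph(corr: np.ndarray) -> WeightedGraph:
    """Absolute off-diagonal correlations rescaled to a max weight of 1."""
    corr = np.asarray(corr, dtype=float)
    if corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
        raise DimensionError("correlation matrix must be square")
    if np.max(np.abs(corr - corr.T)) > 1e-8:
        raise ValueError("correlation matrix must be symmetric")
    w = np.abs(corr).astype(float)
    np.fill_diagonal(w, 0.0)
    peak = w.max()
    if peak > 0:
        w = w / peak
    return WeightedGraph((w + w.T) / 2.0)


def local_clustering_coefficient(
    graph: WeightedGraph, node: int, mode: str = "triangle"
) -> float:
    """Weighted local clustering coefficient of one node (see module docs)."""
    w = graph.weights
    if not 0 <= node < graph.n_nodes:
        raise IndexError(f"node {node} out of range for {graph.n_nodes}-node graph")
    neighbors = np.flatnonzero(w[node] > 0)
    k = neighbors.size
    if k < 2:
        return 0.0
    if mode == "literal":
        total = np.sum(np.cbrt(w[node, neighbors]))
    elif mode == "triangle":
        total = 0.0
        for a in range(k):
            j = neighbors[a]
            for b in range(a + 1, k):
                h = neighbors[b]
                total += np.cbrt(w[node, j] * w[node, h] * w[j, h])
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return 2.0 * total / (k * (k - 1))


def clustering_coefficients(graph: WeightedGraph, mode: str = "triangle") -> np.ndarray:
    """All-node clustering coefficients, vectorized for dense graphs."""
    w = graph.weights
    n = graph.n_nodes
    if mode == "literal":
        return np.array([local_clustering_coefficient(graph, i, "literal") for i in range(n)])
    w3 = np.cbrt(w)
    # diagonal of w3^3 counts each (j, h) neighbour pair twice; terms with
    # w_ij = 0 or w_ih = 0 vanish, so no explicit neighbourhood mask is needed
    tri = np.einsum("ij,jh,hi->i", w3, w3, w3)
    deg = (w > 0).sum(axis=1)
    denom = deg * (deg - 1)
    out = np.zeros(n)
    ok = denom > 0
    out[ok] = tri[ok] / denom[ok]
    return out


def feature_names(n_roi: int, n_clusters: int) -> list[str]:
    low = [f"low_cc_{i + 1:03d}" for i in range(n_roi)]
    high = [f"high_cc_{i + 1:03d}" for i in range(n_clusters)]
    return low + high


def feature_vector(
    subject_id: str,
    label: str,
    avg_low: np.ndarray,
    high_matrix: np.ndarray,
    mode: str = "triangle",
) -> FeatureVector:
    """Concatenate low-order and high-order clustering-coefficient features."""
    avg_low = np.asarray(avg_low)
    high_matrix = np.asarray(high_matrix)
    for name, m in (("avg_low", avg_low), ("high", high_matrix)):
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise DimensionError(f"{name} matrix must be square, got {m.shape}")
    low_cc = clustering_coefficients(to_weighted_graph(avg_low), mode)
    high_cc = clustering_coefficients(to_weighted_graph(high_matrix), mode)
    values = np.concatenate([low_cc, high_cc])
    if not np.all(np.isfinite(values)):
        raise ValueError(f"{subject_id}: non-finite feature values")
    return FeatureVector(
        subject_id, label, feature_names(avg_low.shape[0], high_matrix.shape[0]), values
    )


def feature_table(vectors: list[FeatureVector]) -> pd.DataFrame:
    """Subjects x features DataFrame with subject_id and label columns first."""
    if not vectors:
        raise ValueError("no feature vectors")
    names = vectors[0].names
    for v in vectors[1:]:
        if v.names != names:
            raise DimensionError("feature vectors have inconsistent feature names")
    data = {
        "subject_id": [v.subject_id for v in vectors],
        "label": [v.label for v in vectors],
    }
    mat = np.vstack([v.values for v in vectors])
    for j, name in enumerate(names):
        data[name] = mat[:, j]
    return pd.DataFrame(data)


def write_feature_table(table: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)
    return path


def read_feature_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
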