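"""Small shared helpers: edge indexing and correlation-matrix repair."""

from __future__ import annotations

import numpy as np


def edge_pairs(n_nodes: int) -> list[tuple[int, int]]:
    """Strict upper-triangle (p, q) pairs, p < q, in row-major order.

    This fixes the edge universe of an undirected network with unit
    self-connection: for 90 nodes there are 90*89/2 = 4005 edges.
    Indices are 0-based.
    """
    return [(p, q) for p in range(n_nodes) for q in range(p + 1, n_nodes)]


def nearest_correlation(mat: np.ndarray, n_iter: int = 3) -> np.ndarray:
    """Project a symmetric matrix to a nearby valid correlation matrix.

    Alternates eigenvalue clipping at zero with unit-diagonal rescaling.
    A couple of passes suffice for the mildly indefinite matrices produced
    by additive edits of a correlation matrix.
    """
    out = np.asarray(mat, dtype=float)
    out = (out + out.T) / 2.0
    for _ in range(n_iter):
        vals, vecs = np.linalg.eigh(out)
        if vals[0] >= 0:
            break
        out = (vecs * np.clip(vals, 0.0, None)) @ vecs.T
        d = np.sqrt(np.clip(np.diag(out), 1e-12, None))
        out = out / np.outer(d, d)
        out = (out + out.T) / 2.0
    np.fill_diagonal(out, 1.0)
    return out
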