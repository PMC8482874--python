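"""Low-order and high-order functional-connectivity networks.

The low-order network of a subject is the set of windowed ROI x ROI Pearson
correlation matrices obtained by sliding a window of length ``w`` with step
``s`` over the time axis: with ``t`` timepoints there are
K = floor((t - w)/s) + 1 windows, and at the study settings
(t = 115, w = 90, s = 1) K = 26.

Each ROI pair (p, q), p < q, then has an *edge time series*: its K windowed
correlations.  The high-order network measures co-fluctuation between edges,
i.e. the correlation between edge time series.  Because the full edge x edge
matrix (4005 x 4005 for 90 ROIs) is large and redundant, edges are first
grouped by k-means on their series (fitted on training subjects only), and
the high-order network is the cluster x cluster correlation matrix of
cluster-mean edge series — 300 x 300 at the study settings.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.cluster import KMeans

from ._utils import edge_pairs
from .cohort import SubjectSeries
from .errors import ConfigurationError, DimensionError


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window length and step, in timepoints."""

    window_length: int = 90
    step: int = 1

    def validate(self, n_timepoints: int | None = None) -> None:
        if self.step < 1:
            raise ConfigurationError("step must be >= 1")
        if self.window_length < 2:
            raise ConfigurationError("window_length must be >= 2")
        if n_timepoints is not None and self.window_length > n_timepoints:
            raise DimensionError(
                f"window_length {self.window_length} exceeds series length {n_timepoints}"
            )


@dataclass
class DynamicFCSet:
    """K windowed correlation matrices of one subject."""

    subject_id: str
    matrices: np.ndarray  # (K, n_roi, n_roi)
    window_spec: WindowSpec


@dataclass
class EdgeSeriesSet:
    """Edge-by-window matrix of windowed correlations; rows follow edge_index."""

    subject_id: str
    edge_index: list[tuple[int, int]]
    series: np.ndarray  # (E, K)


@dataclass
class EdgeClustering:
    """Frozen assignment of edges to clusters, learned on training subjects."""

    n_clusters: int
    assignment: np.ndarray  # (E,), values in 0..n_clusters-1
    edge_index: list[tuple[int, int]]
    fitted_on: list[str]
    seed: int


@dataclass
class HighOrderNetwork:
    """Cluster x cluster Pearson correlations of cluster-mean edge series."""

    subject_id: str
    matrix: np.ndarray


def count_windows(n_timepoints: int, spec: WindowSpec) -> int:
    """K = floor((t - w)/s) + 1; window j covers [j*s, j*s + w)."""
    spec.validate(n_timepoints)
    return (n_timepoints - spec.window_length) // spec.step + 1


def window_slices(n_timepoints: int, spec: WindowSpec) -> list[slice]:
    k = count_windows(n_timepoints, spec)
    return [slice(j * spec.step, j * spec.step + spec.window_length) for j in range(k)]


def low_order_fc(
    subject: SubjectSeries, spec: WindowSpec, jitter: bool = False
) -> DynamicFCSet:
    """Windowed Pearson correlation matrices of one subject.

    Entry (p, q) of matrix j is the correlation of ROI p and ROI q restricted
    to window j.  A ROI that is constant within a window makes the correlation
    undefined; by default this raises, naming subject, ROI and window.  With
    ``jitter=True`` a tiny deterministic perturbation (1e-10) is added
    instead, for degenerate synthetic inputs.
    """
    series = subject.series
    slices = window_slices(series.shape[1], spec)
    n_roi = series.shape[0]
    mats = np.empty((len(slices), n_roi, n_roi))
    for j, sl in enumerate(slices):
        win = series[:, sl]
        sd = win.std(axis=1)
        if np.any(sd == 0):
            if jitter:
                rng = np.random.default_rng(0)
                win = win + 1e-10 * rng.normal(size=win.shape)
            else:
                roi = int(np.flatnonzero(sd == 0)[0])
                raise ValueError(
                    f"subject {subject.subject_id}: ROI {roi} constant in window {j}"
                )
        m = np.corrcoef(win)
        m = np.clip((m + m.T) / 2.0, -1.0, 1.0)
        np.fill_diagonal(m, 1.0)
        mats[j] = m
    return DynamicFCSet(subject.subject_id, mats, spec)


def average_low_order(fc: DynamicFCSet) -> np.ndarray:
    """Element-wise mean of the K windowed matrices (the averaged network)."""
    if fc.matrices.shape[0] < 1:
        raise DimensionError("need at least one window")
    return fc.matrices.mean(axis=0)


def edge_series(fc: DynamicFCSet) -> EdgeSeriesSet:
    """Stack each upper-triangle edge's K windowed correlations into a row."""
    k, n_roi, _ = fc.matrices.shape
    if k < 2:
        raise ConfigurationError("edge series need at least 2 windows")
    iu = np.triu_indices(n_roi, k=1)
    series = fc.matrices[:, iu[0], iu[1]].T  # (E, K)
    return EdgeSeriesSet(fc.subject_id, edge_pairs(n_roi), series)


def fit_edge_clustering(
    training: list[EdgeSeriesSet],
    n_clusters: int = 300,
    seed: int = 0,
    n_init: int = 10,
) -> EdgeClustering:
    """Group edges by k-means on their concatenated training edge series.

    Each edge's feature vector is its K-length series concatenated across all
    training subjects, so edges that co-fluctuate the same way across the
    cohort land in the same cluster.  The assignment is fitted once on
    training subjects and then applied unchanged to every subject.
    """
    if not training:
        raise ConfigurationError("need at least one training subject")
    edge_index = training[0].edge_index
    for es in training[1:]:
        if es.edge_index != edge_index:
            raise ConfigurationError("training edge indices differ between subjects")
    features = np.hstack([es.series for es in training])  # (E, K * n_train)
    n_edges = features.shape[0]
    if n_clusters > n_edges:
        raise ConfigurationError(f"n_clusters {n_clusters} exceeds edge count {n_edges}")
    if n_clusters == n_edges:
        labels = np.arange(n_edges)
    else:
        labels = None
        for attempt in range(3):
            km = KMeans(
                n_clusters=n_clusters, n_init=n_init, random_state=seed + attempt
            ).fit(features)
            cand = km.labels_
            if np.unique(cand).size == n_clusters:
                labels = cand
                break
        if labels is None:
            raise RuntimeError("k-means left empty clusters after reseeded retries")
    return EdgeClustering(
        n_clusters=n_clusters,
        assignment=np.asarray(labels),
        edge_index=list(edge_index),
        fitted_on=[es.subject_id for es in training],
        seed=seed,
    )


def cluster_mean_series(edges: EdgeSeriesSet, clustering: EdgeClustering) -> np.ndarray:
    """(n_clusters, K) matrix of unweighted mean edge series per cluster."""
    if edges.edge_index != clustering.edge_index:
        raise ConfigurationError("clustering does not cover this subject's edges")
    out = np.empty((clustering.n_clusters, edges.series.shape[1]))
    for c in range(clustering.n_clusters):
        members = clustering.assignment == c
        if not members.any():
            raise ConfigurationError(f"cluster {c} is empty")
        out[c] = edges.series[members].mean(axis=0)
    return out


def high_order_fc(edges: EdgeSeriesSet, clustering: EdgeClustering) -> HighOrderNetwork:
    """Cluster-level high-order network of one subject.

    Entry (c, d) is the Pearson correlation between the cluster-mean edge
    series of clusters c and d.  A cluster whose mean series is constant
    across windows has undefined correlations; its off-diagonal entries are
    set to 0 with a warning.
    """
    means = cluster_mean_series(edges, clustering)
    sd = means.std(axis=1)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"{constant.sum()} cluster-mean series constant; correlations set to 0",
            stacklevel=2,
        )
    safe = means.copy()
    safe[constant] = np.random.default_rng(0).normal(size=(constant.sum(), means.shape[1]))
    m = np.corrcoef(safe)
    m[constant, :] = 0.0
    m[:, constant] = 0.0
    m = np.clip((m + m.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(m, 1.0)
    return HighOrderNetwork(edges.subject_id, m)


def full_high_order_fc(edges: EdgeSeriesSet) -> np.ndarray:
    """Unclustered edge x edge high-order matrix — small-n debugging only.

    Materializes the E x E correlation matrix of raw edge series; at the
    study scale (E = 4005) this is what the clustering exists to avoid, so
    this helper refuses more than 500 edges.
    """
    if edges.series.shape[0] > 500:
        raise ConfigurationError("full high-order matrix is a small-n debugging utility")
    return np.corrcoef(edges.series)


def save_edge_clustering(clustering: EdgeClustering, directory) -> Path:
    """Serialize as CSV (p, q, cluster) plus JSON metadata; returns the CSV path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    csv_path = directory / "edge_clusters.csv"
    with open(csv_path, "w") as fh:
        fh.write("p,q,cluster\n")
        for (p, q), c in zip(clustering.edge_index, clustering.assignment):
            fh.write(f"{p},{q},{int(c)}\n")
    meta = {
        "n_clusters": clustering.n_clusters,
        "seed": clustering.seed,
        "fitted_on": clustering.fitted_on,
    }
    (directory / "edge_clusters.json").write_text(json.dumps(meta, indent=1))
    return csv_path
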