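"""L0 sparse representation: feature ranking, forward selection, classification.

Two L0-penalized least-squares problems drive the modelling stage:

* feature selection:   phi_hat = argmin ||l - F phi||^2 + eta * ||phi||_0
  with labels l in {-1, +1}, samples-by-features design F and eta = 0.1;
  features are ranked by |phi_hat| and a cross-validated sequential forward
  selection over the ranked list picks the working subset;
* classification (SRC): beta_hat = argmin ||f - D beta||^2 + gamma * ||beta||_0
  with gamma = 0.05, where the dictionary D holds the training subjects as
  columns.  The test subject is assigned the class whose support coefficients
  reconstruct it with the smallest residual r_c = ||f - D delta_c(beta_hat)||.

Exact L0 minimization is NP-hard; both problems are solved with a greedy
orthogonal-matching scheme: repeatedly add the column most correlated with
the current residual, refit least squares on the support, and stop when the
best candidate's squared-residual reduction falls below the penalty.  On
orthonormal designs this equals hard thresholding of F^T l and hence the
exact L0 solution; on tiny general designs it is checked against exhaustive
search in the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from sklearn.model_selection import StratifiedKFold

from .errors import ConfigurationError

_EPS = 1e-12


@dataclass
class SparseSolution:
    coefficients: np.ndarray
    support: list[int]
    residual_norm: float
    penalty: float


@dataclass
class FeatureRanking:
    """Feature indices by descending importance |phi_hat|; ties by index."""

    order: np.ndarray
    coefficients: np.ndarray


@dataclass
class SelectedSubset:
    features: list[int]
    cv_metric: float
    history: list[tuple[int, float]] = field(default_factory=list)


@dataclass
class ClassifierOutput:
    subject_id: str
    predicted_label: object
    residuals: dict
    score: float


class Standardizer:
    """Column z-scoring with training statistics; constant columns pass through."""

    def __init__(self, x: np.ndarray):
        x = np.asarray(x, dtype=float)
        self.mean_ = x.mean(axis=0)
        sd = x.std(axis=0)
        self.sd_ = np.where(sd > 0, sd, 1.0)

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=float) - self.mean_) / self.sd_


def l0_solve(
    design: np.ndarray, target: np.ndarray, penalty: float, nonnegative: bool = False
) -> SparseSolution:
    """Greedy orthogonal-matching solution of min ||l - F phi||^2 + penalty*||phi||_0.

    Candidate choice is by |F_j^T r| on unit-normalized columns; after each
    addition the coefficients are refit by least squares on the support.  The
    iteration stops when adding the best candidate would reduce the squared
    residual by less than ``penalty``, or when the support reaches
    min(n_samples - 1, n_features).  Zero-variance (all-zero) columns are
    excluded with a warning.

    With ``nonnegative=True`` candidates are chosen by signed correlation and
    coefficients are refit by nonnegative least squares.  The SRC classifier
    uses this mode: a training subject expresses similarity to a test subject
    only through a positive weight, so centered classes that differ by a mean
    shift (and are therefore antipodal directions) stay separable.
    """
    design = np.asarray(design, dtype=float)
    target = np.asarray(target, dtype=float).ravel()
    if design.shape[0] != target.size:
        raise ConfigurationError("design rows must match target length")
    if penalty < 0:
        raise ConfigurationError("penalty must be >= 0")
    n_samples, n_features = design.shape
    norms = np.linalg.norm(design, axis=0)
    dead = norms <= _EPS
    if dead.any():
        warnings.warn(f"{dead.sum()} zero-variance columns excluded", stacklevel=2)
    unit = np.where(dead, 1.0, norms)
    max_support = min(n_samples - 1, n_features)

    support: list[int] = []
    coef = np.zeros(n_features)
    residual = target.copy()
    rss = float(residual @ residual)
    in_support = np.zeros(n_features, dtype=bool)
    while len(support) < max_support:
        corr = design.T @ residual / unit
        if not nonnegative:
            corr = np.abs(corr)
        corr[in_support | dead] = -np.inf
        j = int(np.argmax(corr))
        if not np.isfinite(corr[j]) or (nonnegative and corr[j] <= 0):
            break
        trial = support + [j]
        sub = design[:, trial]
        if nonnegative:
            beta, _ = optimize.nnls(sub, target)
        else:
            beta, *_ = np.linalg.lstsq(sub, target, rcond=None)
        new_resid = target - sub @ beta
        new_rss = float(new_resid @ new_resid)
        if rss - new_rss < penalty:
            break
        support = trial
        in_support[j] = True
        coef = np.zeros(n_features)
        coef[trial] = beta
        residual = new_resid
        rss = new_rss
    return SparseSolution(coef, support, float(np.linalg.norm(residual)), penalty)


def rank_features(
    design: np.ndarray, labels: np.ndarray, penalty: float = 0.1
) -> FeatureRanking:
    """Rank features by descending |phi_hat| of the L0 selection solve.

    ``labels`` must take two values; they are encoded -1/+1 internally and
    the design is z-scored with its own statistics.  Features outside the
    support follow the support in descending |F^T residual|, then ascending
    index.
    """
    design = np.asarray(design, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ConfigurationError(f"need exactly 2 classes, got {classes.size}")
    y = np.where(labels == classes[1], 1.0, -1.0)
    z = Standardizer(design).transform(design)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sol = l0_solve(z, y, penalty)
    importance = np.abs(sol.coefficients)
    residual = y - z @ sol.coefficients
    fallback = np.abs(z.T @ residual)
    fallback[importance > 0] = 0.0
    # lexicographic: support coefficient magnitude, then residual correlation,
    # then ascending index (argsort is stable on the negated keys)
    keys = np.lexsort((np.arange(design.shape[1]), -fallback, -importance))
    return FeatureRanking(order=np.asarray(keys), coefficients=sol.coefficients)


def _src_predict_batch(
    train_x: np.ndarray,
    train_labels: np.ndarray,
    test_x: np.ndarray,
    gamma: float,
    positive_label,
    negative_label,
) -> list[ClassifierOutput]:
    """SRC predictions for a standardized test block (helper, no re-scaling)."""
    dictionary = train_x.T.copy()  # columns = training subjects
    norms = np.linalg.norm(dictionary, axis=0)
    norms = np.where(norms > _EPS, norms, 1.0)
    dictionary = dictionary / norms
    is_pos = train_labels == positive_label
    outputs = []
    for i in range(test_x.shape[0]):
        f = test_x[i]
        sol = l0_solve(dictionary, f, gamma, nonnegative=True)
        coef = sol.coefficients
        resid = {}
        for lab, mask in ((positive_label, is_pos), (negative_label, ~is_pos)):
            masked = np.where(mask, coef, 0.0)
            resid[lab] = float(np.linalg.norm(f - dictionary @ masked))
        r_pos, r_neg = resid[positive_label], resid[negative_label]
        score = (r_neg - r_pos) / (r_neg + r_pos + _EPS)
        predicted = positive_label if r_pos < r_neg else negative_label
        outputs.append(ClassifierOutput(f"test-{i}", predicted, resid, score))
    return outputs


def src_classify(
    train_x: np.ndarray,
    train_labels: np.ndarray,
    test_x: np.ndarray,
    gamma: float = 0.05,
    positive_label="DNR",
    negative_label=None,
) -> list[ClassifierOutput]:
    """Sparse-representation classification of test subjects.

    Features are z-scored with training statistics, training subjects become
    unit-norm dictionary columns, and each test subject is L0-sparse coded
    against the dictionary.  The class whose support columns reconstruct the
    test vector with smaller residual wins; ties go to the negative
    (majority) class.  ``score`` = (r_neg - r_pos)/(r_neg + r_pos + eps) is a
    continuous DNR-likeness score for ROC analysis.
    """
    train_x = np.atleast_2d(np.asarray(train_x, dtype=float))
    test_x = np.atleast_2d(np.asarray(test_x, dtype=float))
    train_labels = np.asarray(train_labels)
    classes = set(train_labels.tolist())
    if positive_label not in classes:
        raise ConfigurationError(f"no training subjects of class {positive_label!r}")
    rest = sorted(classes - {positive_label}, key=str)
    if negative_label is None:
        if len(rest) != 1:
            raise ConfigurationError("negative_label ambiguous; pass it explicitly")
        negative_label = rest[0]
    if negative_label not in classes:
        raise ConfigurationError(f"no training subjects of class {negative_label!r}")
    scaler = Standardizer(train_x)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return _src_predict_batch(
            scaler.transform(train_x),
            train_labels,
            scaler.transform(test_x),
            gamma,
            positive_label,
            negative_label,
        )


def _cv_accuracy(
    x: np.ndarray,
    labels: np.ndarray,
    feature_idx: list[int],
    folds: int,
    seed: int,
    gamma: float,
    positive_label,
) -> float:
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    correct = 0
    sub = x[:, feature_idx]
    for train_ix, test_ix in skf.split(sub, labels):
        preds = src_classify(
            sub[train_ix], labels[train_ix], sub[test_ix], gamma, positive_label
        )
        correct += sum(p.predicted_label == t for p, t in zip(preds, labels[test_ix]))
    return correct / len(labels)


def forward_select(
    train_x: np.ndarray,
    train_labels: np.ndarray,
    ranking: FeatureRanking,
    folds: int = 10,
    max_rank: int = 100,
    init: int = 5,
    seed: int = 0,
    gamma: float = 0.05,
    positive_label="DNR",
) -> SelectedSubset:
    """Cross-validated sequential forward selection over a ranked feature list.

    The top ``init`` ranked features seed the subset; candidates ranked
    ``init+1`` .. ``max_rank`` are then tried in rank order and kept only if
    they strictly improve the stratified ``folds``-fold CV accuracy of the
    SRC classifier (ties favour the smaller subset).  Returns the best subset
    with its CV accuracy and the full (subset size, accuracy) history.
    """
    train_x = np.asarray(train_x, dtype=float)
    train_labels = np.asarray(train_labels)
    n = len(train_labels)
    if folds > n:
        raise ConfigurationError(f"folds {folds} exceeds training size {n}")
    max_rank = min(max_rank, train_x.shape[1])
    init = min(init, max_rank)
    current = [int(i) for i in ranking.order[:init]]
    best = _cv_accuracy(train_x, train_labels, current, folds, seed, gamma, positive_label)
    history = [(len(current), best)]
    for rank_pos in range(init, max_rank):
        candidate = int(ranking.order[rank_pos])
        trial = current + [candidate]
        metric = _cv_accuracy(
            train_x, train_labels, trial, folds, seed, gamma, positive_label
        )
        history.append((len(trial), metric))
        if metric > best:
            best = metric
            current = trial
    return SelectedSubset(features=current, cv_metric=best, history=history)
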