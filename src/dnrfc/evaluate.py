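"""Cohort splitting, DNR labelling, screening and final metrics.

DNR (delayed neurocognitive recovery) is diagnosed from a neuropsychological
battery: for each test, the patient's baseline-minus-postoperative change is
compared to the control group's changes as a Z-score, and a patient is DNR
when two or more tests exceed Z = 1.96.  Model evaluation uses a stratified
2:1 train/test split (74 subjects -> 49 train / 25 test), per-feature
two-sample t-tests, unsupervised 2-group Ward clustering agreement, and
AUC / accuracy / sensitivity / specificity with DNR as the positive class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage

from .cohort import DNR, NON_DNR
from .errors import ConfigurationError
from .sparse import ClassifierOutput


@dataclass(frozen=True)
class SplitSpec:
    train_fraction: float = 2.0 / 3.0
    stratified: bool = True
    seed: int = 0


@dataclass
class ConfusionCounts:
    tp: int
    fn: int
    tn: int
    fp: int


@dataclass
class NeuroScorePanel:
    """Per-test change scores: patient delta and control deltas (baseline - postop)."""

    patient_deltas: dict  # test name -> float
    control_deltas: dict  # test name -> array of floats


def _largest_remainder(counts: np.ndarray, total_train: int, fraction: float) -> np.ndarray:
    ideal = counts * fraction
    base = np.floor(ideal).astype(int)
    short = total_train - base.sum()
    if short > 0:
        # rounding kills float noise so exact remainder ties are real ties,
        # then ties break toward the larger class: the minority keeps test members
        remainders = np.round(ideal - base, 9)
        order = np.lexsort((-counts, -remainders))
        for i in order[:short]:
            base[i] += 1
    return base


def split_cohort(labels, spec: SplitSpec = SplitSpec()):
    """Stratified 2:1 train/test split with largest-remainder per-class rounding.

    Returns (train_indices, test_indices); at the study composition
    (16 DNR / 58 non-DNR) this yields 49 train and 25 test subjects.  Classes
    with fewer than 3 members cannot be stratified; a warning is issued and a
    global split is used.
    """
    labels = np.asarray(labels)
    n = len(labels)
    if n < 3:
        raise ConfigurationError("need at least 3 subjects to split")
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 2:
        raise ConfigurationError("both classes must be present")
    total_train = int(round(n * spec.train_fraction))
    rng = np.random.default_rng(spec.seed)
    if spec.stratified and counts.min() >= 3:
        per_class = _largest_remainder(counts, total_train, spec.train_fraction)
        train = []
        for cls, n_train in zip(classes, per_class):
            members = np.flatnonzero(labels == cls)
            rng.shuffle(members)
            train.extend(members[:n_train])
    else:
        if spec.stratified:
            warnings.warn("a class has < 3 members; falling back to a global split",
                          stacklevel=2)
        perm = rng.permutation(n)
        train = list(perm[:total_train])
    train = np.sort(np.asarray(train, dtype=int))
    mask = np.zeros(n, dtype=bool)
    mask[train] = True
    return train, np.flatnonzero(~mask)


def dnr_label(panel: NeuroScorePanel, z_threshold: float = 1.96, min_tests: int = 2) -> str:
    """Z-score diagnosis: DNR iff Z > threshold on ``min_tests`` or more tests.

    Per test, Z = (patient delta - mean control delta) / sd(control delta),
    with delta = baseline - postoperative score, oriented so positive delta
    means decline.  Only exceedances in the decline direction count.
    """
    exceed = 0
    for test, patient_delta in panel.patient_deltas.items():
        if test not in panel.control_deltas:
            raise ConfigurationError(f"no control distribution for test {test!r}")
        ctrl = np.asarray(panel.control_deltas[test], dtype=float)
        if ctrl.size < 2:
            raise ConfigurationError(f"test {test!r}: need >= 2 controls")
        sd = ctrl.std(ddof=1)
        if sd == 0:
            raise ConfigurationError(f"test {test!r}: zero control standard deviation")
        z = (patient_delta - ctrl.mean()) / sd
        if z > z_threshold:
            exceed += 1
    return DNR if exceed >= min_tests else NON_DNR


def read_neuro_panels(path):
    """Read neuropsychological panels from CSV.

    Columns: subject_id, test, baseline, postop, group — where group is
    'patient' or 'control'.  Returns {subject_id: NeuroScorePanel} with every
    patient sharing the pooled control distributions.
    """
    df = pd.read_csv(path)
    required = {"subject_id", "test", "baseline", "postop", "group"}
    if not required.issubset(df.columns):
        raise ConfigurationError(f"panel CSV needs columns {sorted(required)}")
    df = df.assign(delta=df["baseline"] - df["postop"])
    controls = df[df["group"] == "control"]
    control_deltas = {t: g["delta"].to_numpy() for t, g in controls.groupby("test")}
    panels = {}
    for sid, g in df[df["group"] == "patient"].groupby("subject_id"):
        panels[sid] = NeuroScorePanel(
            patient_deltas=dict(zip(g["test"], g["delta"])),
            control_deltas=control_deltas,
        )
    return panels


def feature_ttests(features: np.ndarray, labels, equal_var: bool = True) -> pd.DataFrame:
    """Two-sample t-test per feature column (pooled-variance by default).

    Returns a DataFrame with columns t and p; features with zero pooled
    variance get t = 0, p = 1 with a warning.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ConfigurationError("need exactly 2 classes")
    a = features[labels == classes[0]]
    b = features[labels == classes[1]]
    if len(a) < 2 or len(b) < 2:
        raise ConfigurationError("need >= 2 subjects per class")
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(a, b, axis=0, equal_var=equal_var)
    bad = ~np.isfinite(t)
    if bad.any():
        warnings.warn(f"{bad.sum()} features with zero pooled variance; p set to 1",
                      stacklevel=2)
        t = np.where(bad, 0.0, t)
        p = np.where(bad, 1.0, p)
    return pd.DataFrame({"t": t, "p": p})


def significance_counts(ttests: pd.DataFrame, thresholds=(0.05, 0.01)) -> dict:
    return {thr: int((ttests["p"] < thr).sum()) for thr in thresholds}


def clustering_agreement(features: np.ndarray, labels, k: int = 2) -> int:
    """Agreement between unsupervised Ward 2-group clustering and true labels.

    Features are z-scored, clustered hierarchically (Ward linkage, Euclidean)
    and cut at ``k`` groups; agreement is the maximum, over assignments of
    cluster identities to classes, of the number of correctly grouped
    subjects.  Degenerate (all-identical) features return the majority count.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    n = len(labels)
    if n < k:
        raise ConfigurationError("need at least k subjects")
    _, counts = np.unique(labels, return_counts=True)
    majority = int(counts.max())
    sd = features.std(axis=0)
    keep = sd > 0
    if not keep.any():
        return majority
    z = (features[:, keep] - features[:, keep].mean(axis=0)) / sd[keep]
    assign = fcluster(linkage(z, method="ward"), t=k, criterion="maxclust")
    classes = np.unique(labels)
    if k != 2 or classes.size != 2:
        raise ConfigurationError("agreement defined for 2 clusters vs 2 classes")
    direct = int(((assign == 1) == (labels == classes[0])).sum())
    return max(direct, n - direct)


def confusion_from_outputs(outputs: list[ClassifierOutput], truth) -> ConfusionCounts:
    truth = np.asarray(truth)
    pred = np.asarray([o.predicted_label for o in outputs])
    tp = int(np.sum((pred == DNR) & (truth == DNR)))
    fn = int(np.sum((pred == NON_DNR) & (truth == DNR)))
    tn = int(np.sum((pred == NON_DNR) & (truth == NON_DNR)))
    fp = int(np.sum((pred == DNR) & (truth == NON_DNR)))
    return ConfusionCounts(tp, fn, tn, fp)


def metrics_from_confusion(counts: ConfusionCounts) -> dict:
    n = counts.tp + counts.fn + counts.tn + counts.fp
    acc = (counts.tp + counts.tn) / n
    sen = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else float("nan")
    spe = counts.tn / (counts.tn + counts.fp) if counts.tn + counts.fp else float("nan")
    return {"ACC": acc, "SEN": sen, "SPE": spe}


def rank_auc(scores, positive_mask) -> float:
    """Mann-Whitney AUC of scores for the positive class, ties credited 0.5."""
    scores = np.asarray(scores, dtype=float)
    positive_mask = np.asarray(positive_mask, dtype=bool)
    n_pos = int(positive_mask.sum())
    n_neg = int((~positive_mask).sum())
    if n_pos == 0 or n_neg == 0:
        raise ConfigurationError("AUC needs both classes in the truth")
    ranks = stats.rankdata(scores)  # average ranks give 0.5 tie credit
    u = ranks[positive_mask].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def roc_points(scores, positive_mask) -> pd.DataFrame:
    """ROC curve as (threshold, FPR, TPR) rows, thresholds descending."""
    scores = np.asarray(scores, dtype=float)
    positive_mask = np.asarray(positive_mask, dtype=bool)
    thresholds = np.concatenate(([np.inf], np.unique(scores)[::-1]))
    rows = []
    n_pos = positive_mask.sum()
    n_neg = (~positive_mask).sum()
    for thr in thresholds:
        pred = scores >= thr
        tpr = np.sum(pred & positive_mask) / n_pos
        fpr = np.sum(pred & ~positive_mask) / n_neg
        rows.append((thr, fpr, tpr))
    return pd.DataFrame(rows, columns=["threshold", "FPR", "TPR"])


def classification_metrics(outputs: list[ClassifierOutput], truth) -> dict:
    """AUC/ACC/SEN/SPE plus ROC points, with DNR as the positive class."""
    truth = np.asarray(truth)
    counts = confusion_from_outputs(outputs, truth)
    metrics = metrics_from_confusion(counts)
    scores = np.asarray([o.score for o in outputs])
    pos = truth == DNR
    metrics["AUC"] = rank_auc(scores, pos)
    metrics["confusion"] = counts
    metrics["roc"] = roc_points(scores, pos)
    return metrics
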