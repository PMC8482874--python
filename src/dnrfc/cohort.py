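"""Synthetic two-class cohorts of ROI time series.

The study cohort this generator emulates is a surgical population of older
adults, 16 of whom showed delayed neurocognitive recovery (DNR) and 58 of whom
did not, each scanned at rest and reduced to 90 regional (AAL-90) BOLD time
series of 115 usable timepoints (TR = 3 s).  The raw scans are not released,
so every downstream stage is exercised on draws from this generator instead.

Signal model
------------
Each subject's series is a zero-mean multivariate Gaussian AR(1) process:

    x_t = a * x_{t-1} + e_t,   e_t ~ N(0, noise_sd**2 * R)

with smoothing coefficient ``a`` = 0.3 to mimic the temporal autocorrelation
of band-passed BOLD.  ``R`` is a correlation matrix built from shared low-rank
loadings (so both classes have a common network backbone).  DNR subjects
receive an additional correlation of ``effect_size`` on ``n_effect_edges``
designated ROI pairs — the "more connections among ROIs" phenotype — and,
when ``dynamic_effect`` > 0, that increment is modulated blockwise over 3-5
equal-length stationary segments, which makes the *edge time series* (the
windowed-correlation trajectories) class-separable and hence gives the
high-order network something to detect.  Edited matrices are projected back
to the nearest valid correlation matrix before sampling.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._utils import edge_pairs, nearest_correlation
from .errors import ConfigurationError, DataFormatError

DNR = "DNR"
NON_DNR = "non-DNR"
_LABELS = (DNR, NON_DNR)

_AR_COEF = 0.3
_BURN_IN = 25
_CORR_CAP = 0.97


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of one synthetic cohort draw.

    Defaults mirror the emulated study: 16 DNR vs 58 non-DNR subjects,
    90 ROIs x 115 timepoints at TR = 3 s.  ``effect_size`` is the added
    within-class correlation on the designated effect edges;
    ``dynamic_effect`` the relative amplitude of its blockwise temporal
    modulation in the DNR class.
    """

    n_dnr: int = 16
    n_control: int = 58
    n_roi: int = 90
    n_timepoints: int = 115
    tr_seconds: float = 3.0
    effect_size: float = 0.4
    dynamic_effect: float = 0.3
    noise_sd: float = 1.0
    n_effect_edges: int = 50
    seed: int = 0

    def validate(self) -> None:
        if self.n_roi < 3:
            raise ConfigurationError("n_roi must be >= 3")
        if self.n_timepoints < 2:
            raise ConfigurationError("n_timepoints must be >= 2")
        if self.n_dnr < 0 or self.n_control < 0 or self.n_dnr + self.n_control == 0:
            raise ConfigurationError("need a nonempty cohort")
        max_edges = self.n_roi * (self.n_roi - 1) // 2
        if not 0 <= self.n_effect_edges <= max_edges:
            raise ConfigurationError(
                f"n_effect_edges must be in [0, {max_edges}], got {self.n_effect_edges}"
            )
        if self.effect_size < 0 or self.dynamic_effect < 0:
            raise ConfigurationError("effect_size and dynamic_effect must be >= 0")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be > 0")
        if self.tr_seconds <= 0:
            raise ConfigurationError("tr_seconds must be > 0")


@dataclass
class SubjectSeries:
    """One subject's ROI x time signal matrix with identity and class label."""

    subject_id: str
    label: str
    series: np.ndarray  # shape (n_roi, n_timepoints)

    def __post_init__(self) -> None:
        self.series = np.asarray(self.series, dtype=float)
        if self.series.ndim != 2:
            raise DataFormatError(f"{self.subject_id}: series must be 2-D")
        if self.label not in _LABELS:
            raise DataFormatError(
                f"{self.subject_id}: label must be one of {_LABELS}, got {self.label!r}"
            )


@dataclass
class GeneratedCohort:
    """A cohort draw plus the ground truth used to generate it."""

    subjects: list[SubjectSeries]
    effect_edges: list[tuple[int, int]] = field(default_factory=list)
    base_correlation: np.ndarray | None = None


def _base_correlation(n_roi: int, rng: np.random.Generator) -> np.ndarray:
    """Shared network backbone: blend of a low-rank loading structure and identity."""
    rank = max(2, n_roi // 15)
    loadings = rng.normal(size=(n_roi, rank))
    s = loadings @ loadings.T
    d = np.sqrt(np.diag(s))
    corr = s / np.outer(d, d)
    base = 0.35 * corr + 0.65 * np.eye(n_roi)
    np.fill_diagonal(base, 1.0)
    return base


def _pick_effect_edges(
    base: np.ndarray, n_effect_edges: int, rng: np.random.Generator
) -> list[tuple[int, int]]:
    """Prefer weakly connected pairs so the added correlation stays in range."""
    pairs = edge_pairs(base.shape[0])
    strength = np.array([abs(base[p, q]) for p, q in pairs])
    order = np.argsort(strength, kind="stable")
    weak = order[strength[order] < 0.3]
    pool = weak if weak.size >= n_effect_edges else order[:n_effect_edges]
    chosen = rng.choice(pool, size=n_effect_edges, replace=False)
    return [pairs[i] for i in chosen]


def _with_effect(
    base: np.ndarray, edges: list[tuple[int, int]], delta: float, n_iter: int = 30
) -> np.ndarray:
    """Add ``delta`` on the designated edges, keeping the matrix a correlation.

    A single PSD projection shrinks the edit, so the two constraints (PSD
    with unit diagonal; designated edges at their target values) are enforced
    by alternating projections, which converges close to their intersection
    for the moderate edits used here.
    """
    ii = np.array([p for p, _ in edges])
    jj = np.array([q for _, q in edges])
    target = np.clip(base[ii, jj] + delta, -_CORR_CAP, _CORR_CAP)
    mat = base.copy()
    for _ in range(n_iter):
        mat[ii, jj] = target
        mat[jj, ii] = target
        vals, vecs = np.linalg.eigh(mat)
        if vals[0] >= -1e-12:
            break
        mat = (vecs * np.clip(vals, 0.0, None)) @ vecs.T
        d = np.sqrt(np.clip(np.diag(mat), 1e-12, None))
        mat = mat / np.outer(d, d)
        mat = (mat + mat.T) / 2.0
    np.fill_diagonal(mat, 1.0)
    return nearest_correlation(mat)


def _sample_ar1(
    segment_corrs: list[np.ndarray],
    segment_lengths: list[int],
    noise_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """AR(1) draw with piecewise-stationary innovation covariance."""
    n_roi = segment_corrs[0].shape[0]
    chols = []
    for corr in segment_corrs:
        # tiny ridge guards the Cholesky against clipped-to-zero eigenvalues
        chols.append(np.linalg.cholesky(corr + 1e-8 * np.eye(n_roi)))
    total = sum(segment_lengths)
    x = np.empty((n_roi, total))
    state = chols[0] @ rng.normal(size=n_roi)
    for _ in range(_BURN_IN):
        state = _AR_COEF * state + chols[0] @ rng.normal(size=n_roi)
    t = 0
    for chol, length in zip(chols, segment_lengths):
        innov = chol @ rng.normal(size=(n_roi, length))
        for j in range(length):
            state = _AR_COEF * state + innov[:, j]
            x[:, t] = state
            t += 1
    return noise_sd * x


def _segment_lengths(n_timepoints: int, n_segments: int) -> list[int]:
    base, extra = divmod(n_timepoints, n_segments)
    return [base + (1 if i < extra else 0) for i in range(n_segments)]


def generate_cohort(config: CohortConfig) -> GeneratedCohort:
    """Draw a reproducible two-class cohort of ROI time series.

    Non-DNR subjects are stationary draws from the shared backbone
    correlation; DNR subjects add ``effect_size`` on the designated edges,
    modulated blockwise when ``dynamic_effect`` > 0.  Fixed ``config.seed``
    gives bit-identical output.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    n_total = config.n_dnr + config.n_control
    cohort_rng = np.random.default_rng(ss.spawn(1)[0])
    subject_seeds = ss.spawn(n_total + 1)[1:]

    base = _base_correlation(config.n_roi, cohort_rng)
    effect_edges = (
        _pick_effect_edges(base, config.n_effect_edges, cohort_rng)
        if config.n_effect_edges > 0
        else []
    )
    base = nearest_correlation(base)

    subjects: list[SubjectSeries] = []
    labels = [DNR] * config.n_dnr + [NON_DNR] * config.n_control
    for i, (label, seed_i) in enumerate(zip(labels, subject_seeds)):
        rng = np.random.default_rng(seed_i)
        if label == DNR and config.effect_size > 0 and effect_edges:
            if config.dynamic_effect > 0:
                n_seg = int(rng.integers(3, 6))
                deltas = config.effect_size * (
                    1.0 + config.dynamic_effect * rng.uniform(-1.0, 1.0, size=n_seg)
                )
                corrs = [_with_effect(base, effect_edges, d) for d in deltas]
                lengths = _segment_lengths(config.n_timepoints, n_seg)
            else:
                corrs = [_with_effect(base, effect_edges, config.effect_size)]
                lengths = [config.n_timepoints]
        else:
            corrs = [base]
            lengths = [config.n_timepoints]
        series = _sample_ar1(corrs, lengths, config.noise_sd, rng)
        if np.any(series.std(axis=1) == 0):  # pragma: no cover - Gaussian a.s. varies
            series = series + 1e-10 * rng.normal(size=series.shape)
        subjects.append(SubjectSeries(f"sub-{i + 1:03d}", label, series))
    return GeneratedCohort(subjects, effect_edges, base)


def write_cohort(cohort: GeneratedCohort | list[SubjectSeries], directory) -> Path:
    """Write one TSV per subject (rows = ROIs, no header) plus a CSV manifest.

    Values are written with 17 significant digits so the round trip through
    text reproduces every float64 exactly.  Returns the manifest path.
    """
    subjects = cohort.subjects if isinstance(cohort, GeneratedCohort) else cohort
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = directory / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["subject_id", "label", "path"])
        for subj in subjects:
            fname = f"{subj.subject_id}.tsv"
            np.savetxt(directory / fname, subj.series, fmt="%.17g", delimiter="\t")
            writer.writerow([subj.subject_id, subj.label, fname])
    return manifest


def read_cohort(manifest_path) -> list[SubjectSeries]:
    """Read a cohort back from a manifest written by :func:`write_cohort`."""
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise DataFormatError(f"manifest not found: {manifest_path}")
    subjects: list[SubjectSeries] = []
    n_roi = n_tp = None
    with open(manifest_path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or set(reader.fieldnames) != {
            "subject_id",
            "label",
            "path",
        }:
            raise DataFormatError(
                f"manifest must have header subject_id,label,path: {manifest_path}"
            )
        for row in reader:
            sid = row["subject_id"]
            if row["label"] not in _LABELS:
                raise DataFormatError(f"{sid}: bad label {row['label']!r}")
            path = manifest_path.parent / row["path"]
            if not path.exists():
                raise DataFormatError(f"{sid}: subject file missing: {path}")
            try:
                series = np.loadtxt(path, delimiter="\t", ndmin=2)
            except ValueError as exc:
                raise DataFormatError(f"{sid}: malformed subject file: {exc}") from exc
            if not np.all(np.isfinite(series)):
                raise DataFormatError(f"{sid}: non-finite values in series")
            if n_roi is None:
                n_roi, n_tp = series.shape
            elif series.shape != (n_roi, n_tp):
                raise DataFormatError(
                    f"{sid}: shape {series.shape} differs from cohort shape {(n_roi, n_tp)}"
                )
            subjects.append(SubjectSeries(sid, row["label"], series))
    if not subjects:
        raise DataFormatError(f"manifest lists no subjects: {manifest_path}")
    return subjects
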