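"""Temporal preprocessing of ROI time series.

Covers the per-series steps applied to resting-state BOLD before network
construction: discarding initial volumes acquired before signal equilibrium,
linear detrending, zero-phase band-pass filtering to the canonical
resting-state band (0.01-0.08 Hz), optional nuisance-covariate regression,
and ROI-mean extraction from a labelled 4-D volume.  Spatial preprocessing
(realignment, normalization, smoothing) is assumed done upstream by an
imaging toolchain.

The fixed order is: discard -> detrend + band-pass -> covariate regression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .errors import ConfigurationError, DimensionError


@dataclass(frozen=True)
class PreprocessConfig:
    """Band edges in Hz, repetition time in seconds, volume discard count."""

    n_discard: int = 5
    band_low_hz: float = 0.01
    band_high_hz: float = 0.08
    tr_seconds: float = 3.0
    detrend: bool = True

    def validate(self) -> None:
        nyquist = 0.5 / self.tr_seconds
        if not 0 < self.band_low_hz < self.band_high_hz < nyquist:
            raise ConfigurationError(
                f"band ({self.band_low_hz}, {self.band_high_hz}) Hz must satisfy "
                f"0 < low < high < Nyquist ({nyquist:.4g} Hz at TR={self.tr_seconds}s)"
            )
        if self.n_discard < 0:
            raise ConfigurationError("n_discard must be >= 0")


def discard_initial(series: np.ndarray, n_discard: int = 5) -> np.ndarray:
    """Drop the first ``n_discard`` timepoints (columns) of a ROI x time matrix."""
    series = np.asarray(series, dtype=float)
    if n_discard < 0:
        raise ConfigurationError("n_discard must be >= 0")
    if series.shape[1] <= n_discard:
        raise DimensionError(
            f"cannot discard {n_discard} of {series.shape[1]} timepoints"
        )
    return series[:, n_discard:].copy()


def detrend_bandpass(series: np.ndarray, config: PreprocessConfig) -> np.ndarray:
    """Remove each ROI's linear trend, then band-pass with zero phase.

    The filter is a 4th-order Butterworth applied forward-backward
    (``sosfiltfilt``), so the passband is traversed twice but no phase is
    introduced — window alignment across ROIs is preserved.
    """
    config.validate()
    series = np.asarray(series, dtype=float)
    if series.shape[1] < 8:
        raise DimensionError("need at least 8 timepoints to filter")
    out = signal.detrend(series, axis=1, type="linear") if config.detrend else series
    fs = 1.0 / config.tr_seconds
    sos = signal.butter(
        4, [config.band_low_hz, config.band_high_hz], btype="bandpass", fs=fs, output="sos"
    )
    return signal.sosfiltfilt(sos, out, axis=1)


def regress_covariates(series: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    """Replace each ROI row by its least-squares residual against covariates.

    An intercept is always included, so output rows are demeaned.  Rank
    deficient designs fall back to the pseudo-inverse with a warning.
    """
    series = np.asarray(series, dtype=float)
    covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
    if covariates.shape[1] != series.shape[1]:
        raise DimensionError(
            f"covariates have {covariates.shape[1]} timepoints, series has {series.shape[1]}"
        )
    design = np.column_stack([np.ones(series.shape[1]), covariates.T])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        warnings.warn("rank-deficient covariates; using pseudo-inverse", stacklevel=2)
    beta = np.linalg.pinv(design) @ series.T
    return series - (design @ beta).T


def extract_roi_means(volume4d: np.ndarray, atlas: np.ndarray) -> np.ndarray:
    """Average voxels per atlas label at each timepoint.

    ``volume4d`` has shape (x, y, z, t); ``atlas`` is an integer label volume
    on the same grid with positive labels.  Returns an (n_labels, t) matrix,
    rows ordered by ascending label.
    """
    volume4d = np.asarray(volume4d, dtype=float)
    atlas = np.asarray(atlas)
    if volume4d.ndim != 4:
        raise DimensionError("volume4d must be 4-D (x, y, z, t)")
    if atlas.shape != volume4d.shape[:3]:
        raise DimensionError(
            f"atlas grid {atlas.shape} does not match volume grid {volume4d.shape[:3]}"
        )
    labels = np.unique(atlas)
    labels = labels[labels > 0]
    if labels.size == 0:
        raise ValueError("atlas contains no positive labels")
    flat = volume4d.reshape(-1, volume4d.shape[3])
    flat_atlas = atlas.reshape(-1)
    rows = []
    for lab in labels:
        mask = flat_atlas == lab
        if not mask.any():  # pragma: no cover - unique() guarantees presence
            raise ValueError(f"label {lab} has no voxels")
        rows.append(flat[mask].mean(axis=0))
    return np.vstack(rows)


def load_nifti_pair(volume_path, atlas_path):
    """Load a 4-D NIfTI and its integer atlas as arrays (real-data path)."""
    import nibabel as nib

    vol = np.asanyarray(nib.load(str(volume_path)).dataobj, dtype=float)
    atl = np.asanyarray(nib.load(str(atlas_path)).dataobj)
    return vol, np.rint(atl).astype(int)


def preprocess_subject(series: np.ndarray, config: PreprocessConfig) -> np.ndarray:
    """Apply the full fixed-order temporal pipeline to one ROI x time matrix."""
    out = discard_initial(series, config.n_discard) if config.n_discard else np.asarray(series, float)
    return detrend_bandpass(out, config)
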