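"""Rolling-window feature extraction and Fisher-criterion selection.

The five-step procedure:

1. **Cleaning** — each session is compacted by deleting missing
   samples (no interpolation); sessions with more than 80% missing are
   rejected.
2. **Segmentation** — the cleaned signal is tiled into consecutive
   non-overlapping windows (default 1024 samples); the trailing
   remainder is discarded.
3. **Slope estimation** — each window's wavelet spectral slope is
   estimated, giving a sessions x windows slope matrix per subject.
4. **Session averaging** — the per-window mean over sessions yields
   one feature vector per subject; stacking subjects gives the feature
   matrix.
5. **Selection** — window positions are ranked by Fisher's criterion
   F = (mu_case - mu_control)^2 / (var_case + var_control) and the top
   m (default 6) are kept.

Windows are cut from the *compacted* signal, so sample times are not
uniform within a window wherever data were removed; this is inherent
to compaction-based cleaning and documented rather than corrected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .distvar import DISTANCE_VARIANCE, EnergyEstimator
from .dwt import DomainError
from .signal_io import Signal, TimeSeriesRecording
from .spectra import SpectrumError, estimate_hurst

logger = logging.getLogger(__name__)

REJECTED = "REJECTED"


@dataclass
class SlopeMatrix:
    """Per-subject sessions x windows matrix of window spectral slopes."""

    participant_id: str
    values: np.ndarray  # (sessions, windows)
    mask: np.ndarray  # True where the window's slope failed
    window_size: int

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.mask = np.atleast_2d(np.asarray(self.mask, dtype=bool))
        if self.values.shape != self.mask.shape:
            raise DomainError("values and mask shapes differ")


@dataclass
class FeatureMatrix:
    """Subjects x windows matrix of session-averaged slopes with labels."""

    subject_ids: list[str]
    X: np.ndarray
    y: np.ndarray  # 1 = case, 0 = control
    window_size: int

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.y = np.asarray(self.y, dtype=int)
        if self.X.shape[0] != self.y.size or self.X.shape[0] != len(self.subject_ids):
            raise DomainError("rows of X, y and subject_ids must align")

    @property
    def n_features(self) -> int:
        return self.X.shape[1]


@dataclass
class FisherScores:
    """Fisher criterion per window position and the selected indices."""

    scores: np.ndarray
    selected: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.selected = np.asarray(self.selected, dtype=int)


def clean_signal(signal: Signal, max_missing_fraction: float = 0.8) -> np.ndarray | None:
    """Compact a signal by deleting masked samples, preserving order.

    Returns the cleaned vector, or None (rejection) when the missing
    fraction exceeds ``max_missing_fraction``.
    """
    frac = signal.missing_fraction
    if frac > max_missing_fraction:
        logger.info(
            "session %d rejected: %.1f%% missing > %.0f%% limit",
            signal.session_index, 100 * frac, 100 * max_missing_fraction,
        )
        return None
    return signal.values[~signal.missing_mask].copy()


def segment(cleaned: np.ndarray, window_size: int = 1024) -> list[np.ndarray]:
    """Tile a cleaned signal into floor(N / window_size) consecutive
    non-overlapping windows, discarding the remainder."""
    if window_size < 64 or window_size & (window_size - 1):
        raise DomainError(f"window_size must be a power of two >= 64, got {window_size}")
    n = len(cleaned)
    k = n // window_size
    if k == 0:
        logger.warning("signal of length %d shorter than window %d", n, window_size)
        return []
    return [
        np.asarray(cleaned[i * window_size : (i + 1) * window_size], dtype=float)
        for i in range(k)
    ]


def slope_matrix(
    recording: TimeSeriesRecording,
    window_size: int = 1024,
    wavelet_name: str = "db6",
    n_levels: int = 5,
    estimator: EnergyEstimator = DISTANCE_VARIANCE,
    max_missing_fraction: float = 0.8,
) -> SlopeMatrix | None:
    """Per-window spectral slopes for every retained session.

    Sessions failing the cleaning rule are dropped; windows whose
    spectrum is degenerate (e.g. constant data) are masked.  Sessions
    of unequal cleaned length are aligned by truncating to the minimum
    window count.  Returns None when no session survives.
    """
    rows, masks = [], []
    for sig in recording.sessions:
        cleaned = clean_signal(sig, max_missing_fraction)
        if cleaned is None:
            continue
        slopes, mask = [], []
        for window in segment(cleaned, window_size):
            try:
                fit = estimate_hurst(
                    window, wavelet_name=wavelet_name, n_levels=n_levels,
                    estimator=estimator,
                )
                slopes.append(fit.slope)
                mask.append(False)
            except (SpectrumError, DomainError) as exc:
                logger.info(
                    "window masked (%s session %d): %s",
                    recording.participant_id, sig.session_index, exc,
                )
                slopes.append(np.nan)
                mask.append(True)
        if slopes:
            rows.append(slopes)
            masks.append(mask)
    if not rows:
        logger.warning("subject %s rejected: no usable session", recording.participant_id)
        return None
    k = min(len(r) for r in rows)
    if k == 0:
        logger.warning("subject %s rejected: sessions shorter than one window",
                       recording.participant_id)
        return None
    values = np.array([r[:k] for r in rows])
    mask = np.array([m[:k] for m in masks])
    return SlopeMatrix(
        participant_id=recording.participant_id,
        values=values, mask=mask, window_size=window_size,
    )


def average_sessions(matrix: SlopeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Mean slope across sessions for each window position.

    Masked entries are excluded from the mean; a window position with
    no unmasked session yields a masked feature (NaN).  Returns
    (means, feature_mask).
    """
    sums = np.where(matrix.mask, 0.0, matrix.values).sum(axis=0)
    counts = (~matrix.mask).sum(axis=0)
    feature_mask = counts == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(feature_mask, np.nan, sums / np.maximum(counts, 1))
    return means, feature_mask


def build_feature_matrix(
    recordings: list[TimeSeriesRecording],
    window_size: int = 1024,
    wavelet_name: str = "db6",
    n_levels: int = 5,
    estimator: EnergyEstimator = DISTANCE_VARIANCE,
    max_missing_fraction: float = 0.8,
) -> FeatureMatrix:
    """Steps 1-4 for a whole cohort.

    Subjects are aligned by truncating every feature vector to the
    cohort-wide minimum window count; columns that are masked for every
    subject are dropped.
    """
    ids, rows, labels = [], [], []
    for rec in recordings:
        sm = slope_matrix(
            rec, window_size=window_size, wavelet_name=wavelet_name,
            n_levels=n_levels, estimator=estimator,
            max_missing_fraction=max_missing_fraction,
        )
        if sm is None:
            continue
        means, _ = average_sessions(sm)
        ids.append(rec.participant_id)
        rows.append(means)
        labels.append(1 if rec.group == "case" else 0)
    if not rows:
        raise DomainError("no subject survived cleaning")
    k = min(len(r) for r in rows)
    X = np.array([r[:k] for r in rows])
    keep = ~np.all(np.isnan(X), axis=0)
    if not keep.all():
        logger.info("dropping %d all-masked feature column(s)", int((~keep).sum()))
        X = X[:, keep]
    return FeatureMatrix(
        subject_ids=ids, X=X, y=np.array(labels), window_size=window_size
    )


def fisher_scores(X_cases: np.ndarray, X_controls: np.ndarray) -> FisherScores:
    """Fisher criterion F = (mu_c - mu_k)^2 / (s2_c + s2_k) per column.

    Sample means and (ddof=1) variances are taken over subjects,
    ignoring masked (NaN) entries.  Columns with zero pooled variance
    get F = 0 (uninformative constant feature).
    """
    X_cases = np.atleast_2d(np.asarray(X_cases, dtype=float))
    X_controls = np.atleast_2d(np.asarray(X_controls, dtype=float))
    if X_cases.shape[1] != X_controls.shape[1]:
        raise DomainError("case and control matrices must have equal column counts")
    if X_cases.shape[0] < 2 or X_controls.shape[0] < 2:
        raise DomainError("need >= 2 subjects per group for sample variances")
    with np.errstate(invalid="ignore"):
        mu_c = np.nanmean(X_cases, axis=0)
        mu_k = np.nanmean(X_controls, axis=0)
        s2_c = np.nanvar(X_cases, axis=0, ddof=1)
        s2_k = np.nanvar(X_controls, axis=0, ddof=1)
    denom = s2_c + s2_k
    scores = np.zeros(X_cases.shape[1])
    ok = denom > 0
    if not ok.all():
        logger.warning("%d column(s) with zero pooled variance get F = 0", int((~ok).sum()))
    scores[ok] = (mu_c[ok] - mu_k[ok]) ** 2 / denom[ok]
    scores = np.nan_to_num(scores, nan=0.0)
    order = np.argsort(-scores, kind="stable")  # ties -> lower index first
    return FisherScores(scores=scores, selected=order)


def select_features(scores: FisherScores, m: int = 6) -> np.ndarray:
    """Indices of the m largest Fisher scores, descending; ties break
    toward the lower index."""
    k = scores.scores.size
    if m > k:
        raise DomainError(f"requested {m} features but only {k} available")
    return scores.selected[:m].copy()
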