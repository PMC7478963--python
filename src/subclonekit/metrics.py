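"""SMC-Het-style scoring of a heterogeneity prediction against a truth.

Five sub-scores, each 1 for a perfect prediction:

* purity (1A): one minus the absolute purity error;
* clone count (1B): relative error, ``1 - |n_t - n_p| / n_t``, clamped at 0
  (an alternative normalization by ``max(n_t, n_p)`` is available);
* proportions (1C): one minus the mean absolute difference of per-SNV
  cellular prevalence;
* co-clustering (2): Pearson correlation between the flattened SNV x SNV
  co-clustering matrices ``S = P P^T`` of truth and prediction, where P is
  the row-stochastic SNV-to-subclone probability matrix;
* ancestry (3): the same correlation on ``M = P A P^T`` with A the strict
  subclone ancestor matrix.

The correlation scores are invariant to cluster relabeling because S and M
live in SNV space.  Degenerate (constant) matrices score 1 when the two
matrices are equal and 0 otherwise, with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ScoreReport",
    "Prediction",
    "score_purity",
    "score_nclones",
    "score_proportions",
    "coclustering_score",
    "ancestry_score",
    "score_report",
]


@dataclass(frozen=True)
class ScoreReport:
    purity_score: float
    nclone_score: float
    proportion_score: float
    coclustering_score: float
    ancestry_score: float


@dataclass(frozen=True)
class Prediction:
    """A full heterogeneity call in the shape the scoring functions consume."""

    purity: float
    clone_prevalence: np.ndarray  # (C,) descending
    P: np.ndarray  # (n, C) row-stochastic SNV-to-subclone probabilities
    ancestry: np.ndarray  # (C, C) strict ancestor indicator
    snv_prevalence: np.ndarray  # (n,) cellular prevalence per SNV

    @property
    def n_clones(self) -> int:
        return int(np.asarray(self.clone_prevalence).size)


def score_purity(truth: float, pred: float) -> float:
    if not (0.0 <= truth <= 1.0 and 0.0 <= pred <= 1.0):
        raise ValueError("purities must lie in [0, 1]")
    return 1.0 - abs(truth - pred)


def score_nclones(n_truth: int, n_pred: int, *, denominator: str = "truth") -> float:
    """Relative-error score for the subclone count, clamped below at 0.

    ``denominator="truth"`` is the canonical definition; ``"max"`` divides by
    ``max(n_truth, n_pred)`` instead.
    """
    if n_truth < 1 or n_pred < 1:
        raise ValueError("clone counts must be >= 1")
    if denominator == "truth":
        den = n_truth
    elif denominator == "max":
        den = max(n_truth, n_pred)
    else:
        raise ValueError(f"unknown denominator rule {denominator!r}")
    return max(0.0, 1.0 - abs(n_truth - n_pred) / den)


def score_proportions(truth, pred) -> float:
    """One minus the mean absolute per-SNV cellular-prevalence error."""
    truth = np.asarray(truth, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if truth.shape != pred.shape:
        raise ValueError(
            f"per-SNV prevalence lists differ in length: {truth.shape} vs {pred.shape}"
        )
    return float(1.0 - np.abs(truth - pred).mean())


def _matrix_correlation(truth: np.ndarray, pred: np.ndarray) -> float:
    truth = np.asarray(truth, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if truth.shape != pred.shape:
        raise ValueError(f"matrix shapes differ: {truth.shape} vs {pred.shape}")
    if np.array_equal(truth, pred):
        return 1.0
    a, b = truth.ravel(), pred.ravel()
    if np.ptp(a) == 0.0 or np.ptp(b) == 0.0:
        warnings.warn(
            "constant matrix in correlation score; returning equality indicator",
            stacklevel=3,
        )
        return 1.0 if np.allclose(a, b) else 0.0
    return float(np.corrcoef(a, b)[0, 1])


def coclustering_score(P_truth: np.ndarray, P_pred: np.ndarray) -> float:
    """Correlation of the SNV co-clustering matrices S = P P^T."""
    P_truth = np.asarray(P_truth, dtype=float)
    P_pred = np.asarray(P_pred, dtype=float)
    if P_truth.shape[0] != P_pred.shape[0]:
        raise ValueError("truth and prediction cover different SNV sets")
    return _matrix_correlation(P_truth @ P_truth.T, P_pred @ P_pred.T)


def ancestry_score(
    P_truth: np.ndarray,
    A_truth: np.ndarray,
    P_pred: np.ndarray,
    A_pred: np.ndarray,
) -> float:
    """Correlation of the SNV ancestry matrices M = P A P^T."""
    P_truth = np.asarray(P_truth, dtype=float)
    P_pred = np.asarray(P_pred, dtype=float)
    if P_truth.shape[0] != P_pred.shape[0]:
        raise ValueError("truth and prediction cover different SNV sets")
    M_truth = P_truth @ np.asarray(A_truth, dtype=float) @ P_truth.T
    M_pred = P_pred @ np.asarray(A_pred, dtype=float) @ P_pred.T
    return _matrix_correlation(M_truth, M_pred)


def score_report(truth: Prediction, pred: Prediction) -> ScoreReport:
    """Score a prediction against a truth record on all five criteria."""
    return ScoreReport(
        purity_score=max(0.0, score_purity(truth.purity, pred.purity)),
        nclone_score=score_nclones(truth.n_clones, pred.n_clones),
        proportion_score=max(
            0.0, score_proportions(truth.snv_prevalence, pred.snv_prevalence)
        ),
        coclustering_score=coclustering_score(truth.P, pred.P),
        ancestry_score=ancestry_score(truth.P, truth.ancestry, pred.P, pred.ancestry),
    )
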