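"""Denoising source separation (DSS) for trial-wise response functions.

DSS finds spatial filters ordered by the consistency of their output over
trials: it whitens by the total covariance (summed over trials) and then
diagonalizes the covariance of the trial average in the whitened space.
Keeping the leading components and projecting back to sensor space
suppresses activity that is not reproducible across trials.  In this
pipeline DSS is applied to per-trial TRF weight matrices (the lag axis
plays the role of time) before summarizing them as sensor-RMS time courses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np


@dataclass
class DSSDecomposition:
    filters: np.ndarray  # sensors x components
    patterns: np.ndarray  # components x sensors
    scores: np.ndarray  # consistency eigenvalues, descending

    def __post_init__(self) -> None:
        if np.any(np.diff(self.scores) > 1e-10):
            raise ValueError("scores must be sorted descending")


def _covariance(X: np.ndarray) -> np.ndarray:
    Xc = X - X.mean(axis=0)
    return Xc.T @ Xc


def dss_fit(trial_data: np.ndarray | list, rank_tol: float = 1e-10) -> DSSDecomposition:
    """Fit DSS on trials x samples x sensors data (equal trial lengths).

    The total covariance is the unnormalized sum of per-trial covariances;
    the biased covariance comes from the trial average.  Whitening drops
    dimensions with relative eigenvalue below ``rank_tol``.
    """
    trials = np.stack([np.asarray(t, dtype=float) for t in trial_data])
    if trials.ndim != 3:
        raise ValueError("expected trials x samples x sensors")
    if trials.shape[0] < 2:
        raise ValueError("DSS needs at least 2 trials")
    c_total = sum(_covariance(t) for t in trials)
    c_evoked = _covariance(trials.mean(axis=0))
    e, V = np.linalg.eigh(c_total)
    keep = e > rank_tol * e.max()
    if not np.all(keep):
        warnings.warn(
            f"total covariance rank-deficient; reducing to {int(keep.sum())} dimensions"
        )
    W1 = V[:, keep] / np.sqrt(e[keep])
    c2 = W1.T @ c_evoked @ W1
    e2, U = np.linalg.eigh(c2)
    order = np.argsort(e2)[::-1]
    filters = W1 @ U[:, order]
    return DSSDecomposition(filters, np.linalg.pinv(filters), e2[order])


def dss_denoise(
    trial_data: np.ndarray | list, decomposition: DSSDecomposition, n_keep: int = 3
) -> np.ndarray:
    """Keep the ``n_keep`` most consistent components and back-project."""
    trials = np.stack([np.asarray(t, dtype=float) for t in trial_data])
    F = decomposition.filters[:, :n_keep]
    P = decomposition.patterns[:n_keep]
    return np.einsum("tns,sc,cm->tnm", trials, F, P)


def sensor_rms(data: np.ndarray, sensor_subset: np.ndarray | None = None) -> np.ndarray:
    """RMS over a sensor subset at every sample; ``data`` is samples x sensors."""
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if sensor_subset is not None:
        data = data[:, np.asarray(sensor_subset)]
    return np.sqrt(np.mean(data**2, axis=1))
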