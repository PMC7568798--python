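"""Reduce per-beat scattering tensors (paths x windows) to classifier features.

Four reductions are provided: expanding every time window to its own row
(with per-beat labels repeated), selecting a single window, selecting a
window subset, and projecting each scattering path's 8 window values onto
its leading principal component.  Window indices are 0-based throughout, so
the "4th time window" of the evaluation tables is ``window_index=3``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np


@dataclass
class FeatureMatrix:
    """Classifier-ready features: one row per observation.

    ``beat_index[i]`` maps row ``i`` back to its source beat so per-beat
    majority voting can aggregate multi-window rows.
    """

    features: np.ndarray       # (n_rows, n_paths)
    labels: np.ndarray         # (n_rows,) class strings
    beat_index: np.ndarray     # (n_rows,) source beat per row

    @property
    def n_rows(self) -> int:
        return self.features.shape[0]


def _as_stack(tensors) -> np.ndarray:
    arr = np.asarray([t.coefficients if hasattr(t, "coefficients") else t
                      for t in tensors], dtype=float)
    if arr.ndim != 3:
        raise ValueError("expected uniformly shaped (paths x windows) tensors")
    return arr


def expand_window_rows(tensors, labels) -> FeatureMatrix:
    """One row per (beat, window); row i*W + w holds window w of beat i."""
    arr = _as_stack(tensors)
    n, p, w = arr.shape
    labels = np.asarray(labels)
    if len(labels) != n:
        raise ValueError("labels length does not match the number of beats")
    feats = arr.transpose(0, 2, 1).reshape(n * w, p)
    return FeatureMatrix(feats, np.repeat(labels, w), np.repeat(np.arange(n), w))


def select_window(tensors, labels, window_index: int) -> FeatureMatrix:
    """One row per beat containing a single window's path coefficients."""
    arr = _as_stack(tensors)
    n, _, w = arr.shape
    if not 0 <= window_index < w:
        raise ValueError(f"window_index {window_index} out of range [0, {w})")
    labels = np.asarray(labels)
    return FeatureMatrix(arr[:, :, window_index].copy(), labels.copy(),
                         np.arange(n))


def select_window_subset(tensors, labels, indices) -> FeatureMatrix:
    """One row per (beat, selected window), windows in ascending index order."""
    arr = _as_stack(tensors)
    n, p, w = arr.shape
    indices = sorted(int(i) for i in indices)
    if len(set(indices)) != len(indices):
        raise ValueError("window indices must be distinct")
    if indices and (indices[0] < 0 or indices[-1] >= w):
        raise ValueError("window index out of range")
    k = len(indices)
    feats = arr[:, :, indices].transpose(0, 2, 1).reshape(n * k, p)
    labels = np.asarray(labels)
    return FeatureMatrix(feats, np.repeat(labels, k), np.repeat(np.arange(n), k))


def per_node_pc1(tensors, labels, fit_index=None
                 ) -> tuple[FeatureMatrix, np.ndarray]:
    """Leading-principal-component score of the windows, per scattering path.

    For each of the P paths independently, the W window values are treated
    as variables and beats as observations: center by the fitting-set mean,
    eigendecompose the W x W covariance, and project every beat onto the
    leading eigenvector (sign fixed so its largest-magnitude entry is
    positive).  Returns the (n_beats x P) score matrix and the per-path
    contribution rates (eigenvalue fractions, shape (P, W), descending).

    ``fit_index`` restricts covariance estimation to a row subset (e.g. the
    training fold) while still projecting all beats; by default all beats
    are used for fitting.  Zero-variance paths score 0 with a warning.
    """
    arr = _as_stack(tensors)
    n, p, w = arr.shape
    fit = np.arange(n) if fit_index is None else np.asarray(fit_index)
    if len(fit) < 2:
        raise ValueError("need at least 2 fitting observations")
    scores = np.zeros((n, p))
    rates = np.zeros((p, w))
    for node in range(p):
        x = arr[:, node, :]
        mean = x[fit].mean(axis=0)
        cov = np.cov(x[fit] - mean, rowvar=False, ddof=1)
        total = np.trace(cov)
        if total <= 1e-300:
            warnings.warn(f"path {node} has zero variance; scores set to 0")
            rates[node, 0] = 1.0
            continue
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        evals = np.clip(evals[order], 0.0, None)
        v = evecs[:, order[0]]
        if v[np.argmax(np.abs(v))] < 0:
            v = -v
        scores[:, node] = (x - mean) @ v
        rates[node] = evals / evals.sum()
    labels = np.asarray(labels)
    return FeatureMatrix(scores, labels.copy(), np.arange(n)), rates
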