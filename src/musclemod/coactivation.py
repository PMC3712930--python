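"""Pairwise muscle coactivation across tasks.

For each subject a 7x7 Pearson correlation matrix of the trial-level
activation samples (96 per muscle) quantifies how strongly muscle pairs
co-vary across the six tasks; percentile-bootstrap confidence intervals
flag correlations distinguishable from zero.  Group-level matrices are
element-wise means over subjects.  The 3-D workspace projection exposes
the geometry behind a high mean correlation: trial points collapsing onto
a line in a 3-muscle subspace indicate amplitude-only modulation.
"""

from __future__ import annotations

import warnings

import numpy as np

from .datatypes import (CHANNELS7, CorrelationResult, N_CHANNELS, N_TASKS,
                        N_TRIALS, TrialSet)
from .exceptions import ParameterError


def _samples(trials: TrialSet, use_task_means: bool) -> np.ndarray:
    if use_task_means:
        return trials.activations.mean(axis=1)          # (6, 7)
    return trials.activations.reshape(-1, N_CHANNELS)    # (96, 7)


def pairwise_correlation(trials: TrialSet, use_task_means: bool = False
                         ) -> CorrelationResult:
    """Pearson correlation matrix of the per-muscle activation samples.

    Defaults to the 96 trial-level samples; ``use_task_means`` switches to
    the 6 task means (a sensitivity variant).  A zero-variance channel's
    row and column are NaN with a warning.
    """
    X = _samples(trials, use_task_means)
    sd = X.std(axis=0)
    dead = sd < 1e-10 * (np.abs(X.mean(axis=0)) + 1.0)
    if np.any(dead):
        warnings.warn(f"zero-variance channels {np.flatnonzero(dead).tolist()}; "
                      "their correlations are undefined", RuntimeWarning)
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.corrcoef(X, rowvar=False)
    R[dead, :] = np.nan
    R[:, dead] = np.nan
    np.fill_diagonal(R, 1.0)
    return CorrelationResult(R=R, n_samples=X.shape[0])


def _corr_stack(X: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Correlation matrices for a stack of resampled datasets.

    ``idx`` is (n_boot, n_rows); returns (n_boot, 7, 7) with NaN where a
    resample has a degenerate (zero-variance) channel.
    """
    B = X[idx]                                           # (n_boot, n, 7)
    Bc = B - B.mean(axis=1, keepdims=True)
    cov = np.einsum("bij,bik->bjk", Bc, Bc) / (B.shape[1] - 1)
    sd = np.sqrt(np.einsum("bjj->bj", cov))
    with np.errstate(invalid="ignore", divide="ignore"):
        R = cov / (sd[:, :, None] * sd[:, None, :])
    return R


def bootstrap_ci(trials: TrialSet, n_boot: int = 1000, alpha: float = 0.05,
                 seed: int = 0, use_task_means: bool = False) -> CorrelationResult:
    """Percentile-bootstrap CIs for the pairwise correlation matrix.

    Trials are resampled with replacement (96 rows); resamples with a
    degenerate channel are dropped from that channel's percentile (and
    counted via a warning when they occur).  ``significant`` marks pairs
    whose CI excludes zero.
    """
    if n_boot < 100:
        raise ParameterError("n_boot must be >= 100")
    X = _samples(trials, use_task_means)
    base = pairwise_correlation(trials, use_task_means=use_task_means)
    rng = np.random.default_rng(int(seed))
    idx = rng.integers(0, X.shape[0], size=(n_boot, X.shape[0]))
    R = _corr_stack(X, idx)
    n_bad = int(np.isnan(R).any(axis=(1, 2)).sum())
    if n_bad:
        warnings.warn(f"{n_bad} degenerate bootstrap resamples skipped", RuntimeWarning)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        lo = np.nanpercentile(R, 100 * alpha / 2, axis=0)
        hi = np.nanpercentile(R, 100 * (1 - alpha / 2), axis=0)
    significant = (lo > 0) | (hi < 0)
    np.fill_diagonal(significant, False)
    return CorrelationResult(R=base.R, ci_low=lo, ci_high=hi,
                             significant=significant, n_samples=X.shape[0])


def group_mean_matrix(matrices: list[np.ndarray]) -> np.ndarray:
    """Element-wise mean of per-subject 7x7 correlation matrices."""
    if not matrices:
        raise ParameterError("need at least one matrix")
    stack = np.stack([np.asarray(m, dtype=float) for m in matrices])
    if stack.shape[1:] != (N_CHANNELS, N_CHANNELS):
        raise ParameterError("matrices must be 7x7")
    return stack.mean(axis=0)


def mean_offdiagonal(R: np.ndarray) -> float:
    """Mean of the 21 upper-triangle off-diagonal entries of a 7x7 matrix."""
    R = np.asarray(R, dtype=float)
    iu = np.triu_indices(N_CHANNELS, k=1)
    return float(R[iu].mean())


#: The two published workspace projections: intrinsic and extrinsic hand muscles.
INTRINSIC_TRIPLE = ("FDI", "THE", "HTH")
EXTRINSIC_TRIPLE = ("FDS", "EDC", "FCR/U")


def workspace_projection(trials: TrialSet, channel_triple: tuple[str, str, str]
                         ) -> tuple[np.ndarray, np.ndarray, float]:
    """Project the 96 trials into a 3-muscle activation subspace.

    Returns ``(points, task_labels, first_axis_fraction)``: the (96, 3)
    point cloud, the task index of each point, and the fraction of the
    cloud's (centered) variance captured by its first principal axis — a
    scalar summary of how line-like the explored workspace is.
    """
    for ch in channel_triple:
        if ch not in CHANNELS7:
            raise ParameterError(f"unknown channel {ch!r}")
    cols = [CHANNELS7.index(ch) for ch in channel_triple]
    pts = trials.activations.reshape(-1, N_CHANNELS)[:, cols]
    labels = np.repeat(np.arange(N_TASKS), N_TRIALS)
    centered = pts - pts.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    total = float(np.sum(sv ** 2))
    frac = float(sv[0] ** 2 / total) if total > 0 else float("nan")
    return pts, labels, frac
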