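"""Inter-task separation and intra-task variability of activation patterns.

The squared-Euclidean-distance (SED) matrix summarizes how far apart the
mean 7-muscle activation vectors of the six tasks sit (off-diagonals) and
how variable the pattern is within each task (diagonal, the within-task
mean square summed over channels).  Entries are scaled by 100 so that
activations on the 0-1 MVC-normalized scale yield percent-scale values.
Larger off-diagonals mean stronger task-specific modulation; larger
diagonals mean less consistent task execution.

Statistical backing: a one-way MANOVA of the activation vector on task
(Wilks' lambda) tests whether patterns differ across tasks at all, and
per-muscle Tukey HSD tests count, over all 15 task pairs x 7 muscles = 105
comparisons, how many pairs fail to differ — the paper-level index of
unmodulated muscle activity.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .datatypes import N_CHANNELS, N_TASKS, N_TRIALS, TASKS, SedMatrix, TrialSet
from .exceptions import ParameterError

#: Scale factor taking squared distances on the 0-1 scale to percent units.
SED_SCALE = 100.0


def task_means(trials: TrialSet) -> np.ndarray:
    """Per-task mean activation vectors: a (6, 7) matrix."""
    return trials.activations.mean(axis=1)


def sed_matrix(trials: TrialSet) -> SedMatrix:
    """SED matrix of a subject's trial tensor.

    ``d[i, j] = 100 * ||mbar_i - mbar_j||^2`` for i != j and
    ``d[i, i] = 100 * (1/(n-1)) * sum_k ||m_i(k) - mbar_i||^2`` with n = 16
    trials — the unbiased within-task variance summed over the 7 channels.
    """
    acts = trials.activations
    n = acts.shape[1]
    if n < 2:
        raise ParameterError("intra-task variability needs at least 2 trials")
    means = acts.mean(axis=1)                               # (6, 7)
    diff = means[:, None, :] - means[None, :, :]
    d = SED_SCALE * np.sum(diff ** 2, axis=2)
    resid = acts - means[:, None, :]
    within = np.sum(resid ** 2, axis=(1, 2)) / (n - 1)
    np.fill_diagonal(d, SED_SCALE * within)
    return SedMatrix(d=d, task_order=TASKS)


def separation_summary(sed: SedMatrix) -> tuple[float, float]:
    """Mean of the 15 upper-triangle off-diagonals and of the 6 diagonals."""
    iu = np.triu_indices(N_TASKS, k=1)
    return float(sed.d[iu].mean()), float(np.diag(sed.d).mean())


def group_mean_sed(seds: list[SedMatrix]) -> SedMatrix:
    """Element-wise mean of subject-level SED matrices (group-level table)."""
    if not seds:
        raise ParameterError("need at least one SED matrix")
    order = seds[0].task_order
    stack = np.stack([s.reordered(order).d for s in seds])
    return SedMatrix(stack.mean(axis=0), order)


def _wilks_pvalue(endog: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """Wilks' lambda and its Rao F-approximation p-value, via pseudo-inverse.

    Fallback used when the within-group scatter is singular and the
    statsmodels MANOVA machinery refuses the fit.
    """
    groups = np.unique(labels)
    p = endog.shape[1]
    grand = endog.mean(axis=0)
    W = np.zeros((p, p))
    B = np.zeros((p, p))
    for g in groups:
        xg = endog[labels == g]
        mg = xg.mean(axis=0)
        W += (xg - mg).T @ (xg - mg)
        B += len(xg) * np.outer(mg - grand, mg - grand)
    T = W + B
    lam = float(np.linalg.det(W @ np.linalg.pinv(T))) if np.linalg.matrix_rank(T) < p \
        else float(np.linalg.det(W) / np.linalg.det(T))
    lam = min(max(lam, 1e-300), 1.0)
    # Rao's F approximation
    k = len(groups)
    n = endog.shape[0]
    q = k - 1
    t = np.sqrt((p**2 * q**2 - 4) / (p**2 + q**2 - 5)) if (p**2 + q**2 - 5) > 0 else 1.0
    df1 = p * q
    df2 = t * ((n - 1) - (p + k) / 2) - (p * q - 2) / 2
    L = lam ** (1 / t)
    f = (1 - L) / L * df2 / df1
    pval = float(sstats.f.sf(f, df1, df2))
    return lam, pval


def manova_tasks(trials: TrialSet) -> tuple[float, float]:
    """One-way MANOVA of the 7-channel activation vector on task.

    Returns ``(wilks_lambda, p_value)``.  A singular within-task covariance
    triggers a pseudo-inverse Wilks computation with a warning.
    """
    acts = trials.activations
    endog = acts.reshape(-1, N_CHANNELS)
    labels = np.repeat(np.arange(N_TASKS), acts.shape[1])
    try:
        from statsmodels.multivariate.manova import MANOVA

        df = pd.DataFrame(endog, columns=[f"m{i}" for i in range(N_CHANNELS)])
        df["task"] = pd.Categorical(labels)
        mv = MANOVA.from_formula(
            " + ".join(df.columns[:N_CHANNELS]) + " ~ C(task)", data=df)
        res = mv.mv_test().results["C(task)"]["stat"]
        lam = float(res.loc["Wilks' lambda", "Value"])
        pval = float(res.loc["Wilks' lambda", "Pr > F"])
    except Exception:
        warnings.warn("statsmodels MANOVA failed (singular covariance?); "
                      "using pseudo-inverse Wilks' lambda", RuntimeWarning)
        lam, pval = _wilks_pvalue(endog, labels)
    return lam, pval


def tukey_pair_counts(trials: TrialSet, alpha: float = 0.05
                      ) -> tuple[int, int, np.ndarray]:
    """Per-muscle Tukey HSD across the 6 tasks; count nonsignificant pairs.

    Returns ``(n_nonsig, n_total, significant)`` where ``significant`` is a
    (7, 15) boolean array over muscles x task pairs (upper-triangle order)
    and ``n_total`` is always 105.  A muscle with zero variance across all
    trials contributes 15 nonsignificant pairs (with a warning).
    """
    acts = trials.activations
    iu, ju = np.triu_indices(N_TASKS, k=1)
    n_pairs = len(iu)
    significant = np.zeros((N_CHANNELS, n_pairs), dtype=bool)
    for m in range(N_CHANNELS):
        samples = [acts[t, :, m] for t in range(N_TASKS)]
        if np.ptp(np.concatenate(samples)) == 0:
            warnings.warn(f"muscle {m} has zero variance; its {n_pairs} pairs "
                          "counted nonsignificant", RuntimeWarning)
            continue
        res = sstats.tukey_hsd(*samples)
        significant[m] = res.pvalue[iu, ju] <= alpha
    n_total = N_CHANNELS * n_pairs
    n_nonsig = int(n_total - significant.sum())
    return n_nonsig, n_total, significant


def tukey_long_table(trials: TrialSet, alpha: float = 0.05) -> pd.DataFrame:
    """Tukey HSD results as a long table (muscle, task_a, task_b, significant)."""
    from .datatypes import CHANNELS7

    _, _, significant = tukey_pair_counts(trials, alpha=alpha)
    iu, ju = np.triu_indices(N_TASKS, k=1)
    rows = [
        {"muscle": CHANNELS7[m], "task_a": TASKS[i], "task_b": TASKS[j],
         "significant": bool(significant[m, p])}
        for m in range(N_CHANNELS) for p, (i, j) in enumerate(zip(iu, ju))
    ]
    return pd.DataFrame(rows)
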