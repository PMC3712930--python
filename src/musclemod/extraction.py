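"""Muscle-module extraction by nonnegative matrix factorization.

A subject's 96 trial activation vectors (6 tasks x 16 trials, 7 muscles)
are factorized as ``M ~ H @ C`` with nonnegative per-trial coefficients H
and nonnegative modules C.  Quality is measured by the variance accounted
for (VAF), ``100 * (1 - SS_res / SS_data)`` with *uncentered* sums of
squares — both in total and per muscle (local VAF).  The number of modules
is the smallest count whose best-of-restarts fit clears both thresholds
(total VAF > 90 %, every local VAF > 75 % by default).

The optimizer is multiplicative-update NMF minimizing the Frobenius error
(scikit-learn backend), restarted from at least 20 random seeded
initializations; one extra restart per count warm-starts from the best fit
at the previous count plus a small random extra module, which makes the
best total VAF nondecreasing in the module count.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.decomposition import NMF
from sklearn.exceptions import ConvergenceWarning

from .datatypes import (Config, ModuleSet, N_CHANNELS, N_TASKS, N_TRIALS,
                        TrialSet, VafCurve)
from .exceptions import ParameterError

NMF_TOL = 1e-6
NMF_MAX_ITER = 2000
MAX_MODULES = 6


def stack_matrix(trials: TrialSet) -> np.ndarray:
    """Stack the (6, 16, 7) tensor into a task-major (96, 7) matrix."""
    return trials.activations.reshape(N_TASKS * N_TRIALS, N_CHANNELS)


def unstack_matrix(data: np.ndarray) -> np.ndarray:
    """Inverse of :func:`stack_matrix`."""
    return np.asarray(data).reshape(N_TASKS, N_TRIALS, N_CHANNELS)


def vaf_total(data: np.ndarray, recon: np.ndarray) -> float:
    """Total VAF in percent: ``100 * (1 - sum((data-recon)^2) / sum(data^2))``.

    Uncentered (sums of raw squares), so a zero reconstruction scores 0 and
    a perfect one scores 100; poor fits can go negative.
    """
    data = np.asarray(data, dtype=float)
    recon = np.asarray(recon, dtype=float)
    if data.shape != recon.shape:
        raise ParameterError("data and reconstruction shapes differ")
    ss_data = float(np.sum(data ** 2))
    if ss_data == 0:
        raise ParameterError("VAF undefined for all-zero data")
    return 100.0 * (1.0 - float(np.sum((data - recon) ** 2)) / ss_data)


def vaf_local(data: np.ndarray, recon: np.ndarray) -> np.ndarray:
    """Per-muscle (column-wise) VAF in percent.

    An all-zero column has undefined VAF and is reported as NaN; callers
    treat NaN as failing the local criterion.
    """
    data = np.asarray(data, dtype=float)
    recon = np.asarray(recon, dtype=float)
    if data.shape != recon.shape:
        raise ParameterError("data and reconstruction shapes differ")
    ss_data = np.sum(data ** 2, axis=0)
    ss_res = np.sum((data - recon) ** 2, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = 100.0 * (1.0 - ss_res / ss_data)
    out[ss_data == 0] = np.nan
    return out


def _single_module_vafs(data: np.ndarray, H: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Total VAF of each module's rank-1 reconstruction on its own."""
    return np.array([vaf_total(data, np.outer(H[:, j], C[j])) for j in range(C.shape[0])])


def _order_modules(data: np.ndarray, H: np.ndarray, C: np.ndarray
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Order modules by descending single-module VAF; ties by first dominant channel."""
    vafs = _single_module_vafs(data, H, C)
    first_dom = np.argmax(C, axis=1)
    order = sorted(range(C.shape[0]), key=lambda j: (-vafs[j], first_dom[j], j))
    return H[:, order], C[order]


def _run_nmf(data: np.ndarray, n_mod: int, init: str, rs: int | None,
             W0: np.ndarray | None = None, H0: np.ndarray | None = None
             ) -> tuple[np.ndarray, np.ndarray]:
    model = NMF(n_components=n_mod, init=init, solver="mu",
                beta_loss="frobenius", tol=NMF_TOL, max_iter=NMF_MAX_ITER,
                random_state=rs)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        if init == "custom":
            H = model.fit_transform(data, W=W0, H=H0)
        else:
            H = model.fit_transform(data)
    return H, model.components_


def fit_nmf(data: np.ndarray, n_mod: int, n_restarts: int = 20, seed: int = 0,
            warm_start: tuple[np.ndarray, np.ndarray] | None = None,
            subject_id: str = "S0", group: str = "unimpaired") -> ModuleSet:
    """Best-of-restarts NMF of a nonnegative (rows, 7) matrix.

    Runs ``n_restarts`` seeded random initializations (plus an optional
    warm start from a smaller factorization), keeps the restart with the
    highest total VAF, max-normalizes each module row to 1 with the trial
    coefficients compensated, orders modules by descending single-module
    VAF, and derives the task tuning curve as the per-task mean of the
    trial coefficients.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[1] != N_CHANNELS:
        raise ParameterError("data must be (n_rows, 7)")
    if np.any(data < 0):
        raise ParameterError("data must be nonnegative")
    if not (1 <= n_mod <= MAX_MODULES):
        raise ParameterError(f"n_mod must be in 1..{MAX_MODULES}")
    if n_restarts < 1:
        raise ParameterError("n_restarts must be >= 1")

    rng = np.random.default_rng([int(seed), n_mod])
    best: tuple[float, np.ndarray, np.ndarray] | None = None
    restarts = 0
    for _ in range(n_restarts):
        rs = int(rng.integers(0, 2**31 - 1))
        H, C = _run_nmf(data, n_mod, "random", rs)
        restarts += 1
        v = vaf_total(data, H @ C)
        if best is None or v > best[0]:
            best = (v, H, C)
    if warm_start is not None:
        H_prev, C_prev = warm_start
        k_prev = C_prev.shape[0]
        if k_prev < n_mod:
            pad = n_mod - k_prev
            scale = max(data.mean(), 1e-6)
            W0 = np.hstack([H_prev, rng.uniform(0, scale, (data.shape[0], pad))])
            H0 = np.vstack([C_prev, rng.uniform(0, scale, (pad, N_CHANNELS))])
            # strictly positive init required by the multiplicative updates
            H, C = _run_nmf(data, n_mod, "custom", None,
                            W0=np.maximum(W0, 1e-8), H0=np.maximum(H0, 1e-8))
            restarts += 1
            v = vaf_total(data, H @ C)
            if v > best[0]:
                best = (v, H, C)

    _, H, C = best
    # max-normalize modules, compensate coefficients so H @ C is unchanged
    scales = C.max(axis=1)
    scales[scales == 0] = 1.0
    C = C / scales[:, None]
    H = H * scales[None, :]
    H, C = _order_modules(data, H, C)
    recon = H @ C

    n_rows = data.shape[0]
    if n_rows == N_TASKS * N_TRIALS:
        W_task = H.reshape(N_TASKS, N_TRIALS, n_mod).mean(axis=1)
    else:
        # pooled or irregular matrices: fall back to the overall mean profile
        W_task = np.tile(H.mean(axis=0), (N_TASKS, 1))
    return ModuleSet(C=C, W_task=W_task, H_trial=H,
                     vaf_total=vaf_total(data, recon),
                     vaf_local=vaf_local(data, recon),
                     n_mod=n_mod, restarts_used=restarts, seed=int(seed),
                     subject_id=subject_id, group=group)


def select_module_count(data: np.ndarray, config: Config | None = None,
                        stop_at_selection: bool = False,
                        subject_id: str = "S0", group: str = "unimpaired"
                        ) -> tuple[ModuleSet, VafCurve]:
    """Pick the smallest module count meeting the dual VAF criterion.

    Counts 1..6 are fit in turn; the selected count is the first whose best
    fit has total VAF above ``config.vaf_total_threshold`` and every local
    VAF above ``config.vaf_local_threshold`` (NaN locals fail).  If no
    count qualifies, the 6-module fit is returned flagged.  With
    ``stop_at_selection`` the scan stops at the selected count — the
    selection is unchanged, only the tail of the diagnostic curve is
    omitted.
    """
    cfg = config or Config()
    fits: list[ModuleSet] = []
    selected: ModuleSet | None = None
    prev: ModuleSet | None = None
    for n in range(1, MAX_MODULES + 1):
        warm = (prev.H_trial, prev.C) if prev is not None else None
        ms = fit_nmf(data, n, n_restarts=cfg.n_restarts, seed=cfg.seed,
                     warm_start=warm, subject_id=subject_id, group=group)
        fits.append(ms)
        prev = ms
        locals_ok = np.all(np.nan_to_num(ms.vaf_local, nan=-np.inf)
                           > cfg.vaf_local_threshold)
        if selected is None and ms.vaf_total > cfg.vaf_total_threshold and locals_ok:
            selected = ms
            if stop_at_selection:
                break
    criterion_met = selected is not None
    if selected is None:
        selected = fits[-1]
    curve = VafCurve(
        n_values=np.array([m.n_mod for m in fits]),
        vaf_total=np.array([m.vaf_total for m in fits]),
        min_vaf_local=np.array([np.nan if np.all(np.isnan(m.vaf_local))
                                else np.nanmin(m.vaf_local) for m in fits]),
        selected_n=selected.n_mod,
        criterion_met=criterion_met,
    )
    return selected, curve


def first_module_vaf(data: np.ndarray, config: Config | None = None) -> float:
    """Total VAF of the single best module (the paper-level complexity index)."""
    cfg = config or Config()
    ms = fit_nmf(data, 1, n_restarts=cfg.n_restarts, seed=cfg.seed)
    return ms.vaf_total
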