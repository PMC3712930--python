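"""Cross-group module fitting, critical VAF, and module merging.

Fixing a module set C and fitting only the nonnegative combination
coefficients (per-row NNLS) measures how well one group's modules span
another group's activation data — cross-validation VAF.  Chance level is
the 95th percentile of the VAF obtained by fitting k *random* modules
(drawn from the data's own mean/SD) over repeated draws.  Separately,
individual stroke modules can be reconstructed as nonnegative merges of
unimpaired modules, scored by cosine similarity.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import nnls

from .datatypes import CrossFitResult, MergeResult, ModuleSet, N_CHANNELS
from .exceptions import ParameterError
from .extraction import vaf_total
from .similarity import module_similarity


def fit_weights_fixed_modules(data: np.ndarray, C: np.ndarray
                              ) -> tuple[np.ndarray, float]:
    """Nonnegative least-squares fit of each data row onto fixed modules.

    Solves ``min ||C.T @ h - m||`` with ``h >= 0`` per row (Lawson-Hanson
    active set) and returns the (rows, k) coefficients and the uncentered
    total VAF of the reconstruction.
    """
    data = np.asarray(data, dtype=float)
    C = np.asarray(C, dtype=float)
    if data.ndim == 1:
        data = data[None, :]
    if C.ndim != 2 or C.shape[1] != N_CHANNELS or data.shape[1] != N_CHANNELS:
        raise ParameterError("data and C must have 7 channel columns")
    if np.any(np.linalg.norm(C, axis=1) == 0):
        raise ParameterError("modules must be nonzero")
    A = C.T
    H = np.empty((data.shape[0], C.shape[0]))
    for i, row in enumerate(data):
        H[i], _ = nnls(A, row)
    return H, vaf_total(data, H @ C)


def cross_vaf_curve(data: np.ndarray, modules: ModuleSet,
                    source_group: str = "", target_group: str = "",
                    vaf_crit: float | None = None) -> CrossFitResult:
    """VAF of the top-k modules for k = 1..N_mod (modules in extraction order).

    Modules are assumed ordered by descending single-module VAF (the order
    :func:`musclemod.extraction.fit_nmf` produces), so the curve is the
    cumulative explanatory power of the most important modules first.
    """
    C = modules.C if isinstance(modules, ModuleSet) else np.asarray(modules, dtype=float)
    vafs = []
    for k in range(1, C.shape[0] + 1):
        _, v = fit_weights_fixed_modules(data, C[:k])
        vafs.append(v)
    return CrossFitResult(vaf_by_k=np.array(vafs), source_group=source_group,
                          target_group=target_group, vaf_crit=vaf_crit)


def vaf_crit_random(data: np.ndarray, k: int, n_reps: int = 100, seed: int = 0,
                    data_mean: float | None = None, data_sd: float | None = None
                    ) -> float:
    """Critical VAF: 95th percentile of random-module fits to the data.

    Each repetition draws k random modules from Gaussian(mean, SD of the
    data entries) truncated at zero, fits them by NNLS, and records the
    VAF; the empirical 95th percentile over ``n_reps`` repetitions is the
    chance-level VAF against which real module fits are judged.
    """
    if k < 1:
        raise ParameterError("k must be >= 1")
    data = np.asarray(data, dtype=float)
    mu = data.mean() if data_mean is None else data_mean
    sd = data.std(ddof=1) if data_sd is None else data_sd
    if sd <= 0:
        raise ParameterError("data SD must be positive")
    rng = np.random.default_rng(int(seed))
    vafs = np.empty(n_reps)
    for r in range(n_reps):
        C = np.clip(rng.normal(mu, sd, size=(k, N_CHANNELS)), 0.0, None)
        while np.any(np.linalg.norm(C, axis=1) == 0):
            dead = np.linalg.norm(C, axis=1) == 0
            C[dead] = np.clip(rng.normal(mu, sd, size=(int(dead.sum()), N_CHANNELS)), 0.0, None)
        _, vafs[r] = fit_weights_fixed_modules(data, C)
    return float(np.percentile(vafs, 95))


def merge_reconstruct(target: ModuleSet | np.ndarray,
                      basis: ModuleSet | np.ndarray) -> MergeResult:
    """Reconstruct each target module as a nonnegative merge of basis modules.

    Per-module NNLS of the target module vector onto the basis module
    matrix; quality is the cosine between each module and its merged
    reconstruction.  A module orthogonal to the whole basis gets an
    identically-zero reconstruction and a similarity of 0.
    """
    Ct = target.C if isinstance(target, ModuleSet) else np.asarray(target, dtype=float)
    Cb = basis.C if isinstance(basis, ModuleSet) else np.asarray(basis, dtype=float)
    if Ct.size == 0 or Cb.size == 0:
        raise ParameterError("both module sets must be nonempty")
    coeffs = np.empty((Ct.shape[0], Cb.shape[0]))
    rs = np.empty(Ct.shape[0])
    for j, c in enumerate(Ct):
        coeffs[j], _ = nnls(Cb.T, c)
        recon = coeffs[j] @ Cb
        rs[j] = 0.0 if np.all(recon == 0) else module_similarity(c, recon)
    mean_r = float(rs.mean())
    return MergeResult(coefficients=coeffs, reconstruction_r=rs, mean_r=mean_r)
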