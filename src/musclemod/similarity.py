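"""Module-to-module similarity with a randomized-module null.

Similarity between two muscle modules is the normalized scalar product
(cosine) of the two nonnegative 7-vectors — scale-invariant, 1 for
identical shapes, 0 for disjoint muscle support.  Module sets from two
subjects are compared through the injective pairing of their modules that
maximizes the mean similarity (exhaustive over assignments; at most 6
modules per set).  Chance level is calibrated by scoring all cross pairs
of two sets of random modules drawn from the data's own mean and SD
(truncated at zero); the 95th percentile of that null is the critical R.
"""

from __future__ import annotations

from itertools import permutations

import numpy as np
import pandas as pd

from .datatypes import (ModuleSet, N_CHANNELS, NullDistribution, SimilarityResult)
from .exceptions import ParameterError


def module_similarity(c1: np.ndarray, c2: np.ndarray, centered: bool = False) -> float:
    """Cosine similarity between two module vectors.

    With ``centered=True`` the (mean-subtracted) Pearson correlation is
    returned instead — a sensitivity variant; the cosine is the default
    because modules are nonnegative activation profiles whose baseline is
    meaningful.
    """
    c1 = np.asarray(c1, dtype=float).ravel()
    c2 = np.asarray(c2, dtype=float).ravel()
    if centered:
        c1 = c1 - c1.mean()
        c2 = c2 - c2.mean()
    n1, n2 = np.linalg.norm(c1), np.linalg.norm(c2)
    if n1 == 0 or n2 == 0:
        raise ParameterError("similarity undefined for a zero module")
    return float(np.dot(c1, c2) / (n1 * n2))


def _similarity_matrix(CA: np.ndarray, CB: np.ndarray) -> np.ndarray:
    na = np.linalg.norm(CA, axis=1, keepdims=True)
    nb = np.linalg.norm(CB, axis=1, keepdims=True)
    if np.any(na == 0) or np.any(nb == 0):
        raise ParameterError("similarity undefined for a zero module")
    return (CA / na) @ (CB / nb).T


def optimal_pairing(set_a: ModuleSet | np.ndarray, set_b: ModuleSet | np.ndarray,
                    critical_r: float | None = None) -> SimilarityResult:
    """Injective module pairing maximizing the mean similarity.

    All assignments of the smaller set into the larger are enumerated
    (<= 6! = 720), so the returned pairing is exactly optimal.  Unmatched
    modules of the larger set are reported separately.
    """
    CA = set_a.C if isinstance(set_a, ModuleSet) else np.asarray(set_a, dtype=float)
    CB = set_b.C if isinstance(set_b, ModuleSet) else np.asarray(set_b, dtype=float)
    if CA.size == 0 or CB.size == 0:
        raise ParameterError("both module sets must be nonempty")
    R = _similarity_matrix(CA, CB)
    na, nb = R.shape
    swap = na > nb
    M = R.T if swap else R                       # rows = smaller set
    k = M.shape[0]
    best_perm, best_mean = None, -np.inf
    for perm in permutations(range(M.shape[1]), k):
        mean = M[np.arange(k), perm].mean()
        if mean > best_mean:
            best_mean, best_perm = mean, perm
    if swap:
        pairing = [(int(j), int(i)) for i, j in enumerate(best_perm)]
    else:
        pairing = [(int(i), int(j)) for i, j in enumerate(best_perm)]
    pairing.sort()
    r_values = np.array([R[i, j] for i, j in pairing])
    matched_a = {i for i, _ in pairing}
    matched_b = {j for _, j in pairing}
    n_above = int(np.sum(r_values > critical_r)) if critical_r is not None else 0
    return SimilarityResult(
        pairing=pairing, r_values=r_values,
        mean_r=float(r_values.mean()),
        sd_r=float(r_values.std(ddof=1)) if len(r_values) > 1 else 0.0,
        n_above_critical=n_above,
        unmatched_a=[i for i in range(na) if i not in matched_a],
        unmatched_b=[j for j in range(nb) if j not in matched_b],
    )


def random_module_null(data_mean: float, data_sd: float, n: int = 1000,
                       seed: int = 0) -> NullDistribution:
    """Similarity null from two sets of ``n`` random modules.

    Modules are 7-vectors of Gaussian(data_mean, data_sd) entries truncated
    at zero; degenerate all-zero draws are resampled (and counted).  All
    ``n * n`` cross-set cosines form the null; the critical R is its
    empirical 95th percentile.
    """
    if data_sd <= 0:
        raise ParameterError("data_sd must be positive")
    if n < 1:
        raise ParameterError("n must be >= 1")
    rng = np.random.default_rng(int(seed))
    n_resampled = 0

    def draw_set() -> np.ndarray:
        nonlocal n_resampled
        C = np.clip(rng.normal(data_mean, data_sd, size=(n, N_CHANNELS)), 0.0, None)
        while True:
            dead = np.flatnonzero(np.linalg.norm(C, axis=1) == 0)
            if len(dead) == 0:
                return C
            n_resampled += len(dead)
            C[dead] = np.clip(rng.normal(data_mean, data_sd,
                                         size=(len(dead), N_CHANNELS)), 0.0, None)

    A, B = draw_set(), draw_set()
    r = _similarity_matrix(A, B).ravel()
    return NullDistribution(r_samples=r, critical_r=float(np.percentile(r, 95)),
                            generator_mean=float(data_mean), generator_sd=float(data_sd),
                            n_modules_per_set=n, seed=int(seed),
                            n_resampled=n_resampled)


def pooled_mean_sd(data: np.ndarray) -> tuple[float, float]:
    """Pooled mean and SD of the activation entries (null-generator defaults)."""
    data = np.asarray(data, dtype=float)
    return float(data.mean()), float(data.std(ddof=1))


def group_similarity_table(sets_a: list[ModuleSet], sets_b: list[ModuleSet],
                           within: bool | None = None) -> pd.DataFrame:
    """Similarity summary cells partitioned by module count.

    Rows/columns are module-count strata of the two collections (e.g. the
    published tables stratify stroke survivors into 2-, 3- and 4-module
    groups and unimpaired subjects into 4- and 5-module groups).  Each cell
    pools the optimally-paired R values over all subject pairs in that
    stratum pair and reports ``mean (SD)``; when the two collections are the
    same (``within=True``, auto-detected by identity), only distinct subject
    pairs contribute.  Empty cells report ``NaN``.
    """
    if within is None:
        within = sets_a is sets_b
    counts_a = sorted({m.n_mod for m in sets_a})
    counts_b = sorted({m.n_mod for m in sets_b})
    table = pd.DataFrame(index=[f"n={c}" for c in counts_a],
                         columns=[f"n={c}" for c in counts_b], dtype=object)
    for ca in counts_a:
        for cb in counts_b:
            if within and cb < ca:
                table.loc[f"n={ca}", f"n={cb}"] = ""
                continue
            rs: list[float] = []
            for ia, ma in enumerate(sets_a):
                if ma.n_mod != ca:
                    continue
                for ib, mb in enumerate(sets_b):
                    if mb.n_mod != cb:
                        continue
                    if within:
                        if ia >= ib:
                            continue
                    elif ma is mb:
                        continue
                    rs.extend(optimal_pairing(ma, mb).r_values)
            if not rs:
                table.loc[f"n={ca}", f"n={cb}"] = "NaN"
            else:
                arr = np.array(rs)
                sd = arr.std(ddof=1) if len(arr) > 1 else 0.0
                table.loc[f"n={ca}", f"n={cb}"] = f"{arr.mean():.2f} ({sd:.2f})"
    return table


def fraction_above_critical(results: list[SimilarityResult], critical_r: float
                            ) -> tuple[int, int, float]:
    """Count paired-module R values exceeding the critical R.

    Returns ``(k, n, pct)``; with no pairs at all, pct is NaN.
    """
    if not (0.0 <= critical_r <= 1.0):
        raise ParameterError("critical_r must lie in [0, 1]")
    all_r = np.concatenate([res.r_values for res in results]) if results else np.array([])
    n = len(all_r)
    k = int(np.sum(all_r > critical_r))
    pct = 100.0 * k / n if n else float("nan")
    return k, n, pct
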