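"""Synthetic subjects with known modular ground truth.

Each synthetic subject is generated from the same low-dimensional model the
pipeline later tries to recover: a set of nonnegative muscle modules (rows
max-normalized to 1) recruited with nonnegative task-dependent coefficients,
plus truncated Gaussian trial-to-trial noise.  Impairment profiles control
the three features the analysis is sensitive to:

``severe``
    2-3 modules, each with 3-4 dominant muscles (high inter-muscle
    coupling), recruited broadly across all six tasks with independent
    moderate weights — activation patterns differ across tasks mostly in
    amplitude, not structure.
``moderate``
    exactly 4 modules with 2-3 dominant muscles, each tuned to 1-2
    preferred tasks above a nonzero baseline recruitment.
``unimpaired``
    4-5 modules with 2 dominant muscles, sharply tuned: near-zero
    recruitment outside each module's 1-2 preferred tasks.

Dominant-muscle slots are dealt so that every one of the 7 channels is
dominant in at least one module; a muscle that were weak in every module
would have an ill-determined local VAF at the true module count.
"""

from __future__ import annotations

import numpy as np

from .datatypes import (GROUPS, N_CHANNELS, N_TASKS, N_TRIALS, SubjectTruth, TrialSet)
from .exceptions import ParameterError
from .preprocess import bandpass_filter, trial_rms

#: Default trial-to-trial noise SD on the MVC-normalized scale.
DEFAULT_NOISE_SD = 0.05

#: Per-group sizes of the motivating study design (severe, moderate, unimpaired).
STUDY_GROUP_SIZES = (8, 6, 4)

_PROFILE_STREAM = {"severe": 11, "moderate": 13, "unimpaired": 17}


def _deal_dominant_channels(rng: np.random.Generator, n_mod: int,
                            dom_counts: list[int]) -> list[np.ndarray]:
    """Assign dominant channels: one private channel per module, full coverage.

    Each module first receives a *private* dominant channel (dominant in no
    other module) — without one, a module's contribution can be absorbed by
    the others and the true module count is not recoverable from the VAF
    criterion.  The remaining channels are dealt to modules still short of
    their dominant quota (covering all 7 channels), and leftover quota is
    topped up from the shared pool.
    """
    perm = list(rng.permutation(N_CHANNELS))
    private = perm[:n_mod]
    shared_pool = perm[n_mod:]
    sets: list[set[int]] = [{int(private[j])} for j in range(n_mod)]
    order = list(rng.permutation(n_mod))
    # deal every shared channel to some module needing a slot (coverage)
    for i, ch in enumerate(shared_pool):
        for j in order[i % n_mod:] + order[:i % n_mod]:
            if len(sets[j]) < dom_counts[j]:
                sets[j].add(int(ch))
                break
    for j in range(n_mod):                    # top up from the shared pool only
        free = [c for c in shared_pool if c not in sets[j]]
        need = dom_counts[j] - len(sets[j])
        if need > 0:
            extra = rng.choice(free, size=need, replace=False)
            sets[j].update(int(c) for c in extra)
    return [np.array(sorted(s)) for s in sets], [int(c) for c in private]


# channel indices: THE=0 FDI=1 HTH=2 EDC=3 FDS=4 ECR/U=5 FCR/U=6
# task indices:    WF=0 WE=1 FE=2 LP=3 PG=4 TP=5


def _canonical_modules(rng: np.random.Generator, n_mod: int, profile: str
                       ) -> tuple[np.ndarray, list[list[int]], list[int]]:
    """Canonical module templates shared by moderate and unimpaired subjects.

    Unimpaired (and, with more coactivation, moderately impaired) hands
    recruit a consistent repertoire: a thumb/index grip module (THE + FDI,
    pinch tasks), a finger/wrist extension module (EDC + ECR/U, hand open
    and wrist extension), a finger/wrist flexion module (FDS + FCR/U,
    power grip and wrist flexion), and a more idiosyncratic hypothenar
    module (HTH plus a variable partner).  Five-module subjects split the
    grip module into a thumb-weighted (lateral pinch) and an index-weighted
    (tip pinch) variant.  Returns module matrix, preferred-task lists, and
    the private channel of each module.
    """
    LP, TP, WE, FE, WF, PG = 3, 5, 1, 2, 0, 4
    second_lo = 0.75 if profile == "unimpaired" else 0.6
    mods: list[dict] = []
    if n_mod == 4:
        mods.append({"dom": [(0, 1.0), (1, rng.uniform(second_lo, 1.0))],
                     "prefs": [LP, TP], "private": 0})
    else:
        mods.append({"dom": [(0, 1.0), (1, rng.uniform(0.05, 0.2))],
                     "prefs": [LP], "private": 0})
        mods.append({"dom": [(1, 1.0), (0, rng.uniform(0.05, 0.2))],
                     "prefs": [TP], "private": 1})
    mods.append({"dom": [(3, 1.0), (5, rng.uniform(second_lo, 1.0))],
                 "prefs": [WE, FE], "private": 3})
    mods.append({"dom": [(4, 1.0), (6, rng.uniform(second_lo, 1.0))],
                 "prefs": [WF, PG], "private": 4})
    partner_pool = [5, 6] if n_mod == 5 else [1, 5, 6]
    partner = int(rng.choice(partner_pool))
    # the hypothenar module takes over one task from a two-task module, so
    # every module is the dominant contributor of at least one task — a
    # module with no task of its own is absorbed by the others and its
    # count is not recoverable
    donors = [j for j, m in enumerate(mods) if len(m["prefs"]) == 2]
    donor = int(rng.choice(donors))
    hyp_task = mods[donor]["prefs"].pop(int(rng.integers(2)))
    mods.append({"dom": [(2, 1.0), (partner, rng.uniform(second_lo, 1.0))],
                 "prefs": [hyp_task], "private": 2})

    private = [m["private"] for m in mods]
    C = rng.uniform(0.0, 0.3, size=(n_mod, N_CHANNELS))
    C[:, private] = rng.uniform(0.0, 0.05, size=(n_mod, len(private)))
    for j, m in enumerate(mods):
        if profile == "moderate" and rng.random() < 0.5:
            # extra strongly coupled muscle: abnormal coactivation creeps in
            pool = [c for c in partner_pool if c not in [d for d, _ in m["dom"]]]
            if pool:
                m["dom"].append((int(rng.choice(pool)), rng.uniform(0.5, 1.0)))
        for ch, gain in m["dom"]:
            C[j, ch] = gain
    prefs = [m["prefs"] for m in mods]
    return C, prefs


def make_subject_truth(profile: str, seed: int,
                       noise_sd: float = DEFAULT_NOISE_SD) -> SubjectTruth:
    """Draw a ground-truth subject for the given impairment profile.

    Deterministic given ``(profile, seed)``.
    """
    if profile not in GROUPS:
        raise ParameterError(f"unknown profile {profile!r}")
    rng = np.random.default_rng([_PROFILE_STREAM[profile], int(seed)])

    if profile == "severe":
        # idiosyncratic broad modules: random dominant sets of 3-4 strongly
        # coupled muscles, near-silent elsewhere (stereotyped all-or-none
        # recruitment; no shared canonical repertoire across subjects)
        n_mod = int(rng.choice([2, 3]))
        dom_counts = [4] * n_mod if n_mod == 2 \
            else [int(rng.choice([3, 4])) for _ in range(n_mod)]
        dom_sets, private = _deal_dominant_channels(rng, n_mod, dom_counts)
        C = rng.uniform(0.0, 0.1, size=(n_mod, N_CHANNELS))
        # private channels stay near-silent in every other module: each
        # module must own one muscle, or its count is not identifiable
        C[:, private] = rng.uniform(0.0, 0.05, size=(n_mod, len(private)))
        for j, dom in enumerate(dom_sets):
            C[j, dom] = 1.0
        # Broad recruitment: every module is active in all six tasks, but
        # each has a disjoint block of "strong" tasks (3+3 or 2+2+2) so the
        # tunings stay distinguishable and the modules identifiable.
        W = rng.uniform(0.1, 0.25, size=(N_TASKS, n_mod))
        task_perm = list(rng.permutation(N_TASKS))
        block = N_TASKS // n_mod
        for j in range(n_mod):
            strong = task_perm[j * block:(j + 1) * block] if j < n_mod - 1 \
                else task_perm[j * block:]
            for t in strong:
                W[t, j] = rng.uniform(0.7, 1.0)
        # overall amplitude varies with task (the hallmark of severely
        # impaired modulation: same pattern, different gain), coupling all
        # muscles positively across tasks
        W *= rng.uniform(0.75, 1.05, size=(N_TASKS, 1))
    else:
        n_mod = 4 if profile == "moderate" else int(rng.choice([4, 5]))
        C, prefs = _canonical_modules(rng, n_mod, profile)
        lo, hi = ((0.03, 0.18) if profile == "moderate" else (0.0, 0.08))
        plo, phi = ((0.85, 1.05) if profile == "moderate" else (1.0, 1.25))
        W = rng.uniform(lo, hi, size=(N_TASKS, n_mod))
        for j, tasks in enumerate(prefs):
            for t in tasks:
                W[t, j] = rng.uniform(plo, phi)

    return SubjectTruth(C_true=C, W_true=W, noise_sd=float(noise_sd),
                        profile=profile, seed=int(seed))


def simulate_trialset(truth: SubjectTruth, subject_id: str | None = None) -> TrialSet:
    """Simulate the (6, 16, 7) activation tensor implied by a SubjectTruth.

    Each trial is the noiseless task pattern ``W_true[i] @ C_true`` plus
    i.i.d. Gaussian noise truncated (clipped) at zero, preserving the
    nonnegativity of RMS-derived activations.
    """
    rng = np.random.default_rng([_PROFILE_STREAM[truth.profile], truth.seed, 202])
    acts = _noisy_activations(truth, truth.n_trials, rng)
    return TrialSet(activations=acts,
                    subject_id=subject_id or f"{truth.profile[:3]}-{truth.seed}",
                    group=truth.profile)


def _noisy_activations(truth: SubjectTruth, n_trials: int,
                       rng: np.random.Generator) -> np.ndarray:
    noiseless = truth.W_true @ truth.C_true                     # (6, 7)
    acts = np.repeat(noiseless[:, None, :], n_trials, axis=1)
    if truth.noise_sd > 0:
        acts = acts + rng.normal(0.0, truth.noise_sd, size=acts.shape)
    return np.clip(acts, 0.0, None)


def simulate_activation_samples(truth: SubjectTruth, n_samples: int,
                                seed: int = 0) -> np.ndarray:
    """Draw an arbitrary number of noisy trials per task: a (6, n, 7) array.

    Diagnostic companion to :func:`simulate_trialset` (which is fixed at the
    experiment's 16 trials): same noise model, free sample count.
    """
    if n_samples < 1:
        raise ParameterError("n_samples must be >= 1")
    rng = np.random.default_rng([_PROFILE_STREAM[truth.profile], truth.seed,
                                 303, int(n_samples)])
    return _noisy_activations(truth, n_samples, rng)


def simulate_raw_emg(target_rms: float, fs: float = 1000.0, duration: float = 3.0,
                     seed: int = 0) -> np.ndarray:
    """Band-limited (20-500 Hz) Gaussian noise rescaled to an exact RMS.

    A fixture signal for the preprocessing chain: its spectrum mimics
    surface EMG's acquisition band and its full-window RMS is ``target_rms``
    to machine precision.
    """
    if target_rms < 0:
        raise ParameterError("target_rms must be >= 0")
    n = int(round(duration * fs))
    if n < 100:
        raise ParameterError("duration * fs must give at least 100 samples")
    if target_rms == 0:
        return np.zeros(n)
    rng = np.random.default_rng(seed)
    x = bandpass_filter(rng.standard_normal(n), fs)
    return x * (target_rms / trial_rms(x))


def simulate_cohort(n_per_group: int | None = None, seed: int = 0,
                    group_sizes: tuple[int, int, int] | None = None,
                    noise_sd: float = DEFAULT_NOISE_SD
                    ) -> list[tuple[TrialSet, SubjectTruth]]:
    """Simulate a cohort across the three impairment groups.

    Either ``n_per_group`` (equal sizes) or ``group_sizes`` (severe,
    moderate, unimpaired) must be given; ``group_sizes=STUDY_GROUP_SIZES``
    mirrors the 8/6/4 design of the motivating study.
    """
    if group_sizes is None:
        if n_per_group is None or n_per_group < 1:
            raise ParameterError("need n_per_group >= 1 or explicit group_sizes")
        group_sizes = (n_per_group,) * 3
    rng = np.random.default_rng(int(seed))
    cohort: list[tuple[TrialSet, SubjectTruth]] = []
    idx = 0
    for group, size in zip(GROUPS, group_sizes):
        for _ in range(size):
            idx += 1
            subj_seed = int(rng.integers(0, 2**31 - 1))
            truth = make_subject_truth(group, subj_seed, noise_sd=noise_sd)
            trials = simulate_trialset(truth, subject_id=f"S{idx:02d}")
            cohort.append((trials, truth))
    return cohort
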