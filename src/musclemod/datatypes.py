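"""Core containers for the hand-muscle coordination pipeline.

Conventions used throughout the package
---------------------------------------
Channels (7, merged) are indexed in the fixed order ``THE, FDI, HTH, EDC,
FDS, ECR/U, FCR/U`` — thenar group, first dorsal interosseous, hypothenar
group, extensor digitorum communis, flexor digitorum superficialis, and the
averaged radial/ulnar wrist extensors and flexors.  The raw 9-channel order
keeps the wrist muscles unmerged: ``THE, FDI, HTH, EDC, FDS, ECR, ECU, FCR,
FCU``.

Tasks (6 isometric hand/wrist tasks) are indexed ``WF, WE, FE, LP, PG, TP``
— wrist flexion, wrist extension, finger extension (hand open), lateral
pinch, power grip, tip pinch.  Each task is repeated 16 times per subject,
so a subject's data is a (6, 16, 7) tensor of MVC-normalized activations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import IntegrityError, ParameterError

CHANNELS9: tuple[str, ...] = ("THE", "FDI", "HTH", "EDC", "FDS", "ECR", "ECU", "FCR", "FCU")
CHANNELS7: tuple[str, ...] = ("THE", "FDI", "HTH", "EDC", "FDS", "ECR/U", "FCR/U")

#: Canonical task order used by every matrix in the package.
TASKS: tuple[str, ...] = ("WF", "WE", "FE", "LP", "PG", "TP")
#: Alternate order used by the published group-level SED tables (WE first).
TASKS_TABLE_ORDER: tuple[str, ...] = ("WE", "WF", "FE", "LP", "PG", "TP")

GROUPS: tuple[str, ...] = ("severe", "moderate", "unimpaired")

N_TASKS = 6
N_TRIALS = 16
N_CHANNELS = 7


@dataclass
class Config:
    """Pipeline-wide settings.

    Parameters
    ----------
    seed : master seed for all stochastic stages.
    n_restarts : NMF restarts per module count; at least 20 random
        initializations are required to guard against local minima.
    vaf_total_threshold : percent of total variance a fit must account for.
    vaf_local_threshold : percent of per-muscle variance a fit must account
        for, applied to every channel.
    n_null_modules : size of each of the two random-module sets used for
        the similarity null (n x n pairs are scored).
    n_bootstrap : bootstrap resamples for correlation confidence intervals.
    n_vaf_crit_reps : repetitions of the random-module fit used for the
        critical VAF.
    noise_sd : trial-to-trial noise SD of the synthetic generator, on the
        MVC-normalized scale.
    """

    seed: int = 0
    n_restarts: int = 20
    vaf_total_threshold: float = 90.0
    vaf_local_threshold: float = 75.0
    n_null_modules: int = 1000
    n_bootstrap: int = 1000
    n_vaf_crit_reps: int = 100
    noise_sd: float = 0.05

    def __post_init__(self) -> None:
        if self.n_restarts < 20:
            raise ParameterError("n_restarts must be >= 20")
        for name in ("vaf_total_threshold", "vaf_local_threshold"):
            v = getattr(self, name)
            if not (0.0 < v <= 100.0):
                raise ParameterError(f"{name} must lie in (0, 100]")
        for name in ("n_null_modules", "n_bootstrap", "n_vaf_crit_reps"):
            if getattr(self, name) < 1:
                raise ParameterError(f"{name} must be >= 1")


@dataclass
class TrialSet:
    """One subject's MVC-normalized activations: a (6, 16, 7) tensor."""

    activations: np.ndarray
    subject_id: str = "S0"
    group: str = "unimpaired"

    def __post_init__(self) -> None:
        self.activations = np.asarray(self.activations, dtype=float)
        if self.activations.shape != (N_TASKS, N_TRIALS, N_CHANNELS):
            raise IntegrityError(
                f"activations must have shape {(N_TASKS, N_TRIALS, N_CHANNELS)}, "
                f"got {self.activations.shape}"
            )
        if not np.all(np.isfinite(self.activations)):
            raise IntegrityError("activations must be finite")
        if np.any(self.activations < 0):
            raise IntegrityError("activations must be nonnegative")
        if self.group not in GROUPS:
            raise ParameterError(f"unknown group {self.group!r}")


@dataclass
class SubjectTruth:
    """Ground-truth generative model for one synthetic subject.

    The subject's noiseless activation for task ``i`` is
    ``W_true[i] @ C_true`` — a nonnegative combination of N_mod muscle
    modules, each max-normalized to 1.
    """

    C_true: np.ndarray          # (n_mod, 7)
    W_true: np.ndarray          # (6, n_mod)
    noise_sd: float
    profile: str
    seed: int
    n_trials: int = N_TRIALS

    def __post_init__(self) -> None:
        self.C_true = np.asarray(self.C_true, dtype=float)
        self.W_true = np.asarray(self.W_true, dtype=float)
        if self.C_true.ndim != 2 or self.C_true.shape[1] != N_CHANNELS:
            raise IntegrityError("C_true must be (n_mod, 7)")
        if self.W_true.shape != (N_TASKS, self.C_true.shape[0]):
            raise IntegrityError("W_true must be (6, n_mod)")
        if not (2 <= self.n_mod <= 5):
            raise IntegrityError("n_mod must be in {2,3,4,5}")
        if np.any(self.C_true < 0) or np.any(self.W_true < 0):
            raise IntegrityError("C_true and W_true must be nonnegative")
        if not np.allclose(self.C_true.max(axis=1), 1.0):
            raise IntegrityError("every module must have max element 1")
        if self.profile not in GROUPS:
            raise ParameterError(f"unknown profile {self.profile!r}")

    @property
    def n_mod(self) -> int:
        return self.C_true.shape[0]


@dataclass
class SedMatrix:
    """6x6 squared-Euclidean-distance matrix, in percent of the normalized scale.

    Off-diagonal ``d[i, j]`` is the inter-task separation between the mean
    activation vectors of tasks i and j; diagonal ``d[i, i]`` is the
    intra-task variability (within-task mean square summed over channels).
    """

    d: np.ndarray
    task_order: tuple[str, ...] = TASKS

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        if self.d.shape != (N_TASKS, N_TASKS):
            raise IntegrityError("SED matrix must be 6x6")
        if not np.allclose(self.d, self.d.T):
            raise IntegrityError("SED matrix must be symmetric")
        if np.any(self.d < -1e-12):
            raise IntegrityError("SED entries must be nonnegative")

    def reordered(self, task_order: tuple[str, ...]) -> "SedMatrix":
        """Return the same matrix with rows/columns permuted to ``task_order``."""
        idx = [self.task_order.index(t) for t in task_order]
        return SedMatrix(self.d[np.ix_(idx, idx)], tuple(task_order))


@dataclass
class ModuleSet:
    """Extracted muscle modules and their task tuning for one data matrix.

    ``C`` holds the modules (rows max-normalized to 1), ``H_trial`` the
    per-trial nonnegative combination coefficients, and ``W_task`` the task
    tuning curves (per-task mean of the trial coefficients).
    """

    C: np.ndarray               # (n_mod, 7)
    W_task: np.ndarray          # (6, n_mod)
    H_trial: np.ndarray         # (n_rows, n_mod)
    vaf_total: float
    vaf_local: np.ndarray       # (7,)
    n_mod: int
    restarts_used: int
    seed: int
    subject_id: str = "S0"
    group: str = "unimpaired"

    def __post_init__(self) -> None:
        self.C = np.asarray(self.C, dtype=float)
        self.W_task = np.asarray(self.W_task, dtype=float)
        self.H_trial = np.asarray(self.H_trial, dtype=float)
        self.vaf_local = np.asarray(self.vaf_local, dtype=float)
        if self.C.shape != (self.n_mod, N_CHANNELS):
            raise IntegrityError("C must be (n_mod, 7)")
        if self.W_task.shape != (N_TASKS, self.n_mod):
            raise IntegrityError("W_task must be (6, n_mod)")

    def reconstruction(self) -> np.ndarray:
        return self.H_trial @ self.C


@dataclass
class VafCurve:
    """Best-restart VAF diagnostics as the module count grows."""

    n_values: np.ndarray        # module counts probed (subset of 1..6)
    vaf_total: np.ndarray       # best total VAF per count
    min_vaf_local: np.ndarray   # worst local VAF of the best fit per count
    selected_n: int
    criterion_met: bool


@dataclass
class SimilarityResult:
    """Optimal module pairing between two module sets and its R values."""

    pairing: list[tuple[int, int]]
    r_values: np.ndarray
    mean_r: float
    sd_r: float
    n_above_critical: int = 0
    unmatched_a: list[int] = field(default_factory=list)
    unmatched_b: list[int] = field(default_factory=list)


@dataclass
class NullDistribution:
    """Similarity null from two sets of random modules."""

    r_samples: np.ndarray
    critical_r: float
    generator_mean: float
    generator_sd: float
    n_modules_per_set: int
    seed: int
    n_resampled: int = 0


@dataclass
class CrossFitResult:
    """VAF of a fixed module set fit to (possibly another group's) data."""

    vaf_by_k: np.ndarray
    source_group: str
    target_group: str
    vaf_crit: float | None = None


@dataclass
class MergeResult:
    """Reconstruction of one module set as nonnegative merges of another."""

    coefficients: np.ndarray        # (n_target_modules, n_basis_modules)
    reconstruction_r: np.ndarray    # (n_target_modules,)
    mean_r: float


@dataclass
class CorrelationResult:
    """7x7 pairwise coactivation matrix with optional bootstrap CIs."""

    R: np.ndarray
    ci_low: np.ndarray | None = None
    ci_high: np.ndarray | None = None
    significant: np.ndarray | None = None
    n_samples: int = 0
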