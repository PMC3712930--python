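# Methods

`musclemod` analyses how hand-muscle coordination patterns are modulated
across isometric tasks, and how that modulation degrades with hand
impairment after stroke.  The unit of analysis is one subject's trial
tensor: 6 tasks (wrist flexion WF, wrist extension WE, finger extension
FE, lateral pinch LP, power grip PG, tip pinch TP) x 16 repetitions x 7
muscle channels (THE, FDI, HTH, EDC, FDS, ECR/U, FCR/U), each entry an
MVC-normalized RMS activation.

## Preprocessing

Raw surface-EMG trials (nominally 3 s at 1000 Hz, hardware-bandpassed
20–500 Hz) are reduced to one scalar per muscle: a zero-phase 60 Hz IIR
notch (second order, Q = 30, applied forward–backward) removes mains
interference, the full-window RMS summarizes the trial, and each RMS is
divided by the electrode's maximum-voluntary-contraction RMS (the maximum
over all maximal-effort maneuvers on that electrode).  Supra-MVC values
are retained, not clipped: paretic muscles often produce task activations
above their depressed MVC reference.  The ECR/ECU and FCR/FCU pairs are
averaged into single wrist-extensor and wrist-flexor channels.  Whether
the MVC window should be the full maximal trial is unspecified in the
protocol we emulate; the full window is used.

## Inter-task separation (SED)

With `m_i(k)` the 7-vector of task `i`, trial `k`, and `m̄_i` its mean
over the 16 trials, the squared-Euclidean-distance matrix is

    d_ij = 100 · ‖m̄_i − m̄_j‖²                  (i ≠ j)
    d_ii = 100 · (1/(n−1)) Σ_k ‖m_i(k) − m̄_i‖²   (n = 16)

Off-diagonals measure inter-task separation, diagonals intra-task
variability (the within-group mean square of a one-way MANOVA, summed
over channels).  The x100 scale puts 0–1 normalized activations in
percent-like units.  Group-level tables are element-wise means of
subject-level matrices.  A one-way MANOVA (Wilks' lambda, F
approximation; pseudo-inverse fallback if the within-task scatter is
singular) tests task dependence overall, and per-muscle Tukey HSD over
the 15 task pairs (7 x 15 = 105 comparisons, alpha = 0.05, no further
correction) counts pairs with no significant difference — the index of
unmodulated muscles.

## Muscle modules

The 96 x 7 trial matrix `M` is factorized as `M ≈ H·C` with `H ≥ 0`
(per-trial recruitment coefficients) and `C ≥ 0` (modules, rows
max-normalized to 1 with `H` compensated).  Goodness of fit is the
uncentered variance accounted for,

    VAF = 100 · (1 − Σ(M − H·C)² / Σ M²),

in total and per muscle column (local VAF).  The module count is the
smallest n in 1..6 whose best fit exceeds total VAF 90 % with every local
VAF above 75 %; if none qualifies the 6-module fit is returned flagged.
The task tuning curve `W` is the per-task mean of the trial coefficients,
which reduces to the single-coefficient model exactly when trials repeat.

Optimization uses multiplicative-update NMF (Frobenius loss, tolerance
1e-6, max 2000 iterations; scikit-learn backend) restarted from 20 seeded
random initializations, keeping the restart with the highest VAF.  One
additional restart warm-starts from the best (n−1)-module fit plus a
small random extra module; because the updates are monotone this makes
the best-VAF curve nondecreasing in n.  Modules are ordered by descending
single-module VAF (ties by first dominant channel) for reproducible
output and cumulative-curve plots.  Fitting uses trial-level rows;
task-mean fitting is available for sensitivity analysis.

## Module similarity and its null

Similarity between modules is the cosine (normalized scalar product) of
the raw nonnegative vectors; a centered (Pearson) variant exists behind a
flag.  Two module sets are matched by the injective pairing that
maximizes mean similarity, found exhaustively (≤ 6 modules per set).
Chance level: two sets of 1,000 random modules are drawn with entries
Gaussian(mean, SD of the analyzed activation data) truncated at zero
(all-zero draws resampled), all 1,000,000 cross-set cosines are scored,
and the 95th percentile is the critical R.  Group similarity tables
stratify subjects by module count and pool paired-module R values over
distinct subject pairs per cell.

## Cross-fitting and merging

Fixing a module set and solving each trial row by nonnegative least
squares (Lawson–Hanson) measures how well one group's repertoire spans
another group's data; curves over the top-k modules use the extraction
ordering.  The critical VAF is the 95th percentile over 100 repetitions
of fitting k random modules (same null generator).  Separately, each
stroke module is reconstructed as a nonnegative combination of unimpaired
modules (per-module NNLS), scored by cosine; a module orthogonal to the
whole basis scores 0.  The nonnegativity constraint matters: even 7
random modules leave the critical VAF well below 100, unlike an
unconstrained rank argument would suggest.  Group-level cross-fits
extract group modules from the pooled (concatenated-subject) matrix;
per-subject cross-fits are also supported.

## Coactivation

Per subject, a 7 x 7 Pearson correlation matrix over the 96 trial-level
samples quantifies muscle-pair coupling across tasks (trial level, not
the 6 task means: within-task variability is part of the phenomenon and
6 samples would make bootstrap CIs vacuous).  Percentile-bootstrap CIs
(1000 resamples of the 96 rows) flag pairs whose correlation excludes
zero; degenerate resamples are dropped with a warning.  Workspace
projections return the 96 trials as a 3-D point cloud in a chosen muscle
triple (intrinsic: FDI/THE/HTH; extrinsic: FDS/EDC/FCR/U) plus the
fraction of variance on the first principal axis — near 1 means
amplitude-only modulation along a line.

## Synthetic subjects

The generator emulates the study conditions so every stage is testable
with known ground truth.  A subject is `activation(i,k) = W[i]·C + ε`,
ε ~ N(0, 0.05) truncated at zero (noise SD on the normalized scale,
default 0.05; truncation rather than resampling preserves the additive
model).  Impairment profiles:

- **unimpaired** (4–5 modules): canonical physiological templates shared
  across subjects — a THE+FDI grip module (pinch tasks; 5-module
  subjects split it into thumb-weighted lateral-pinch and index-weighted
  tip-pinch variants), an EDC+ECR/U extension module (WE/FE), an
  FDS+FCR/U flexion module (WF/PG) and an HTH module with a random
  partner.  Preferred-task weights U(1.0, 1.25), off-task U(0, 0.08).
- **moderate** (4 modules): the same templates with weaker tuning
  contrast (preferred U(0.85, 1.05), off U(0.03, 0.18)) and a 50 % chance
  per module of an extra strongly coupled muscle.
- **severe** (2–3 modules): idiosyncratic broad modules — 3–4 dominant
  muscles drawn at random (distinct sets, all 7 channels covered),
  suppressed baseline U(0, 0.1) elsewhere — recruited in disjoint
  strong-task blocks times a common per-task gain U(0.75, 1.05), i.e.
  largely amplitude-scaled versions of a stereotyped pattern.

Two structural choices are identifiability requirements rather than
phenomenology: every module owns a *private* dominant muscle (near-silent,
U(0, 0.05), in all other modules) and a *task of its own* (the HTH module
takes over one task from a two-task template).  Without either, a
module's contribution can be absorbed by the rest and its count is not
recoverable from the dual-VAF rule at any noise level.  Non-dominant
module entries are otherwise U(0, 0.3).

What the generator does **not** emulate: electrode noise and cross-talk,
task-to-task MVC drift, supra-MVC normalization artifacts, within-trial
temporal structure (a single scalar per trial, as in the isometric
design), subject-specific compensation strategies, and realistic SED
magnitudes (synthetic inter-task SED values run ~100–300 versus ~20–80
in real group tables; only orderings, not magnitudes, are asserted).
Passing tests therefore demonstrate the pipeline's correctness and its
sensitivity to the modeled contrasts, not performance on real EMG.

## Problem sizes and numerical choices

Recovery checks use 50 subjects per profile at noise SD 0.05; ordering
checks use 20 replicate cohorts of 4 subjects per group; bootstrap
calibration uses 500 simulated null datasets with 300 resamples each;
MANOVA calibration uses 200 null datasets.  NNLS tolerance is the scipy
default (machine-level); NMF restarts derive per-restart seeds from a
single seed sequence, so every result is reproducible bit-for-bit given
(data, seed).  Degenerate inputs are defined failures: all-zero data has
undefined VAF, zero modules have undefined cosine, zero-variance channels
propagate NaN/warnings rather than silent numbers.

## Known limitations

- The dual-VAF thresholds (90/75) are conventions inherited from the
  posture-synergy literature; the generator's identifiability margins are
  tuned to them, and data violating the private-muscle assumption (fully
  overlapping modules) will under-select by design of the criterion, not
  by a defect of the optimizer.
- Cosine similarity ignores overall module scale by construction; two
  modules differing only in a shared baseline offset score near 1.
- The random-module null inherits the truncated-Gaussian convention; a
  study using untruncated draws would obtain a slightly lower critical R.
- Group SED summaries average subject matrices element-wise; per-subject
  aggregates of the off-diagonal mean generally differ from the mean of
  the group matrix's off-diagonals, so the two summaries are reported
  separately and should not be compared across conventions.
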