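# musclemod

Analysis of task-specific modulation of hand-muscle coordination from
surface EMG — for motor-control and neurorehabilitation researchers who
want to quantify how far a subject's multi-muscle activation patterns
separate across manual tasks, and how that separation collapses with
hand impairment after stroke.

A subject performs 6 isometric tasks (wrist flexion/extension, finger
extension, lateral pinch, power grip, tip pinch), 16 trials each, while 7
muscle channels (THE, FDI, HTH, EDC, FDS, ECR/U, FCR/U) are recorded and
reduced to MVC-normalized RMS activations.  The package implements the
full analysis chain:

- **SED separation** — the squared-Euclidean-distance matrix
  `d_ij = 100·‖m̄_i − m̄_j‖²` between task-mean activation vectors
  (diagonal: within-task mean square), with one-way MANOVA (Wilks' Λ)
  and per-muscle Tukey HSD over all 15 task pairs × 7 muscles = 105
  comparisons.
- **Muscle modules** — nonnegative matrix factorization `M ≈ H·C` of the
  96×7 trial matrix; the module count is the smallest n with uncentered
  total VAF > 90 % and every per-muscle VAF > 75 % (best of ≥ 20
  restarts).
- **Module similarity** — cosine similarity with optimal injective
  pairing, against a critical R defined as the 95th percentile of
  1,000,000 cosines between random modules drawn from the data's own
  mean/SD.
- **Cross-fitting and merging** — NNLS fits of one group's modules to
  another group's data (with a random-module critical VAF), and
  reconstruction of stroke modules as nonnegative merges of unimpaired
  modules.
- **Coactivation** — 7×7 trial-level correlation matrices with
  percentile-bootstrap CIs, group means, and 3-D muscle-workspace
  projections.
- **Synthetic subjects** — a generator with known modular ground truth
  (severe 2–3 broad amplitude-gated modules, moderate 4, unimpaired 4–5
  sharply tuned canonical modules), used to validate every stage end to
  end.

## Worked example

```python
import musclemod as mm

truth = mm.make_subject_truth("moderate", seed=7)   # 4 true modules
trials = mm.simulate_trialset(truth)                # (6, 16, 7) tensor
modules, curve = mm.select_module_count(mm.stack_matrix(trials))
print(curve.selected_n, round(modules.vaf_total, 1))
```

prints `4 99.7`: the dual-VAF rule recovers the true 4-module structure,
whose best fit accounts for 99.7 % of the uncentered variance.  The VAF
curve behind that selection (from `examples/03_extract_modules.py`):

```
n  total VAF  min local VAF
1      68.2          42.8
2      82.3          43.7
3      95.6          59.7
4      99.7          99.5 <- selected
5      99.8          99.5
6      99.9          99.5
```

Three modules already clear the 90 % total threshold, but the worst
muscle is only fit at 59.7 % — the local criterion is what forces the
fourth module.  Matched against ground truth, the estimated modules have
cosine similarities `[1.0, 0.999, 0.997, 0.989]`.

The `examples/` directory has one short script per capability (simulation,
SED, modules, similarity, cross-fitting, coactivation).  A thin CLI wraps
the same library:

```
musclemod simulate --n-per-group 2 --seed 1 --out cohort.csv
musclemod run --input cohort.csv --schema norm7 --out results/
```

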