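"""Quantify inter-task separation vs intra-task variability (SED matrix).

Off-diagonal SED entries measure how far apart two tasks' mean 7-muscle
activation vectors lie (x100, on the MVC-normalized scale); diagonals
measure trial-to-trial variability within a task.  Larger off-diagonals
mean stronger task-specific modulation.
"""

import numpy as np

import musclemod as mm

for profile in ("severe", "unimpaired"):
    trials = mm.simulate_trialset(mm.make_subject_truth(profile, seed=3))
    sed = mm.sed_matrix(trials)
    off, diag = mm.separation_summary(sed)
    lam, p = mm.manova_tasks(trials)
    n_nonsig, n_total, _ = mm.tukey_pair_counts(trials)
    print(f"{profile}: mean inter-task SED {off:.1f}, mean intra-task {diag:.2f}, "
          f"Wilks lambda {lam:.2e} (p={p:.1e}), "
          f"Tukey nonsignificant {n_nonsig}/{n_total}")

# The severely impaired profile separates its tasks far less than the
# unimpaired one, while trial-to-trial variability is similar — the same
# contrast the SED analysis is designed to expose.
trials = mm.simulate_trialset(mm.make_subject_truth("unimpaired", seed=3))
print("\nSED matrix (canonical task order WF WE FE LP PG TP):")
print(np.array_str(mm.sed_matrix(trials).d, precision=1, suppress_small=True))
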