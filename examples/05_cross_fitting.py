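"""Fit one group's modules to another's data, and merge-reconstruct modules.

Cross-fitting holds the modules fixed and solves only for nonnegative
per-trial weights (NNLS); the resulting VAF says how well one repertoire
spans another group's activation workspace.  The critical VAF is the
chance level reached by random modules.
"""

import numpy as np

import musclemod as mm

cohort = mm.simulate_cohort(n_per_group=3, seed=5)
sev_ts, sev_tr = next((p for p in cohort if p[1].profile == "severe"))
uni_sets = [tr.C_true for _, tr in cohort if tr.profile == "unimpaired"]
mod_sets = [tr.C_true for _, tr in cohort if tr.profile == "moderate"]

data = mm.stack_matrix(sev_ts)
own = mm.cross_vaf_curve(data, sev_tr.C_true, "severe", "severe")
cross = mm.cross_vaf_curve(data, uni_sets[0], "unimpaired", "severe")
crit = mm.vaf_crit_random(data, k=3, n_reps=100, seed=0)
print("VAF of severe subject's data, by number of modules used:")
print("  own modules:       ", np.round(own.vaf_by_k, 1))
print("  unimpaired modules:", np.round(cross.vaf_by_k[:4], 1))
print(f"  critical VAF (3 random modules, 95th pct): {crit:.1f}")

basis = np.vstack(uni_sets)
for name, sets in (("moderate", mod_sets), ("severe", [sev_tr.C_true])):
    rs = [mm.merge_reconstruct(C, basis).mean_r for C in sets]
    print(f"merge of {name} modules from unimpaired basis: mean R {np.mean(rs):.3f}")
# Moderate modules are near-perfect nonnegative merges of unimpaired ones;
# severe modules fall partly outside that cone.
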