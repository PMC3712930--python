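"""Extract muscle modules by NMF and select the count by the dual VAF rule.

The module count is the smallest n whose best-of-20-restarts factorization
has total VAF > 90% and every per-muscle (local) VAF > 75%.
"""

import numpy as np

import musclemod as mm

truth = mm.make_subject_truth("moderate", seed=7)
trials = mm.simulate_trialset(truth)
data = mm.stack_matrix(trials)

modules, curve = mm.select_module_count(data)
print("n  total VAF  min local VAF")
for n, v, lo in zip(curve.n_values, curve.vaf_total, curve.min_vaf_local):
    mark = " <- selected" if n == curve.selected_n else ""
    print(f"{n}  {v:8.1f}  {lo:12.1f}{mark}")

print(f"\ntrue module count: {truth.n_mod}, selected: {curve.selected_n}")
pairing = mm.optimal_pairing(modules, truth.C_true)
print("cosine similarity of matched estimated-vs-true modules:",
      np.round(pairing.r_values, 3))
print("modules (rows; channels THE FDI HTH EDC FDS ECR/U FCR/U):")
print(np.array_str(modules.C, precision=2, suppress_small=True))
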