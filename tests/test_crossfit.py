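"""Fixed-module NNLS fitting, cross-VAF curves, critical VAF, module merging."""

from itertools import combinations

import numpy as np
import pytest

import musclemod as mm


def nnls_oracle(A, b):
    """Brute-force NNLS: enumerate active sets, solve LS, keep best feasible."""
    n = A.shape[1]
    best_x, best_err = np.zeros(n), np.linalg.norm(b)
    for k in range(1, n + 1):
        for support in combinations(range(n), k):
            xs, *_ = np.linalg.lstsq(A[:, support], b, rcond=None)
            if np.all(xs >= -1e-12):
                x = np.zeros(n)
                x[list(support)] = np.clip(xs, 0, None)
                err = np.linalg.norm(A @ x - b)
                if err < best_err - 1e-12:
                    best_x, best_err = x, err
    return best_x


class TestFitWeightsFixedModules:
    def test_exact_representation(self):
        C = np.zeros((2, 7))
        C[0, 0] = C[1, 1] = 1.0
        row = np.zeros(7)
        row[:2] = [0.3, 0.7]
        H, vaf = mm.fit_weights_fixed_modules(row, C)
        assert np.allclose(H[0], [0.3, 0.7])
        assert vaf == pytest.approx(100.0)

    def test_closed_form_single_module(self):
        """C = (1, 0.5, 0...), row (1, 1, 0...): weight 1.2, VAF 90."""
        C = np.zeros((1, 7))
        C[0, :2] = [1.0, 0.5]
        row = np.zeros(7)
        row[:2] = 1.0
        H, vaf = mm.fit_weights_fixed_modules(row, C)
        assert H[0, 0] == pytest.approx(1.2)
        assert vaf == pytest.approx(90.0)

    def test_orthogonal_data_gets_zero_weights(self):
        C = np.zeros((2, 7))
        C[0, 0] = C[1, 1] = 1.0
        row = np.zeros(7)
        row[2] = 0.8
        H, vaf = mm.fit_weights_fixed_modules(row, C)
        assert np.allclose(H, 0.0)
        assert vaf == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_active_set_oracle_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        C = rng.uniform(0, 1, (3, 7))
        data = rng.uniform(0, 1, (3, 7))
        H, _ = mm.fit_weights_fixed_modules(data, C)
        for i, row in enumerate(data):
            assert np.allclose(H[i], nnls_oracle(C.T, row), atol=1e-6)


class TestCrossVafCurve:
    def test_own_modules_on_noiseless_data_reach_100(self, noiseless_truth, noiseless_trials):
        data = mm.stack_matrix(noiseless_trials)
        res = mm.cross_vaf_curve(data, noiseless_truth.C_true)
        assert res.vaf_by_k[-1] == pytest.approx(100.0, abs=1e-6)

    def test_curve_nondecreasing(self, moderate_trials, moderate_truth):
        data = mm.stack_matrix(moderate_trials)
        ms = mm.fit_nmf(data, 4, seed=0)
        res = mm.cross_vaf_curve(data, ms)
        assert np.all(np.diff(res.vaf_by_k) >= -1e-9)

    def test_severe_first_module_explains_more_everywhere(self):
        """Broad severe modules beat task-specific unimpaired modules at k=1."""
        wins = 0
        for rep in range(5):
            cohort = mm.simulate_cohort(n_per_group=2, seed=300 + rep)
            sev = next(tr.C_true for _, tr in cohort if tr.profile == "severe")
            uni = next(tr.C_true for _, tr in cohort if tr.profile == "unimpaired")
            data = np.concatenate([mm.stack_matrix(ts) for ts, _ in cohort])
            v_sev = mm.cross_vaf_curve(data, sev).vaf_by_k[0]
            v_uni = mm.cross_vaf_curve(data, uni).vaf_by_k[0]
            wins += v_sev > v_uni
        assert wins >= 4


class TestVafCritRandom:
    def test_critical_vaf_grows_with_basis_size(self, moderate_trials):
        """More random modules explain more variance; the nonnegativity
        constraint on the coefficients keeps even 7 modules well short of a
        perfect fit."""
        data = mm.stack_matrix(moderate_trials)
        crits = [mm.vaf_crit_random(data, k, n_reps=20, seed=0)
                 for k in (1, 2, 3, 5, 7)]
        assert all(a <= b + 1e-9 for a, b in zip(crits, crits[1:]))
        assert crits[-1] > crits[0] + 10
        assert crits[-1] <= 100.0

    def test_deterministic_given_seed(self, moderate_trials):
        data = mm.stack_matrix(moderate_trials)
        a = mm.vaf_crit_random(data, 3, n_reps=20, seed=2)
        b = mm.vaf_crit_random(data, 3, n_reps=20, seed=2)
        assert a == b

    def test_true_modules_beat_critical_vaf(self, moderate_trials, moderate_truth):
        data = mm.stack_matrix(moderate_trials)
        _, vaf = mm.fit_weights_fixed_modules(data, moderate_truth.C_true)
        vc = mm.vaf_crit_random(data, moderate_truth.n_mod, n_reps=100, seed=0)
        assert vaf > vc


class TestMergeReconstruct:
    def test_module_present_in_basis_reconstructs_exactly(self):
        rng = np.random.default_rng(0)
        basis = rng.uniform(0.05, 1, (4, 7))
        res = mm.merge_reconstruct(basis[1][None, :], basis)
        assert res.reconstruction_r[0] == pytest.approx(1.0)
        coef = res.coefficients[0]
        assert coef[1] == pytest.approx(1.0, abs=1e-6)
        assert np.allclose(np.delete(coef, 1), 0.0, atol=1e-6)

    def test_exact_merge_of_two_modules(self):
        rng = np.random.default_rng(1)
        basis = rng.uniform(0.05, 1, (3, 7))
        target = 0.5 * basis[0] + 0.5 * basis[2]
        res = mm.merge_reconstruct(target[None, :], basis)
        assert res.reconstruction_r[0] == pytest.approx(1.0)
        assert res.coefficients[0] == pytest.approx([0.5, 0.0, 0.5], abs=1e-8)

    def test_orthogonal_module_scores_zero(self):
        basis = np.zeros((2, 7))
        basis[0, 0] = basis[1, 1] = 1.0
        target = np.zeros((1, 7))
        target[0, 2] = 1.0
        res = mm.merge_reconstruct(target, basis)
        assert res.reconstruction_r[0] == pytest.approx(0.0)

    def test_moderate_modules_merge_better_than_severe(self):
        """Canonical moderate modules lie near the unimpaired module cone;
        idiosyncratic broad severe modules fall partly outside it."""
        wins = 0
        for rep in range(8):
            cohort = mm.simulate_cohort(n_per_group=3, seed=500 + rep)
            basis = np.vstack([tr.C_true for _, tr in cohort
                               if tr.profile == "unimpaired"])
            mean_r = {}
            for g in ("severe", "moderate"):
                rs = [mm.merge_reconstruct(tr.C_true, basis).mean_r
                      for _, tr in cohort if tr.profile == g]
                mean_r[g] = np.mean(rs)
            wins += mean_r["moderate"] > mean_r["severe"]
        assert wins >= 7
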