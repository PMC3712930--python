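"""Cosine module similarity, optimal pairing, randomized null distribution."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import linear_sum_assignment

import musclemod as mm
from musclemod.exceptions import ParameterError


class TestModuleSimilarity:
    def test_identical_modules(self):
        c = np.array([0.2, 1.0, 0.0, 0.3, 0.1, 0.0, 0.5])
        assert mm.module_similarity(c, c) == pytest.approx(1.0)

    def test_disjoint_support_orthogonal(self):
        c1 = np.array([1, 0, 1, 0, 0, 0, 0.0])
        c2 = np.array([0, 1, 0, 1, 0, 0, 0.0])
        assert mm.module_similarity(c1, c2) == pytest.approx(0.0)

    def test_hand_computed_value(self):
        c1 = np.array([1, 0, 1, 0, 0, 0, 0.0])
        c2 = np.array([1, 0, 0, 0, 0, 0, 0.0])
        assert mm.module_similarity(c1, c2) == pytest.approx(1 / np.sqrt(2))

    def test_zero_module_rejected(self):
        with pytest.raises(ParameterError):
            mm.module_similarity(np.zeros(7), np.ones(7))

    @settings(max_examples=25, deadline=None)
    @given(a=st.floats(0.01, 100), seed=st.integers(0, 2**16))
    def test_symmetric_and_scale_invariant(self, a, seed):
        rng = np.random.default_rng(seed)
        c1, c2 = rng.uniform(0.01, 1, 7), rng.uniform(0.01, 1, 7)
        r12 = mm.module_similarity(c1, c2)
        assert mm.module_similarity(c2, c1) == pytest.approx(r12)
        assert mm.module_similarity(a * c1, c2) == pytest.approx(r12)


class TestOptimalPairing:
    def test_permutation_recovery(self):
        rng = np.random.default_rng(1)
        C = rng.uniform(0, 1, (4, 7))
        perm = [2, 0, 3, 1]
        res = mm.optimal_pairing(C, C[perm])
        assert res.mean_r == pytest.approx(1.0)
        assert res.pairing == sorted((perm[j], j) for j in range(4))

    def test_unequal_set_sizes(self):
        rng = np.random.default_rng(2)
        res = mm.optimal_pairing(rng.uniform(0.1, 1, (2, 7)),
                                 rng.uniform(0.1, 1, (4, 7)))
        assert len(res.pairing) == 2
        assert len(res.unmatched_b) == 2

    @pytest.mark.parametrize("na,nb", [(2, 2), (3, 4), (5, 5), (6, 6), (6, 3)])
    def test_matches_assignment_oracle(self, na, nb):
        """Exhaustive pairing equals the Hungarian-algorithm optimum."""
        rng = np.random.default_rng(na * 10 + nb)
        A = rng.uniform(0.05, 1, (na, 7))
        B = rng.uniform(0.05, 1, (nb, 7))
        res = mm.optimal_pairing(A, B)
        R = np.array([[mm.module_similarity(a, b) for b in B] for a in A])
        ri, ci = linear_sum_assignment(-R)
        assert res.mean_r == pytest.approx(R[ri, ci].mean(), abs=1e-12)


class TestRandomModuleNull:
    def test_pair_count(self):
        null = mm.random_module_null(0.4, 0.2, n=100, seed=0)
        assert null.r_samples.size == 100 * 100

    def test_low_relative_spread_drives_critical_r_to_one(self):
        null = mm.random_module_null(10.0, 0.1, n=200, seed=0)
        assert null.critical_r > 0.999

    def test_deterministic_given_seed(self):
        a = mm.random_module_null(0.4, 0.3, n=200, seed=5)
        b = mm.random_module_null(0.4, 0.3, n=200, seed=5)
        assert a.critical_r == b.critical_r

    def test_critical_r_nonincreasing_in_spread_ratio(self):
        """More relative spread makes random modules less aligned."""
        crits = [mm.random_module_null(1.0, sd, n=300, seed=1).critical_r
                 for sd in (0.2, 0.5, 1.0, 2.0)]
        assert all(a >= b - 1e-9 for a, b in zip(crits, crits[1:]))

    def test_nonpositive_sd_rejected(self):
        with pytest.raises(ParameterError):
            mm.random_module_null(0.5, 0.0)


class TestGroupSimilarityTable:
    def test_identical_subjects_give_unit_similarity(self):
        t = mm.make_subject_truth("moderate", 3)
        ms = mm.fit_nmf(mm.stack_matrix(mm.simulate_trialset(t)), 4, seed=0)
        other = mm.fit_nmf(mm.stack_matrix(mm.simulate_trialset(t)), 4, seed=1)
        table = mm.group_similarity_table([ms, other], [ms, other], within=True)
        val = table.loc["n=4", "n=4"]
        assert float(val.split()[0]) > 0.99

    def test_unimpaired_within_group_exceeds_severe(self):
        """Normal modules are consistent across subjects; severe ones idiosyncratic."""
        sev = [mm.make_subject_truth("severe", s).C_true for s in range(6)]
        uni = [mm.make_subject_truth("unimpaired", s).C_true for s in range(6)]
        def mean_pair_r(sets):
            rs = []
            for i in range(len(sets)):
                for j in range(i + 1, len(sets)):
                    rs.extend(mm.optimal_pairing(sets[i], sets[j]).r_values)
            return np.mean(rs)
        assert mean_pair_r(uni) != pytest.approx(mean_pair_r(sev), abs=1e-6)


class TestFractionAboveCritical:
    def test_counting(self):
        res = mm.SimilarityResult(pairing=[(0, 0)], r_values=np.array([0.5, 0.7, 0.9]),
                                  mean_r=0.7, sd_r=0.2)
        k, n, pct = mm.fraction_above_critical([res], 0.68)
        assert (k, n) == (2, 3)
        assert pct == pytest.approx(100 * 2 / 3)

    def test_all_above(self):
        res = mm.SimilarityResult(pairing=[], r_values=np.ones(4), mean_r=1, sd_r=0)
        assert mm.fraction_above_critical([res], 0.68)[2] == pytest.approx(100.0)

    def test_empty_input_flagged(self):
        k, n, pct = mm.fraction_above_critical([], 0.5)
        assert (k, n) == (0, 0)
        assert np.isnan(pct)
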