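"""NMF module extraction, VAF formulas and model-count selection."""

import numpy as np
import pytest

import musclemod as mm
from musclemod.datatypes import Config
from musclemod.exceptions import ParameterError
from tests.conftest import make_trialset


class TestStackMatrix:
    def test_shape_and_indexing_contract(self, moderate_trials):
        data = mm.stack_matrix(moderate_trials)
        assert data.shape == (96, 7)
        assert np.array_equal(data[16], moderate_trials.activations[1, 0])

    def test_round_trip(self, moderate_trials):
        data = mm.stack_matrix(moderate_trials)
        assert np.array_equal(mm.unstack_matrix(data), moderate_trials.activations)


class TestVafFormulas:
    def test_perfect_reconstruction_scores_100(self):
        data = np.random.default_rng(0).uniform(0, 1, (10, 7))
        assert mm.vaf_total(data, data) == pytest.approx(100.0)
        assert np.allclose(mm.vaf_local(data, data), 100.0)

    def test_zero_reconstruction_scores_0(self):
        data = np.random.default_rng(1).uniform(0.1, 1, (10, 7))
        assert mm.vaf_total(data, np.zeros_like(data)) == pytest.approx(0.0)
        assert np.allclose(mm.vaf_local(data, np.zeros_like(data)), 0.0)

    def test_hand_computed_uncentered_vaf(self):
        """data [[1,0],[0,1]], recon half: 100*(1 - 0.5/2) = 75 (embedded in 7 cols)."""
        data = np.zeros((2, 7))
        recon = np.zeros((2, 7))
        data[0, 0] = data[1, 1] = 1.0
        recon[0, 0] = recon[1, 1] = 0.5
        assert mm.vaf_total(data, recon) == pytest.approx(75.0)
        local = mm.vaf_local(data, recon)
        assert local[0] == pytest.approx(75.0)
        assert local[1] == pytest.approx(75.0)

    def test_local_vaf_is_columnwise(self):
        data = np.zeros((2, 7))
        data[:, 0] = [1.0, 2.0]
        data[:, 1] = [1.0, 0.0]
        recon = data.copy()
        recon[0, 1] = 0.5       # only column 1 misfit: 100*(1-0.25/1) = 75
        local = mm.vaf_local(data, recon)
        assert local[0] == pytest.approx(100.0)
        assert local[1] == pytest.approx(75.0)

    def test_all_zero_data_rejected(self):
        with pytest.raises(ParameterError):
            mm.vaf_total(np.zeros((3, 7)), np.zeros((3, 7)))

    def test_all_zero_column_flagged_nan(self):
        data = np.ones((4, 7))
        data[:, 2] = 0.0
        assert np.isnan(mm.vaf_local(data, data)[2])


class TestFitNmf:
    def test_rank_one_exact_recovery(self):
        rng = np.random.default_rng(5)
        h = rng.uniform(0.2, 1.0, 96)
        c = rng.uniform(0.0, 1.0, 7)
        data = np.outer(h, c)
        ms = mm.fit_nmf(data, 1, seed=0)
        assert ms.vaf_total >= 99.999
        assert mm.module_similarity(ms.C[0], c) >= 0.999

    def test_noiseless_subject_recovered_at_true_count(self, noiseless_truth, noiseless_trials):
        ms = mm.fit_nmf(mm.stack_matrix(noiseless_trials), noiseless_truth.n_mod, seed=0)
        assert ms.vaf_total >= 99.9

    def test_deterministic_given_seed(self, moderate_trials):
        data = mm.stack_matrix(moderate_trials)
        a = mm.fit_nmf(data, 3, seed=4)
        b = mm.fit_nmf(data, 3, seed=4)
        assert np.array_equal(a.C, b.C)
        assert np.array_equal(a.H_trial, b.H_trial)

    def test_max_normalization_preserves_product(self, moderate_trials):
        ms = mm.fit_nmf(mm.stack_matrix(moderate_trials), 4, seed=0)
        assert np.allclose(ms.C.max(axis=1), 1.0)
        # reconstruction consistency: re-scaling C rows with H compensated
        data = mm.stack_matrix(moderate_trials)
        assert mm.vaf_total(data, ms.reconstruction()) == pytest.approx(ms.vaf_total, abs=1e-8)

    def test_modules_ordered_by_single_module_vaf(self, moderate_trials):
        data = mm.stack_matrix(moderate_trials)
        ms = mm.fit_nmf(data, 4, seed=0)
        vafs = [mm.vaf_total(data, np.outer(ms.H_trial[:, j], ms.C[j]))
                for j in range(4)]
        assert vafs == sorted(vafs, reverse=True)


class TestSelectModuleCount:
    def test_noiseless_subject_selects_true_count(self, noiseless_truth, noiseless_trials):
        ms, curve = mm.select_module_count(mm.stack_matrix(noiseless_trials))
        assert curve.selected_n == noiseless_truth.n_mod
        assert curve.criterion_met

    def test_rank_one_data_selects_one(self):
        rng = np.random.default_rng(2)
        data = np.outer(rng.uniform(0.2, 1.0, 96), rng.uniform(0.1, 1.0, 7))
        _, curve = mm.select_module_count(data, stop_at_selection=True)
        assert curve.selected_n == 1

    def test_vaf_curve_nondecreasing(self, moderate_trials):
        _, curve = mm.select_module_count(mm.stack_matrix(moderate_trials))
        assert np.all(np.diff(curve.vaf_total) >= -1e-9)

    def test_stop_at_selection_matches_full_scan(self, moderate_trials):
        data = mm.stack_matrix(moderate_trials)
        _, full = mm.select_module_count(data)
        _, early = mm.select_module_count(data, stop_at_selection=True)
        assert full.selected_n == early.selected_n


class TestFirstModuleVaf:
    def test_rank_one_data_scores_100(self):
        rng = np.random.default_rng(3)
        data = np.outer(rng.uniform(0.2, 1.0, 96), rng.uniform(0.1, 1.0, 7))
        assert mm.first_module_vaf(data) >= 99.99

    def test_equal_energy_orthogonal_blocks_score_half(self):
        """Two orthogonal equal-energy rank-1 blocks: one module explains ~50%."""
        data = np.zeros((96, 7))
        data[:48, 0] = 1.0
        data[48:, 1] = 1.0
        assert mm.first_module_vaf(data) == pytest.approx(50.0, abs=0.5)
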