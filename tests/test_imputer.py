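"""Target partitioning, input-gene selection, training, selective merge."""

import numpy as np
import pytest

from convimpute import ExpressionMatrix
from convimpute.dropout import DropoutProbMatrix
from convimpute.imputer import (PAD, ImputationConfig, TargetSubset,
                                build_submodel, impute_matrix,
                                make_training_arrays, partition_targets,
                                select_input_genes, train_submodel)


class TestPartitionTargets:
    def test_ceiling_split_with_padding(self):
        subsets = partition_targets(np.arange(1100), N=512)
        assert len(subsets) == 3
        last = subsets[-1].target_gene_indices
        assert (last[:76] != PAD).all()
        assert (last[76:] == PAD).all()

    def test_exact_fit_no_padding(self):
        subsets = partition_targets(np.arange(512), N=512)
        assert len(subsets) == 1
        assert (subsets[0].target_gene_indices != PAD).all()

    def test_concatenation_recovers_input_order(self, rng):
        targets = rng.permutation(900)
        subsets = partition_targets(targets, N=128)
        recon = np.concatenate([s.real_targets for s in subsets])
        np.testing.assert_array_equal(recon, targets)

    def test_empty_target_list_rejected(self):
        with pytest.raises(ValueError, match="empty target"):
            partition_targets(np.array([], dtype=int))


def _toy_problem(rng, n_genes=30, n_cells=60, n_targets=4, top=5):
    vals = rng.gamma(2.0, 1.0, size=(n_genes, n_cells))
    m = ExpressionMatrix(vals, [f"g{i}" for i in range(n_genes)],
                         [f"c{j}" for j in range(n_cells)], "log_cpm")
    dp = DropoutProbMatrix(np.zeros((n_genes, n_cells)), list(m.gene_ids),
                           list(m.cell_ids))
    cfg = ImputationConfig(subset_size=n_targets, input_top=top, seed=0)
    sub = TargetSubset(np.arange(n_targets, dtype=np.int64))
    return m, dp, cfg, sub


class TestSelectInputGenes:
    def test_perfectly_correlated_candidate_ranks_first(self, rng):
        m, dp, cfg, sub = _toy_problem(rng)
        m.values[10] = m.values[0] * 2.0 + 1.0  # r = 1 with target 0
        inputs = select_input_genes(sub, m, dp, cfg)
        assert inputs[0] == 10

    def test_targets_excluded_and_inputs_unique(self, rng):
        m, dp, cfg, sub = _toy_problem(rng)
        inputs = select_input_genes(sub, m, dp, cfg)
        real = inputs[inputs != PAD]
        assert len(set(real)) == len(real)
        assert not set(real) & set(sub.real_targets.tolist())
        assert inputs.size == cfg.subset_size * cfg.input_top

    def test_duplicate_target_rows_dedup_to_five_inputs(self, rng):
        m, dp, cfg, _ = _toy_problem(rng)
        m.values[1] = m.values[0]  # duplicated target expression
        sub = TargetSubset(np.array([0, 1], dtype=np.int64))
        cfg2 = ImputationConfig(subset_size=2, input_top=5, seed=0)
        inputs = select_input_genes(sub, m, dp, cfg2)
        real = inputs[inputs != PAD]
        assert len(real) == 5  # identical top-5, dedup keeps one copy

    def test_high_dropout_candidates_excluded(self, rng):
        m, dp, cfg, sub = _toy_problem(rng)
        dp.dp[20, :] = 0.9  # dropout fraction 1 > P
        inputs = select_input_genes(sub, m, dp, cfg)
        assert 20 not in inputs[inputs != PAD]

    def test_empty_candidate_pool_raises(self, rng):
        m, dp, cfg, sub = _toy_problem(rng)
        dp.dp[:, :] = 0.9
        with pytest.raises(ValueError, match="input_dropout_max"):
            select_input_genes(sub, m, dp, cfg)

    def test_coexpression_module_recovered(self, rng):
        """Inputs for module-gene targets come from the same module."""
        n_cells = 120
        factor = rng.gamma(3.0, 1.0, n_cells)
        module = np.stack([factor * rng.uniform(0.5, 2.0)
                           + rng.normal(0, 0.1, n_cells) for _ in range(12)])
        noise = rng.gamma(2.0, 1.0, size=(30, n_cells))
        vals = np.vstack([module, noise]).clip(0)
        m = ExpressionMatrix(vals, [f"g{i}" for i in range(42)],
                             [f"c{j}" for j in range(n_cells)], "log_cpm")
        dp = DropoutProbMatrix(np.zeros_like(vals), list(m.gene_ids),
                               list(m.cell_ids))
        cfg = ImputationConfig(subset_size=4, input_top=5, seed=0)
        sub = TargetSubset(np.arange(4, dtype=np.int64))  # module genes
        inputs = select_input_genes(sub, m, dp, cfg)
        real = inputs[inputs != PAD]
        frac_module = np.mean([g < 12 for g in real])
        assert frac_module >= 0.8


class TestTraining:
    def test_linear_teacher_learnable(self):
        """A noiseless local linear map is driven below 0.01 training MSE."""
        rng = np.random.default_rng(0)
        X = np.abs(rng.normal(2, 1, (300, 40)))
        W = np.zeros((40, 8))
        for t in range(8):
            W[5 * t:5 * t + 5, t] = rng.uniform(0.1, 0.5, 5)
        Y = X @ W
        cfg = ImputationConfig(subset_size=8, input_top=5, max_epochs=900,
                               patience=900, learning_rate=3e-3,
                               dropout_rate=0.0, dense_units=256, seed=0)
        model = train_submodel(X, Y, cfg, rng=np.random.default_rng(0))
        assert model.history["train"][-1] < 0.01
        assert model.stopped_epoch <= cfg.max_epochs

    def test_same_seed_identical_history(self, rng):
        X = rng.normal(2, 1, (80, 16)).clip(0)
        Y = rng.normal(1, 1, (80, 4)).clip(0)
        cfg = ImputationConfig(subset_size=4, input_top=4, max_epochs=8,
                               dense_units=32, seed=7)
        m1 = train_submodel(X, Y, cfg, rng=np.random.default_rng(7))
        m2 = train_submodel(X, Y, cfg, rng=np.random.default_rng(7))
        assert m1.history == m2.history

    def test_early_stopping_bounds_epochs(self, rng):
        X = rng.normal(2, 1, (60, 16)).clip(0)
        Y = rng.normal(1, 1, (60, 4)).clip(0)  # pure noise: stops early
        cfg = ImputationConfig(subset_size=4, input_top=4, max_epochs=150,
                               dense_units=16, patience=5, seed=0)
        m = train_submodel(X, Y, cfg, rng=np.random.default_rng(0))
        assert m.stopped_epoch <= 150
        assert len(m.history["val"]) == m.stopped_epoch


class TestPaddingInsulation:
    def test_padded_run_matches_unpadded_on_real_slots(self, rng):
        """76 real targets inside a 512-slot padded model train identically
        to a dedicated 76-output model sharing the same initial weights."""
        n_cells, n_in, n_real, n_pad = 120, 64, 19, 128
        X = rng.gamma(2.0, 1.0, (n_cells, n_in))
        Yreal = rng.gamma(1.5, 1.0, (n_cells, n_real))
        Ypad = np.full((n_cells, n_pad), -1.0)
        Ypad[:, :n_real] = Yreal

        cfg = ImputationConfig(subset_size=n_pad, input_top=5, max_epochs=6,
                               dense_units=64, dropout_rate=0.3, seed=0)
        # float64 so the comparison is not limited by summation-order noise
        pad_net, _ = build_submodel(n_in, n_pad, cfg, np.random.default_rng(3),
                                    dtype=np.float64)
        small_net, _ = build_submodel(n_in, n_real, cfg,
                                      np.random.default_rng(4),
                                      dtype=np.float64)
        # share every weight; slice the output layer down to the real slots
        w_pad = pad_net.get_weights()
        w_small = list(w_pad)
        w_small[-2] = w_pad[-2][:, :n_real]
        w_small[-1] = w_pad[-1][:n_real]
        small_net.set_weights(w_small)

        mp = train_submodel(X, Ypad, cfg, network=pad_net,
                            rng=np.random.default_rng(9), dtype=np.float64)
        ms = train_submodel(X, Yreal, cfg, network=small_net,
                            rng=np.random.default_rng(9), dtype=np.float64)
        np.testing.assert_allclose(mp.history["train"], ms.history["train"],
                                   atol=1e-6)
        np.testing.assert_allclose(mp.history["val"], ms.history["val"],
                                   atol=1e-6)


class TestImputeMatrix:
    def _setup(self, rng, with_dropout=True):
        n_genes, n_cells = 40, 80
        vals = rng.gamma(2.0, 1.0, size=(n_genes, n_cells))
        m = ExpressionMatrix(vals, [f"g{i}" for i in range(n_genes)],
                             [f"c{j}" for j in range(n_cells)], "log_cpm")
        dp_vals = np.zeros((n_genes, n_cells))
        if with_dropout:
            high = rng.random((n_genes, n_cells)) < 0.1
            dp_vals[high] = 0.9
        dp = DropoutProbMatrix(dp_vals, list(m.gene_ids), list(m.cell_ids))
        labels = np.zeros(n_cells, dtype=int)
        cfg = ImputationConfig(subset_size=16, input_top=3, max_epochs=4,
                               dense_units=32, seed=0)
        return m, dp, labels, cfg

    def test_no_op_when_dp_below_threshold(self, rng):
        m, dp, labels, cfg = self._setup(rng, with_dropout=False)
        imputed, report = impute_matrix(m, dp, labels, cfg)
        np.testing.assert_array_equal(imputed.values, m.values)
        assert report["n_imputed"] == 0

    def test_selective_imputation_invariant(self, rng):
        m, dp, labels, cfg = self._setup(rng)
        imputed, report = impute_matrix(m, dp, labels, cfg)
        untouched = dp.dp <= cfg.dp_threshold
        assert (imputed.values[untouched] == m.values[untouched]).all()
        changed = imputed.values != m.values
        assert changed.sum() <= (dp.dp > cfg.dp_threshold).sum()
        assert report["n_imputed"] == (dp.dp > cfg.dp_threshold).sum()
        assert (imputed.values >= 0).all()

    def test_report_bookkeeping(self, rng):
        m, dp, labels, cfg = self._setup(rng)
        _, report = impute_matrix(m, dp, labels, cfg)
        n_subsets = int(np.ceil(report["n_targets"] / cfg.subset_size))
        assert len(report["models"]) == n_subsets  # single cluster
        for entry in report["models"]:
            assert entry["stopped_epoch"] <= cfg.max_epochs


class TestEndToEndRecovery:
    def test_masked_entries_recovered_from_coexpression(self):
        """With planted co-expression and extra masking, imputed values
        correlate with the hidden truth (r >= 0.7) and beat zero-filling."""
        rs = []
        for seed in (0, 1, 2):
            rng = np.random.default_rng(seed)
            n_cells, n_mod = 200, 30
            factor = rng.gamma(3.0, 1.0, n_cells)
            truth = np.stack([
                factor * rng.uniform(0.5, 1.5) + rng.normal(0, 0.2, n_cells)
                for _ in range(n_mod)
            ]).clip(0)
            noise = rng.gamma(2.0, 1.0, size=(20, n_cells))
            full = np.vstack([truth, noise])
            # mask 10% of entries of a third of the module genes, leaving
            # the rest of the module available as informative inputs
            mask = np.zeros_like(full, dtype=bool)
            mask[:n_mod // 3] = rng.random((n_mod // 3, n_cells)) < 0.1
            observed = np.where(mask, 0.0, full)
            m = ExpressionMatrix(observed, [f"g{i}" for i in range(50)],
                                 [f"c{j}" for j in range(n_cells)], "log_cpm")
            dp_vals = np.where(mask, 0.95, 0.0)
            dp = DropoutProbMatrix(dp_vals, list(m.gene_ids), list(m.cell_ids))
            cfg = ImputationConfig(subset_size=32, input_top=5, max_epochs=80,
                                   patience=15, learning_rate=3e-3,
                                   dense_units=64, seed=seed)
            imputed, _ = impute_matrix(m, dp, np.zeros(n_cells, dtype=int), cfg)
            pred = imputed.values[mask]
            true = full[mask]
            r = np.corrcoef(pred, true)[0, 1]
            rs.append(r)
            mse_model = ((pred - true) ** 2).mean()
            mse_zero = (true ** 2).mean()
            assert mse_model < mse_zero
        assert np.median(rs) >= 0.7
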