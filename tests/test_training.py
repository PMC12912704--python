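import numpy as np
import pytest
from dataclasses import replace

from stimpute.core_data import GeneMask, build_gene_mask, lognorm
from stimpute.training import (
    Checkpoint,
    TrainConfig,
    impute,
    run_crossval,
    train,
    training_loss,
)

MICRO = TrainConfig(
    max_iters=25, batch_size=16, learning_rate=1e-3, T=20,
    n_blocks=1, n_heads=2, width=16, encoder_hidden=8, encoder_layers=1,
    log_every=1, seed=3,
)


def _mask(n_cells, col):
    col = np.asarray(col, float)
    return GeneMask(m=np.broadcast_to(col, (n_cells, len(col))).copy(),
                    shared_genes=[f"g{i}" for i in np.flatnonzero(col)])


@pytest.fixture(scope="module")
def prepared(small_pair):
    ref = lognorm(small_pair.reference, target_sum=small_pair.reference.n_genes)
    st = lognorm(small_pair.st_observed,
                 target_sum=small_pair.st_observed.n_genes)
    return ref, st, build_gene_mask(ref, st)


@pytest.fixture(scope="module")
def trained(prepared):
    ref, st, mask = prepared
    return train(ref, mask, replace(MICRO, max_iters=60))


class TestTrainingLoss:
    def test_perfect_prediction_limit(self, rng):
        col = np.array([1.0] + [0.0] * 9)
        eps = rng.standard_normal((10_000, 10))
        lb = training_loss(eps, eps, _mask(1, col), alpha=2.8)
        assert lb.mse_term == 0.0
        assert lb.kl_term < 0.01

    def test_constant_shift_closed_form(self, rng):
        col = np.array([1.0, 0.0, 0.0])
        eps = rng.standard_normal((500, 3))
        shifted = eps + 0.7
        lb = training_loss(eps, shifted, _mask(1, col), alpha=0.0)
        assert lb.mse_term == pytest.approx(0.49, abs=1e-12)

    def test_alpha_zero_reduces_to_mse(self, rng):
        col = np.array([1.0, 0.0])
        eps = rng.standard_normal((50, 2))
        pred = rng.standard_normal((50, 2))
        lb = training_loss(eps, pred, _mask(1, col), alpha=0.0)
        assert lb.total == pytest.approx(lb.mse_term)

    def test_decomposition_identity(self, rng):
        col = np.array([1.0, 0.0, 0.0, 0.0])
        eps = rng.standard_normal((64, 4))
        pred = rng.standard_normal((64, 4))
        for alpha in (0.02, 2.8):
            lb = training_loss(eps, pred, _mask(1, col), alpha=alpha)
            assert lb.total == pytest.approx(lb.mse_term + alpha * lb.kl_term,
                                             rel=1e-12)

    def test_all_shared_mask_rejected(self, rng):
        eps = rng.standard_normal((4, 3))
        with pytest.raises(ValueError, match="masked"):
            training_loss(eps, eps, _mask(1, [1.0, 1.0, 1.0]), alpha=1.0)

    def test_gradient_zero_at_shared_entries(self, rng):
        """Finite differences: the loss is flat wrt predictions at
        shared-gene (mask = 1) entries of a 4 x 6 instance."""
        col = np.array([1.0, 0, 1, 0, 1, 0])
        eps = rng.standard_normal((4, 6))
        pred = rng.standard_normal((4, 6))
        m = _mask(4, col)
        h = 1e-6
        for i in range(4):
            for j in range(6):
                bumped = pred.copy()
                bumped[i, j] += h
                d = (training_loss(eps, bumped, m, 2.8).total
                     - training_loss(eps, pred, m, 2.8).total) / h
                if col[j] == 1:
                    assert d == 0.0
                else:
                    assert abs(d) > 1e-8

    def test_histogram_estimator_close_to_gaussian_for_normal_noise(self, rng):
        col = np.array([1.0, 0.0])
        eps = rng.standard_normal((20_000, 2))
        lb = training_loss(eps, eps, _mask(1, col), alpha=1.0,
                           kl_estimator="histogram")
        assert lb.kl_term < 0.05


class TestTrain:
    def test_smoke_loss_decreases(self, trained):
        totals = [r["total"] for r in trained.loss_trajectory]
        head = np.mean(totals[:5])
        tail = np.mean(totals[-5:])
        assert tail < head

    def test_decomposition_on_every_logged_step(self, trained, prepared):
        ref, _, mask = prepared
        alpha = trained.cfg.resolved_kl_weight(
            int(len(mask.column) - mask.column.sum()))
        for rec in trained.loss_trajectory:
            assert rec["total"] == pytest.approx(
                rec["mse"] + alpha * rec["kl"], rel=1e-9)

    def test_deterministic_trajectory(self, prepared):
        ref, _, mask = prepared
        a = train(ref, mask, replace(MICRO, max_iters=8))
        b = train(ref, mask, replace(MICRO, max_iters=8))
        assert a.loss_trajectory == b.loss_trajectory

    def test_no_bilstm_ablation_uses_identity_condition(self, prepared):
        ref, _, mask = prepared
        cp = train(ref, mask, replace(MICRO, max_iters=4, ablation="no_bilstm"))
        assert cp.encoder is None

    def test_only_variants_drop_kl(self):
        cfg = replace(MICRO, ablation="diffusion_xca_only")
        assert cfg.resolved_kl_weight(10) == 0.0
        assert replace(MICRO, ablation="full").resolved_kl_weight(10) == 2.8
        assert replace(MICRO, ablation="full").resolved_kl_weight(501) == 0.02


class TestImpute:
    def test_shared_columns_pinned_to_conditional(self, trained, prepared):
        _, st, mask = prepared
        out = impute(st, trained, seed=0)
        oi = out.gene_index()
        si = st.gene_index()
        for g in trained.gene_names:
            if trained.mask_column[trained.gene_names.index(g)] == 1:
                assert np.allclose(out.values[:, oi[g]], st.values[:, si[g]])

    def test_output_covers_all_reference_genes(self, trained, prepared):
        _, st, _ = prepared
        out = impute(st, trained, seed=0)
        assert out.gene_names == trained.gene_names
        assert out.n_cells == st.n_cells

    def test_seeds_differ_but_are_individually_deterministic(self, trained, prepared):
        _, st, _ = prepared
        a = impute(st, trained, seed=0)
        b = impute(st, trained, seed=1)
        c = impute(st, trained, seed=0)
        uq = trained.mask_column == 0
        assert not np.allclose(a.values[:, uq], b.values[:, uq])
        assert np.array_equal(a.values, c.values)

    def test_draw_averaging_reduces_sampler_noise(self, trained, prepared):
        _, st, _ = prepared
        uq = trained.mask_column == 0
        singles = [impute(st, trained, seed=s).values[:, uq] for s in (0, 1)]
        single_gap = np.mean((singles[0] - singles[1]) ** 2)
        avgs = [impute(st, trained, seed=s, n_draws=4).values[:, uq]
                for s in (0, 1)]
        avg_gap = np.mean((avgs[0] - avgs[1]) ** 2)
        assert avg_gap < single_gap

    def test_strided_sampler_runs_and_matches_shapes(self, trained, prepared):
        _, st, _ = prepared
        out = impute(st, trained, n_steps=5, seed=0)
        assert out.values.shape == (st.n_cells, len(trained.gene_names))

    def test_disjoint_genes_rejected(self, trained, prepared):
        _, st, _ = prepared
        from stimpute.core_data import ExpressionMatrix

        alien = ExpressionMatrix(
            values=st.values.copy(),
            gene_names=[f"zz{i}" for i in range(st.n_genes)],
            cell_names=list(st.cell_names), modality="st",
        )
        with pytest.raises(ValueError, match="no shared genes"):
            impute(alien, trained, seed=0)


class TestCheckpointRoundTrip:
    def test_save_load_reproduces_imputation(self, trained, prepared, tmp_path):
        _, st, _ = prepared
        path = str(tmp_path / "cp.npz")
        trained.save(path)
        back = Checkpoint.load(path)
        a = impute(st, trained, seed=5)
        b = impute(st, back, seed=5)
        assert np.array_equal(a.values, b.values)
        assert back.gene_names == trained.gene_names
        assert back.value_range == trained.value_range


@pytest.fixture(scope="module")
def report(prepared):
    ref, st, _ = prepared
    return run_crossval(ref, st, k=2, cfg=replace(MICRO, max_iters=10),
                        n_steps=5)


class TestCrossval:
    def test_every_shared_gene_scored_exactly_once(self, report, prepared):
        _, _, mask = prepared
        scored = list(report.per_gene["gene"])
        assert sorted(scored) == sorted(mask.shared_genes)
        assert len(scored) == len(set(scored))

    def test_no_leakage_into_scoring(self, report, prepared):
        """Each gene is scored in the fold that held it out, never as a
        conditioning gene."""
        from stimpute.core_data import make_cv_splits

        _, _, mask = prepared
        plan = make_cv_splits(mask, k=2, seed=MICRO.seed)
        for _, row in report.per_gene.iterrows():
            assert plan.fold_assignments[row["gene"]] == row["fold"]

    def test_summary_fields(self, report):
        for key in ("mean_spcc", "mean_ssim", "mean_rmse", "mean_js"):
            assert np.isfinite(report.summary[key])
        assert report.summary["cv_mode"] == "scratch"

    def test_shared_backbone_mode_labeled(self, prepared):
        ref, st, _ = prepared
        rep = run_crossval(ref, st, k=2, cfg=replace(MICRO, max_iters=6),
                           n_steps=4, cv_mode="shared_backbone")
        assert rep.mode == "shared_backbone"
        assert rep.summary["cv_mode"] == "shared_backbone"
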