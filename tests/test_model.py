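import numpy as np
import pytest

import spotfuse
from spotfuse._autodiff import Parameter, Tensor, numerical_gradient
from spotfuse.model import (
    ContrastiveImputation,
    cosine_row_col_loss,
    cross_modal_loss,
    infonce_loss,
    mse_loss,
)
from helpers import binom_sf, top1_retrieval_rate


class TestCosineRowColLoss:
    def test_identical_matrices_zero(self):
        A = np.random.default_rng(0).standard_normal((4, 3)) + 2
        assert cosine_row_col_loss(A, A).item() == pytest.approx(0.0, abs=1e-12)

    def test_negated_matrix_gives_four(self):
        A = np.random.default_rng(1).standard_normal((5, 4))
        assert cosine_row_col_loss(A, -A).item() == pytest.approx(4.0)

    def test_orthogonal_permutation_example(self):
        # every row and column cosine is 0, so each mean term is 1
        A = np.array([[1.0, 0.0], [0.0, 1.0]])
        B = np.array([[0.0, 1.0], [1.0, 0.0]])
        assert cosine_row_col_loss(A, B).item() == pytest.approx(2.0)

    def test_zero_norm_convention(self):
        A = np.array([[1.0, 0.0]])
        Z = np.zeros((1, 2))
        # row cos 0 -> 1; columns: one zero-pair (1), one zero-pair (1)
        assert cosine_row_col_loss(A, Z).item() == pytest.approx(2.0)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError, match="shape"):
            cosine_row_col_loss(np.ones((2, 2)), np.ones((3, 2)))

    def test_bounded_between_zero_and_four(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            A, B = rng.standard_normal((2, 6, 5))
            v = cosine_row_col_loss(A, B).item()
            assert 0.0 <= v <= 4.0


class TestInfoNCE:
    def test_identical_unit_rows_collapse(self):
        K, tau = 5, 0.3
        H = np.tile([1.0, 0.0, 0.0], (K, 1))
        assert infonce_loss(H, H, tau).item() == pytest.approx(K * np.log(K - 1))

    def test_two_pairs_equal_similarities_zero(self):
        Hi = np.array([[1.0, 0.0], [0.0, 1.0]])
        He = np.array([[1.0, 1.0], [1.0, 1.0]]) / np.sqrt(2)
        # pos dot == neg dot for both rows -> each log-ratio 0
        assert infonce_loss(Hi, He, 0.7).item() == pytest.approx(0.0, abs=1e-12)

    def test_margin_of_tau_ln2_gives_minus_two_ln2(self):
        # both rows have pos_dot - neg_dot = tau*ln2 -> loss = -2 ln2
        tau = 0.11
        q = 1 - tau * np.log(2)
        u = np.array([1.0, 0.0])
        v = np.array([q, np.sqrt(1 - q**2)])
        H = np.stack([u, v])  # pos dots are 1, cross dots are q
        assert infonce_loss(H, H, tau).item() == pytest.approx(-2 * np.log(2))

    def test_single_pair_rejected(self):
        with pytest.raises(ValueError, match="2"):
            infonce_loss(np.ones((1, 3)), np.ones((1, 3)), 0.1)

    def test_standard_denominator_includes_positive(self):
        rng = np.random.default_rng(0)
        Hi, He = rng.standard_normal((2, 4, 3))
        as_written = infonce_loss(Hi, He, 0.5, standard=False).item()
        standard = infonce_loss(Hi, He, 0.5, standard=True).item()
        assert standard > as_written  # larger denominator
        assert standard >= 0.0  # standard form is non-negative


class TestCrossModalLoss:
    def test_perfect_prediction_zero(self):
        rng = np.random.default_rng(0)
        Y = rng.uniform(1, 2, (3, 4))
        tiles = np.repeat(Y / 2.0, 2, axis=0)  # l=2 tiles summing to Y
        assert cross_modal_loss(Y, Tensor(tiles), 2).item() == pytest.approx(0, abs=1e-12)

    def test_orthogonal_single_spot_two_genes(self):
        Y = np.array([[1.0, 0.0]])
        pred = Tensor(np.array([[0.0, 1.0]]))
        # row cosine 0 -> 1; each single-entry column has one zero side -> 1
        assert cross_modal_loss(Y, pred, 1).item() == pytest.approx(2.0)

    def test_zero_prediction_gives_two(self):
        Y = np.array([[2.0, 3.0]])
        assert cross_modal_loss(Y, Tensor(np.zeros((1, 2))), 1).item() == pytest.approx(2.0)

    def test_ragged_groups_rejected(self):
        with pytest.raises(ValueError, match="ragged"):
            cross_modal_loss(np.ones((2, 3)), Tensor(np.ones((5, 3))), 2)


class TestGradients:
    @pytest.mark.parametrize(
        "name,fn,shapes",
        [
            ("cosine", cosine_row_col_loss, [(5, 4), (5, 4)]),
            ("infonce", lambda A, B: infonce_loss(A, B, 0.5), [(6, 3), (6, 3)]),
            ("cross", lambda Y, P: cross_modal_loss(Y, P, 2), [(4, 3), (8, 3)]),
            ("mse", mse_loss, [(5, 4), (5, 4)]),
        ],
    )
    def test_analytic_matches_numerical(self, name, fn, shapes):
        rng = np.random.default_rng(42)
        args = [rng.standard_normal(s) for s in shapes]
        for i in range(len(args)):
            params = [Parameter(a.copy()) for a in args]
            fn(*params).backward()
            analytic = params[i].grad

            def scalar(x):
                vals = [Tensor(a) for a in args]
                vals[i] = Tensor(x)
                return fn(*vals).item()

            numeric = numerical_gradient(scalar, args[i].copy())
            rel = np.abs(analytic - numeric) / (np.abs(numeric) + 1e-6)
            assert rel.max() < 1e-4, f"{name} gradient mismatch {rel.max()}"


class TestTraining:
    def test_loss_breakdown_linearity_in_w4(self, training_inputs, trained_model):
        feats, Y, _, _ = training_inputs
        lb1 = trained_model.loss_breakdown(feats, Y)
        trained_model.w4 *= 2
        try:
            lb2 = trained_model.loss_breakdown(feats, Y)
        finally:
            trained_model.w4 /= 2
        assert lb2.loss_cross == pytest.approx(lb1.loss_cross)
        extra = lb2.loss_total - lb1.loss_total
        assert extra == pytest.approx(lb1.loss_cross, rel=1e-9)
        # breakdown sums to the weighted total
        assert lb1.loss_total == pytest.approx(
            lb1.loss_image + lb1.loss_expr + lb1.loss_infonce + lb1.loss_cross,
            abs=1e-6,
        )

    def test_tau_irrelevant_when_w3_zero(self):
        rng = np.random.default_rng(0)
        feats = rng.uniform(0, 1, (20 * 4, 8))
        Y = rng.uniform(1, 3, (20, 6))
        out = []
        for tau in (0.03, 7.0):
            est = ContrastiveImputation(
                hidden_dim=8, K=8, tau=tau, w3=0.0, epochs=3, seed=0
            ).fit(feats, Y, l=4)
            out.append(est.log_["loss_total"].to_numpy())
        np.testing.assert_allclose(out[0], out[1], rtol=1e-12)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(1)
        feats = rng.uniform(0, 1, (16 * 4, 8))
        Y = rng.uniform(1, 3, (16, 6))
        logs = [
            ContrastiveImputation(hidden_dim=8, K=8, epochs=4, seed=5)
            .fit(feats, Y, l=4).log_
            for _ in range(2)
        ]
        np.testing.assert_array_equal(
            logs[0].to_numpy(float), logs[1].to_numpy(float)
        )

    def test_batch_clipped_with_warning(self):
        rng = np.random.default_rng(2)
        feats = rng.uniform(0, 1, (6 * 2, 5))
        Y = rng.uniform(1, 2, (6, 4))
        with pytest.warns(UserWarning, match="clipped"):
            ContrastiveImputation(hidden_dim=4, K=64, epochs=2, seed=0).fit(
                feats, Y, l=2
            )

    def test_heldout_cross_loss_decreases(self, trained_model):
        log = trained_model.log_
        assert log["heldout_loss_cross"].iloc[-1] < log["heldout_loss_cross"].iloc[0]

    def test_expression_autoencoder_recovers_low_rank(self):
        rng = np.random.default_rng(0)
        U = rng.uniform(0.5, 2, (30, 2))
        V = rng.uniform(0.2, 1.5, (2, 20))
        Y = U @ V
        feats = rng.standard_normal((30 * 4, 16))
        est = ContrastiveImputation(
            hidden_dim=8, K=16, epochs=400, seed=0, w1=0, w3=0, w4=0,
            train_fraction=1.0,
        ).fit(feats, Y, l=4)
        assert est.loss_breakdown(feats, Y).loss_expr < 0.05

    def test_predictions_nonnegative_and_pure(self, trained_model, training_inputs):
        feats, _, _, _ = training_inputs
        pred = trained_model.predict(feats[:128])
        assert (pred >= 0).all()
        dup = trained_model.predict(np.vstack([feats[:1], feats[:1]]))
        np.testing.assert_array_equal(dup[0], dup[1])

    def test_dimension_mismatch_rejected(self, trained_model):
        with pytest.raises(ValueError, match="dimension"):
            trained_model.predict(np.ones((3, 7)))

    def test_spot_prediction_matches_expression_direction(
        self, trained_model, training_inputs
    ):
        feats, Y, _, _ = training_inputs
        pred = trained_model.predict(feats)
        agg = pred.reshape(Y.shape[0], trained_model.l_, -1).sum(axis=1)
        cos = (agg * Y).sum(1) / np.maximum(
            np.linalg.norm(agg, axis=1) * np.linalg.norm(Y, axis=1), 1e-12
        )
        assert cos.mean() >= 0.9

    def test_heldout_retrieval_beats_chance(self, trained_model, training_inputs):
        feats, Y, _, _ = training_inputs
        test = trained_model.test_idx_
        rate = top1_retrieval_rate(trained_model, feats, Y, test, trained_model.l_)
        n = len(test)
        hits = round(rate * n)
        assert binom_sf(hits - 1, n, 1.0 / n) < 0.01

    def test_get_set_params_roundtrip(self):
        est = ContrastiveImputation(hidden_dim=16, tau=0.5)
        params = est.get_params()
        est2 = ContrastiveImputation().set_params(**params)
        assert est2.get_params() == params
        with pytest.raises(ValueError, match="unknown"):
            est.set_params(bogus=1)
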