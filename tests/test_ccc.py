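import numpy as np
import pytest
from scipy import sparse

import spotfuse
from spotfuse.ccc import (
    MoranResult,
    SpatialWeights,
    build_weights,
    global_moran_r,
    local_moran_r,
    pair_expression,
    permutation_global_p,
    score_pairs,
    select_pairs,
)
from spotfuse.io import LRDatabase
from helpers import naive_global_moran, naive_local_moran


def _weights_from_dense(W):
    return SpatialWeights(W=sparse.csr_matrix(W), lengthscale=1.0, cutoff=1)


class TestBuildWeights:
    def test_kernel_half_weight_distance(self):
        ell = 2.0
        d = ell * np.sqrt(2 * np.log(2))
        coords = np.array([[0.0, 0.0], [d, 0.0]])
        w = build_weights(coords, lengthscale=ell, cutoff=1)
        assert w.W[0, 1] == pytest.approx(0.5)

    def test_weight_tends_to_one_at_zero_distance(self):
        coords = np.array([[0.0, 0.0], [1e-9, 0.0], [5.0, 5.0]])
        w = build_weights(coords, lengthscale=1.0, cutoff=2)
        assert w.W[0, 1] == pytest.approx(1.0)
        assert w.W[0, 0] == 0.0  # zero diagonal even with duplicates

    def test_line_cutoff_one_keeps_nearest_neighbors(self):
        coords = np.column_stack([np.array([0.0, 1, 2.2, 3.6, 5.2]), np.zeros(5)])
        w = build_weights(coords, lengthscale=1.0, cutoff=1)
        W = w.W.toarray()
        # union of each point's single nearest neighbor, symmetrized:
        # 0->1, 1->0, 2->1, 3->2, 4->3 gives edges {01, 12, 23, 34}
        assert (W > 0).sum() == 2 * 4
        for i, j in [(0, 1), (1, 2), (2, 3), (3, 4)]:
            assert W[i, j] > 0 and W[j, i] > 0

    def test_identical_coordinates_rejected_for_auto(self):
        coords = np.zeros((4, 2))
        with pytest.raises(ValueError, match="identical"):
            build_weights(coords, lengthscale="auto", cutoff=2)

    def test_row_normalized_rows_sum_to_one(self):
        rng = np.random.default_rng(0)
        coords = rng.uniform(0, 10, (20, 2))
        w = build_weights(coords, cutoff=4, row_normalize=True)
        np.testing.assert_allclose(
            np.asarray(w.W.sum(axis=1)).ravel(), 1.0, rtol=1e-12
        )


class TestPairExpression:
    def test_multi_subunit_receptor_averaged(self):
        genes = ["WNT3", "FZD9", "LRP6"]
        expr = np.array([[1.0, 2.0, 4.0], [2.0, 0.0, 2.0], [0.0, 6.0, 0.0]])
        db = LRDatabase([(["WNT3"], ["FZD9", "LRP6"], "WNT")])
        kept, L, R = pair_expression(expr, genes, db)
        np.testing.assert_allclose(R[:, 0], [(2 + 4) / 2, 1.0, 3.0])
        np.testing.assert_allclose(L[:, 0], [1.0, 2.0, 0.0])

    def test_missing_subunit_drops_pair(self):
        genes = ["WNT3", "FZD9"]
        expr = np.ones((3, 2))
        db = LRDatabase(
            [(["WNT3"], ["FZD9", "LRP6"], "WNT"), (["WNT3"], ["FZD9"], "WNT")]
        )
        kept, L, R = pair_expression(expr, genes, db)
        assert kept == [1]

    def test_no_usable_pairs_raises(self):
        db = LRDatabase([(["X"], ["Y"], "P")])
        with pytest.raises(ValueError, match="no LR pair"):
            pair_expression(np.ones((3, 1)), ["Z"], db)


class TestGlobalMoran:
    def test_two_point_swap_gives_minus_one(self):
        W = np.array([[0.0, 1.0], [1.0, 0.0]])
        L = R = np.array([1.0, -1.0])
        r, z, p = global_moran_r(L, R, _weights_from_dense(W))
        assert r == pytest.approx(-1.0)

    def test_smooth_gradient_positive(self):
        coords = np.column_stack([np.arange(30.0), np.zeros(30)])
        w = build_weights(coords, lengthscale=1.0, cutoff=2)
        grad = np.arange(30.0)
        r, z, p = global_moran_r(grad, grad, w)
        assert r > 0 and p < 0.01

    def test_zero_variance_rejected(self):
        w = build_weights(np.random.default_rng(0).uniform(0, 5, (5, 2)), cutoff=2)
        with pytest.raises(ValueError, match="variance"):
            global_moran_r(np.ones(5), np.arange(5.0), w)

    def test_scale_invariance_under_positive_affine(self):
        rng = np.random.default_rng(0)
        coords = rng.uniform(0, 10, (40, 2))
        w = build_weights(coords, cutoff=4)
        L, R = rng.normal(size=40), rng.normal(size=40)
        r0, _, _ = global_moran_r(L, R, w)
        r1, _, _ = global_moran_r(3.7 * L + 11, 0.2 * R - 4, w)
        assert r1 == pytest.approx(r0, abs=1e-12)

    def test_matches_naive_double_loop(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            M = int(rng.integers(5, 50))
            coords = rng.uniform(0, 10, (M, 2))
            w = build_weights(coords, cutoff=min(4, M - 1))
            L, R = rng.normal(size=M), rng.normal(size=M)
            r, _, _ = global_moran_r(L, R, w)
            assert abs(r - naive_global_moran(L, R, w.W.toarray())) < 1e-10


class TestLocalMoran:
    def test_matches_naive_and_identity(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            M = int(rng.integers(5, 40))
            coords = rng.uniform(0, 10, (M, 2))
            w = build_weights(coords, cutoff=min(4, M - 1))
            L, R = rng.normal(size=M), rng.normal(size=M)
            s, r_, loc, p = local_moran_r(L, R, w)
            ns, nr = naive_local_moran(L, R, w.W.toarray())
            np.testing.assert_allclose(s, ns, atol=1e-10)
            np.testing.assert_allclose(r_, nr, atol=1e-10)
            rg, _, _ = global_moran_r(L, R, w)
            assert loc.sum() == pytest.approx(2 * M * rg, abs=1e-8)

    def test_location_at_mean_contributes_zero_sender(self):
        W = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float)
        L = np.array([1.0, 2.0, 3.0])  # middle value equals the mean
        R = np.array([5.0, 1.0, 2.0])
        s, _, _, _ = local_moran_r(L, R, _weights_from_dense(W))
        assert s[1] == pytest.approx(0.0, abs=1e-14)

    def test_constant_field_rejected(self):
        w = build_weights(np.random.default_rng(0).uniform(0, 5, (6, 2)), cutoff=2)
        with pytest.raises(ValueError, match="variance"):
            local_moran_r(np.ones(6), np.arange(6.0), w)

    def test_permutation_consistency_at_m200(self):
        rng = np.random.default_rng(3)
        coords = rng.uniform(0, 20, (200, 2))
        w = build_weights(coords, cutoff=6)
        close = 0
        n_pairs = 12
        for i in range(n_pairs):
            L, R = rng.normal(size=200), rng.normal(size=200)
            _, _, p = global_moran_r(L, R, w)
            p_perm = permutation_global_p(L, R, w, n_perm=2000, seed=i)
            close += abs(p - p_perm) <= 0.02
        assert close >= 0.9 * n_pairs


class TestSelection:
    def _result(self, pvals, local_p=None):
        import pandas as pd

        M = 6
        P = len(pvals)
        lp = np.ones((M, P)) if local_p is None else local_p
        return MoranResult(
            pairs=pd.DataFrame(
                dict(
                    ligand=[f"L{i}" for i in range(P)],
                    receptor=[f"R{i}" for i in range(P)],
                    pathway=["P"] * P,
                    R_global=0.0,
                    z=0.0,
                    p=pvals,
                )
            ),
            local_r=np.zeros((M, P)),
            local_sender=np.zeros((M, P)),
            local_receiver=np.zeros((M, P)),
            local_p=lp,
            x_bin=np.zeros((M, P), int),
            x_con=1 - lp,
        )

    def test_bh_stepup_worked_example(self):
        res = select_pairs(self._result([0.01, 0.02, 0.04, 0.8]), fdr=0.05)
        assert res.pairs["selected"].tolist() == [True, True, False, False]

    def test_all_ones_select_none(self):
        res = select_pairs(self._result([1.0, 1.0, 1.0]))
        assert not res.pairs["selected"].any()

    def test_sparse_interaction_flagged_out(self):
        lp = np.ones((6, 1))
        lp[:2, 0] = 0.001  # interacts in only 2 locations
        res = select_pairs(self._result([1e-6], lp), min_interacting=3)
        row = res.pairs.iloc[0]
        assert row["selected"] and row["n_interacting"] == 2
        assert not row["eligible"]

    def test_x_bin_and_x_con_conventions(self):
        lp = np.ones((6, 1))
        lp[:4, 0] = 0.01
        res = select_pairs(self._result([0.001], lp))
        assert res.x_bin[:, 0].sum() == 4
        np.testing.assert_allclose(res.x_con, 1 - lp)

    def test_q_at_least_p(self):
        res = select_pairs(self._result([0.01, 0.2, 0.5, 0.04]))
        assert (res.pairs["q"] >= res.pairs["p"] - 1e-15).all()


class TestScorePairs:
    def test_zero_variance_pair_reported_with_p_one(self):
        rng = np.random.default_rng(0)
        coords = rng.uniform(0, 10, (30, 2))
        w = build_weights(coords, cutoff=4)
        expr = np.column_stack([np.ones(30), rng.normal(size=30), rng.normal(size=30)])
        db = LRDatabase([(["A"], ["B"], "P"), (["B"], ["C"], "P")])
        res = score_pairs(expr, ["A", "B", "C"], db, w)
        assert res.pairs.loc[0, "p"] == 1.0
        assert res.pairs.loc[1, "p"] < 1.0
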