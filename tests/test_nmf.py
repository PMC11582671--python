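"""Non-smooth NMF fitting and the three-factor signature index."""

import numpy as np
import pandas as pd
import pytest

from commsig.containers import AbundanceTable
from commsig.nmf import (
    ASVIndexTable,
    asv_index,
    cosine_projection,
    entropy_score,
    nsnmf_best_of,
    nsnmf_fit,
    rank_survey,
    select_signatures,
    smoothing_matrix,
    spearman_rho,
)

from conftest import oracle_asv_index


class TestSmoothingMatrix:
    def test_theta_zero_is_identity(self):
        np.testing.assert_allclose(smoothing_matrix(3, 0.0), np.eye(3))

    def test_rows_sum_to_one(self):
        S = smoothing_matrix(5, 0.7)
        np.testing.assert_allclose(S.sum(axis=1), 1.0)
        assert (S >= 0).all()


class TestNsnmfFit:
    def test_rank_one_exact_factorization(self):
        rng = np.random.default_rng(0)
        w = rng.uniform(0.5, 2, size=6)
        h = rng.uniform(0.5, 2, size=5)
        V = np.outer(w, h)
        model = nsnmf_fit(V, q=1, theta=0.0, seed=1, max_iter=3000, tol=1e-14)
        assert model.objective < 1e-6 * V.sum()

    def test_objective_non_increasing(self):
        rng = np.random.default_rng(1)
        V = rng.uniform(0, 10, size=(15, 8))
        model = nsnmf_fit(V, q=3, theta=0.5, seed=2, max_iter=200, tol=0)
        tr = model.objective_trace
        assert (np.diff(tr) <= 1e-8 * np.maximum(np.abs(tr[:-1]), 1.0)).all()

    def test_block_diagonal_recovery(self):
        # 2-block matrix: each block's taxa load on a single descriptor
        rng = np.random.default_rng(2)
        hits = 0
        for seed in range(20):
            V = np.zeros((10, 8))
            V[:5, :4] = rng.uniform(1, 5, size=(5, 4))
            V[5:, 4:] = rng.uniform(1, 5, size=(5, 4))
            model = nsnmf_fit(V + 1e-9, q=2, theta=0.5, seed=seed)
            W = model.W.to_numpy()
            share = W.max(axis=1) / W.sum(axis=1)
            blocks_ok = (
                len(set(model.W.columns[W[:5].argmax(axis=1)])) == 1
                and len(set(model.W.columns[W[5:].argmax(axis=1)])) == 1
            )
            if blocks_ok and (share >= 0.99).all():
                hits += 1
        assert hits >= 18  # planted structure recovered in nearly every run

    def test_deterministic(self):
        rng = np.random.default_rng(3)
        V = rng.uniform(0, 5, size=(12, 6))
        m1 = nsnmf_fit(V, 2, seed=9)
        m2 = nsnmf_fit(V, 2, seed=9)
        pd.testing.assert_frame_equal(m1.W, m2.W)

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError, match="negative"):
            nsnmf_fit(np.array([[1.0, -1.0], [1.0, 1.0], [1, 1]]), 2)
        with pytest.raises(ValueError, match="all-zero"):
            nsnmf_fit(np.array([[1.0, 1], [0, 0], [1, 1]]), 2)


class TestBestOf:
    def test_single_run_equals_fit(self):
        rng = np.random.default_rng(4)
        V = rng.uniform(0, 5, size=(10, 6))
        run = nsnmf_best_of(V, 2, n_runs=1, seed=5)
        direct = nsnmf_fit(V, 2, seed=run.best.seed)
        assert run.best.objective == direct.objective

    def test_best_is_minimum(self):
        rng = np.random.default_rng(5)
        V = rng.uniform(0, 5, size=(10, 6))
        run = nsnmf_best_of(V, 2, n_runs=8, seed=6)
        assert run.best.objective == run.objectives.min()
        assert 0 <= run.agreement <= 1


class TestRankSurvey:
    def test_objectives_weakly_decrease_with_rank(self):
        rng = np.random.default_rng(6)
        V = rng.uniform(0.1, 5, size=(20, 10))
        out = rank_survey(V, ranks=range(2, 6), n_runs=8, seed=7, max_iter=500)
        objs = out["best_objective"].to_numpy()
        assert (np.diff(objs) <= 1e-6 * np.abs(objs[:-1])).all()

    def test_planted_rank_has_max_cophenetic(self):
        rng = np.random.default_rng(7)
        q_true = 3
        W = np.zeros((30, q_true))
        for k in range(q_true):
            W[10 * k : 10 * (k + 1), k] = rng.uniform(1, 3, 10)
        H = np.zeros((q_true, 12))
        for k in range(q_true):
            H[k, 4 * k : 4 * (k + 1)] = rng.uniform(1, 3, 4)
        V = W @ H + rng.uniform(0, 0.05, size=(30, 12))
        out = rank_survey(V, ranks=range(2, 6), n_runs=10, seed=8, max_iter=500)
        assert out["cophenetic"].idxmax() == q_true


class TestIndexComponents:
    def test_cosine_cases(self):
        assert cosine_projection([1, 2, 3], [2, 4, 6]) == pytest.approx(1.0)
        assert cosine_projection([1, 0], [0, 5]) == pytest.approx(0.0)
        assert cosine_projection([1, 1, 0], [0, 1, 1]) == pytest.approx(0.5)
        with pytest.raises(ValueError):
            cosine_projection([0, 0], [1, 1])

    def test_entropy_score_cases(self):
        assert entropy_score([1, 0, 0, 0]) == pytest.approx(1.0)
        assert entropy_score([0.25] * 4) == pytest.approx(0.0)
        assert entropy_score([0.5, 0.5, 0, 0]) == pytest.approx(0.5)
        with pytest.raises(ValueError):
            entropy_score([1.0])

    def test_spearman_cases(self):
        assert spearman_rho([1, 2, 3], [10, 20, 30]) == pytest.approx(1.0)
        assert spearman_rho([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)
        # tied ranks coincide
        assert spearman_rho([1, 2, 2, 4], [10, 20, 20, 35]) == pytest.approx(1.0)
        with pytest.warns(UserWarning, match="constant"):
            assert spearman_rho([2, 2, 2], [1, 2, 3]) == 0.0


class TestAsvIndex:
    def _fit(self, V, q=2, seed=0):
        return nsnmf_fit(V, q=q, theta=0.5, seed=seed)

    def test_matches_equation_oracle(self):
        rng = np.random.default_rng(8)
        V = rng.uniform(0.1, 10, size=(20, 8))
        model = self._fit(V, q=3, seed=1)
        idx = asv_index(V, model)
        rho_o, cos_o, score_o, index_o = oracle_asv_index(
            V, model.W.to_numpy(), model.H.to_numpy()
        )
        np.testing.assert_allclose(idx.rho.to_numpy(), rho_o, atol=1e-10)
        np.testing.assert_allclose(idx.cos_theta.to_numpy(), cos_o, atol=1e-10)
        np.testing.assert_allclose(idx.score.to_numpy(), score_o, atol=1e-10)
        np.testing.assert_allclose(idx.index.to_numpy(), index_o, atol=1e-10)

    def test_index_sign_is_rho_times_cos(self):
        rng = np.random.default_rng(9)
        V = rng.uniform(0.1, 10, size=(15, 6))
        model = self._fit(V, q=2, seed=2)
        idx = asv_index(V, model)
        sign = np.sign(idx.index.to_numpy())
        expect = np.sign(idx.rho.to_numpy() * idx.cos_theta.to_numpy())
        mask = np.abs(idx.index.to_numpy()) > 1e-12
        np.testing.assert_array_equal(sign[mask], expect[mask])

    def test_score_in_unit_interval_and_probabilities_normalize(self):
        rng = np.random.default_rng(10)
        V = rng.uniform(0.1, 10, size=(15, 6))
        model = self._fit(V, q=3, seed=3)
        idx = asv_index(V, model)
        assert ((idx.score >= 0) & (idx.score <= 1)).all()
        W = model.W.to_numpy()
        P = W / W.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(P.sum(axis=1), 1.0)

    def test_perfect_signature_scores_one(self):
        # taxon matching one descriptor's one-hot structure exactly
        H = pd.DataFrame(
            [[5.0, 4.0, 0, 0], [0, 0, 3.0, 6.0]],
            index=["D1", "D2"], columns=list("wxyz"),
        )
        W = pd.DataFrame(
            {"D1": [1.0, 0.0], "D2": [0.0, 1.0]}, index=["t1", "t2"]
        )
        from commsig.nmf import NMFModel

        model = NMFModel(W, H, theta=0.0, objective_trace=np.array([0.0]),
                         seed=0, n_iter=1, converged=True)
        V = pd.DataFrame(
            [[5.0, 4.0, 0, 0], [0, 0, 3.0, 6.0]],
            index=["t1", "t2"], columns=list("wxyz"),
        )
        idx = asv_index(V, model)
        assert idx.index.loc["t1", "D1"] == pytest.approx(1.0)
        assert idx.index.loc["t2", "D2"] == pytest.approx(1.0)

    def test_dimension_mismatch(self):
        rng = np.random.default_rng(11)
        V = rng.uniform(0.1, 1, size=(10, 6))
        model = self._fit(V, q=2)
        with pytest.raises(ValueError, match="share"):
            asv_index(V[:8], model)


class TestSelectSignatures:
    def _index_table(self, col: np.ndarray) -> ASVIndexTable:
        n = len(col)
        ti = pd.Index([f"t{i}" for i in range(n)], name="taxon_id")
        df = pd.DataFrame({"D1": col}, index=ti)
        ones = pd.DataFrame(np.ones((n, 1)), index=ti, columns=["D1"])
        return ASVIndexTable(ones, ones, pd.Series(np.ones(n), index=ti), df)

    def test_constant_column_selects_nothing(self):
        sigs = select_signatures(self._index_table(np.full(10, 0.3)))
        assert sigs.taxa("D1") == []

    def test_single_outlier_selected(self):
        col = np.concatenate([np.full(30, 0.01), [0.9]])
        # outlier exceeds mean + 3 * sample sd of the column
        m, s = col.mean(), col.std(ddof=1)
        assert 0.9 > m + 3 * s
        sigs = select_signatures(self._index_table(col))
        assert sigs.taxa("D1") == ["t30"]

    def test_threshold_reported(self):
        col = np.concatenate([np.zeros(20), [1.0]])
        sigs = select_signatures(self._index_table(col))
        assert sigs.thresholds["D1"] == pytest.approx(
            col.mean() + 3 * col.std(ddof=1)
        )
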