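"""The three link-prediction algorithms against independent oracles."""

import numpy as np
import pytest

from dtilink.inference import (
    ModelParams,
    TrainedModel,
    fit,
    fit_bge,
    fit_blm,
    fit_pkr,
    score_all_pairs,
    threshold_edges,
)
from dtilink.io_tables import InteractionNetwork, KernelMatrix

from conftest import rand_network, rand_pd_kernel, rand_psd_kernel


def _identity_setup(n_d=4, n_p=3, rng=None, p=0.4):
    rng = rng or np.random.default_rng(0)
    Kd = KernelMatrix([f"d{i}" for i in range(n_d)], np.eye(n_d), "drug")
    Kp = KernelMatrix([f"p{j}" for j in range(n_p)], np.eye(n_p), "protein")
    Y = (rng.random((n_d, n_p)) < p).astype(float)
    net = InteractionNetwork(Kd.object_ids, Kp.object_ids, Y)
    return Kd, Kp, net


def kron_solve(Kd, Kp, Y, lam):
    """Independent oracle: explicit Kronecker pair-kernel ridge solution.

    Pairs ordered drug-major (vec of Y rows stacked per drug), so the pair
    kernel is kron(Kd, Kp).
    """
    n_d, n_p = Y.shape
    Kpair = np.kron(Kd, Kp)
    a = np.linalg.solve(Kpair + lam * np.eye(n_d * n_p), Y.ravel())
    return (Kpair @ a).reshape(n_d, n_p), a.reshape(n_d, n_p)


class TestPairwiseKernelRegression:
    def test_all_zero_labels_give_zero_model(self, rng):
        Kd = rand_psd_kernel(5, rng, "drug")
        Kp = rand_psd_kernel(4, rng, "protein", "p")
        net = InteractionNetwork(Kd.object_ids, Kp.object_ids, np.zeros((5, 4)))
        m = fit_pkr(Kd, Kp, net)
        assert np.abs(m.arrays["C"]).max() <= 1e-12
        assert np.abs(m.F).max() <= 1e-12

    def test_identity_kernels_closed_form(self):
        # Kd = Kp = I decouples pairs; ridge shrinks each label by 1/(1+lambda)
        Kd, Kp, net = _identity_setup()
        m = fit_pkr(Kd, Kp, net, ModelParams(ridge=1.0))
        np.testing.assert_allclose(m.arrays["C"], net.Y / 2, atol=1e-12)
        np.testing.assert_allclose(m.F, net.Y / 2, atol=1e-12)

    @pytest.mark.parametrize("lam", [0.1, 1.0, 10.0])
    def test_explicit_kronecker_oracle(self, lam, rng):
        for _ in range(5):
            n_d, n_p = rng.integers(3, 9), rng.integers(3, 7)
            Kd = rand_psd_kernel(n_d, rng, "drug")
            Kp = rand_psd_kernel(n_p, rng, "protein", "p")
            net = rand_network(n_d, n_p, rng)
            m = fit_pkr(Kd, Kp, net, ModelParams(ridge=lam))
            F_oracle, C_oracle = kron_solve(Kd.values, Kp.values, net.Y, lam)
            np.testing.assert_allclose(m.F, F_oracle, atol=1e-8)
            np.testing.assert_allclose(m.arrays["C"], C_oracle, atol=1e-8)

    def test_predict_on_training_kernels_reproduces_f(self, rng):
        Kd = rand_psd_kernel(6, rng, "drug")
        Kp = rand_psd_kernel(5, rng, "protein", "p")
        net = rand_network(6, 5, rng)
        m = fit_pkr(Kd, Kp, net, ModelParams(ridge=0.5))
        np.testing.assert_allclose(m.predict(Kd.values, Kp.values), m.F, atol=1e-10)

    def test_zero_similarity_drug_scores_zero(self, rng):
        Kd = rand_psd_kernel(5, rng, "drug")
        Kp = rand_psd_kernel(4, rng, "protein", "p")
        net = rand_network(5, 4, rng)
        m = fit_pkr(Kd, Kp, net)
        S = m.predict(np.zeros((1, 5)), Kp.values)
        np.testing.assert_array_equal(S, 0.0)

    def test_duplicated_training_drug_scores_like_original(self, rng):
        Kd = rand_psd_kernel(5, rng, "drug")
        Kp = rand_psd_kernel(4, rng, "protein", "p")
        net = rand_network(5, 4, rng)
        m = fit_pkr(Kd, Kp, net)
        S = m.predict(Kd.values[[2], :], Kp.values)
        np.testing.assert_allclose(S[0], m.F[2], atol=1e-10)

    def test_cross_kernel_shape_mismatch_is_error(self, rng):
        Kd = rand_psd_kernel(5, rng, "drug")
        Kp = rand_psd_kernel(4, rng, "protein", "p")
        m = fit_pkr(Kd, Kp, rand_network(5, 4, rng))
        with pytest.raises(ValueError):
            m.predict(np.zeros((2, 6)), Kp.values)

    def test_misaligned_ids_are_error(self, rng):
        Kd = rand_psd_kernel(5, rng, "drug")
        Kp = rand_psd_kernel(4, rng, "protein", "p")
        net = rand_network(5, 4, rng)
        bad = InteractionNetwork(list(reversed(net.drug_ids)), net.protein_ids, net.Y)
        with pytest.raises(ValueError, match="ids"):
            fit_pkr(Kd, Kp, bad)


class TestBipartiteLocalModel:
    def test_all_zero_labels_score_zero(self, rng):
        Kd = rand_psd_kernel(5, rng, "drug")
        Kp = rand_psd_kernel(4, rng, "protein", "p")
        net = InteractionNetwork(Kd.object_ids, Kp.object_ids, np.zeros((5, 4)))
        m = fit_blm(Kd, Kp, net)
        assert np.abs(m.F).max() == 0.0

    def test_identity_kernels_closed_form(self):
        # both local ridges shrink to Y/2, so mean-combined scores equal Y/2
        Kd, Kp, net = _identity_setup()
        m = fit_blm(Kd, Kp, net, ModelParams("blm", ridge=1.0))
        interacting_drugs = net.Y.sum(axis=1) > 0
        interacting_prots = net.Y.sum(axis=0) > 0
        both = np.outer(interacting_drugs, interacting_prots)
        np.testing.assert_allclose(m.F[both], (net.Y / 2)[both], atol=1e-12)

    def test_per_node_ridge_oracle(self, rng):
        n_d, n_p, lam = 6, 4, 0.7
        Kd = rand_psd_kernel(n_d, rng, "drug")
        Kp = rand_psd_kernel(n_p, rng, "protein", "p")
        net = rand_network(n_d, n_p, rng, p=0.5)
        m = fit_blm(Kd, Kp, net, ModelParams("blm", ridge=lam))
        # hand-composed per-node solutions
        for d in range(n_d):
            for p in range(n_p):
                parts = []
                if net.Y[d].sum() > 0:
                    alpha = np.linalg.solve(Kp.values + lam * np.eye(n_p), net.Y[d])
                    parts.append(Kp.values[p] @ alpha)
                if net.Y[:, p].sum() > 0:
                    beta = np.linalg.solve(Kd.values + lam * np.eye(n_d), net.Y[:, p])
                    parts.append(Kd.values[d] @ beta)
                expect = np.mean(parts) if parts else 0.0
                assert m.F[d, p] == pytest.approx(expect, abs=1e-10)

    def test_max_combine(self, rng):
        Kd = rand_psd_kernel(5, rng, "drug")
        Kp = rand_psd_kernel(4, rng, "protein", "p")
        net = rand_network(5, 4, rng, p=0.9)  # all nodes modeled
        mean_m = fit_blm(Kd, Kp, net, ModelParams("blm", blm_combine="mean"))
        max_m = fit_blm(Kd, Kp, net, ModelParams("blm", blm_combine="max"))
        assert (max_m.F >= mean_m.F - 1e-12).all()

    def test_unmodeled_drug_falls_back_to_protein_side(self, rng):
        Kd = rand_psd_kernel(4, rng, "drug")
        Kp = rand_psd_kernel(3, rng, "protein", "p")
        Y = np.array([[0, 0, 0], [1, 0, 1], [0, 1, 0], [1, 1, 0]], dtype=float)
        net = InteractionNetwork(Kd.object_ids, Kp.object_ids, Y)
        lam = 1.0
        m = fit_blm(Kd, Kp, net, ModelParams("blm", ridge=lam))
        beta = np.linalg.solve(Kd.values + lam * np.eye(4), Y[:, 0])
        assert m.F[0, 0] == pytest.approx(Kd.values[0] @ beta, abs=1e-10)

    def test_new_new_pairs_score_zero(self, rng):
        Kd = rand_psd_kernel(4, rng, "drug")
        Kp = rand_psd_kernel(3, rng, "protein", "p")
        m = fit_blm(Kd, Kp, rand_network(4, 3, rng))
        S = m.predict(rng.standard_normal((2, 4)), rng.standard_normal((2, 3)))
        np.testing.assert_array_equal(S, 0.0)


class TestBipartiteGraphEmbedding:
    def test_two_block_network_separates(self):
        n_d, n_p = 8, 6
        Y = np.zeros((n_d, n_p))
        Y[:4, :3] = 1
        Y[4:, 3:] = 1
        ids_d = [f"d{i}" for i in range(n_d)]
        ids_p = [f"p{j}" for j in range(n_p)]
        Kd = KernelMatrix(ids_d, np.eye(n_d) + Y @ Y.T / 10, "drug")
        Kp = KernelMatrix(ids_p, np.eye(n_p) + Y.T @ Y / 10, "protein")
        net = InteractionNetwork(ids_d, ids_p, Y)
        m = fit_bge(Kd, Kp, net, ModelParams("bge", embed_dim=2, ridge=0.01))
        within = np.concatenate([m.F[:4, :3].ravel(), m.F[4:, 3:].ravel()])
        cross = np.concatenate([m.F[:4, 3:].ravel(), m.F[4:, :3].ravel()])
        assert within.min() > cross.max()

    def test_star_drug_dominates_first_coordinate(self):
        # one drug interacting with every protein carries the top eigenvector
        Y = np.zeros((5, 4))
        Y[0, :] = 1
        Y[1, 0] = 1
        ids_d = [f"d{i}" for i in range(5)]
        ids_p = [f"p{j}" for j in range(4)]
        net = InteractionNetwork(ids_d, ids_p, Y)
        Kd = KernelMatrix(ids_d, np.eye(5), "drug")
        Kp = KernelMatrix(ids_p, np.eye(4), "protein")
        m = fit_bge(Kd, Kp, net, ModelParams("bge", embed_dim=1, ridge=0.01))
        mags = np.abs(m.arrays["Z_d"]).ravel()
        assert np.argmax(mags) == 0

    def test_low_ridge_full_dim_reconstructs_embedded_kernel(self, rng):
        # independent oracle: rank-limited network kernel recomputed from Y via SVD
        from scipy.stats import spearmanr

        n_d, n_p, dim = 10, 8, 7
        net = rand_network(n_d, n_p, rng)
        Kd = rand_pd_kernel(n_d, rng, "drug")
        Kp = rand_pd_kernel(n_p, rng, "protein", "p")
        m = fit_bge(Kd, Kp, net, ModelParams("bge", embed_dim=dim, ridge=1e-8))
        Z = np.vstack([Kd.values @ m.arrays["A_d"], Kp.values @ m.arrays["A_p"]])
        Y = net.Y
        M = np.block([[Y @ Y.T, Y], [Y.T, Y.T @ Y]]) + 1e-6 * np.eye(n_d + n_p)
        w, U = np.linalg.eigh(M)
        keep = np.argsort(w)[::-1][:dim]
        M_rank = (U[:, keep] * np.maximum(w[keep], 0)) @ U[:, keep].T
        rho = spearmanr((Z @ Z.T).ravel(), M_rank.ravel()).statistic
        assert rho >= 0.9

    def test_edgeless_network_is_error(self, rng):
        Kd = rand_psd_kernel(4, rng, "drug")
        Kp = rand_psd_kernel(3, rng, "protein", "p")
        net = InteractionNetwork(Kd.object_ids, Kp.object_ids, np.zeros((4, 3)))
        with pytest.raises(ValueError, match="edge"):
            fit_bge(Kd, Kp, net)

    def test_embed_dim_bound_enforced(self, rng):
        Kd = rand_psd_kernel(4, rng, "drug")
        Kp = rand_psd_kernel(3, rng, "protein", "p")
        with pytest.raises(ValueError, match="embed_dim"):
            fit_bge(Kd, Kp, rand_network(4, 3, rng), ModelParams("bge", embed_dim=3))


class TestGenericPredictConsistency:
    """Scoring training pairs through predict reproduces the fitted F."""

    @pytest.mark.parametrize("algo", ["pkr", "blm", "bge"])
    def test_training_kernels_reproduce_f(self, algo, rng):
        Kd = rand_pd_kernel(6, rng, "drug")
        Kp = rand_pd_kernel(5, rng, "protein", "p")
        net = rand_network(6, 5, rng)
        m = fit(Kd, Kp, net, ModelParams(algorithm=algo, ridge=0.8, embed_dim=3))
        S = m.predict(
            Kd.values, Kp.values, drug_train_idx=range(6), protein_train_idx=range(5)
        )
        np.testing.assert_allclose(S, m.F, atol=1e-8)

    @pytest.mark.parametrize("algo", ["pkr", "blm", "bge"])
    def test_label_equivariance_under_drug_permutation(self, algo, rng):
        n_d, n_p = 6, 5
        Kd = rand_pd_kernel(n_d, rng, "drug")
        Kp = rand_pd_kernel(n_p, rng, "protein", "p")
        net = rand_network(n_d, n_p, rng)
        m = fit(Kd, Kp, net, ModelParams(algorithm=algo, ridge=0.8, embed_dim=3))
        perm = rng.permutation(n_d)
        Kd_perm = KernelMatrix(
            [Kd.object_ids[i] for i in perm], Kd.values[np.ix_(perm, perm)], "drug"
        )
        net_perm = InteractionNetwork(Kd_perm.object_ids, net.protein_ids, net.Y[perm])
        m_perm = fit(Kd_perm, Kp, net_perm, ModelParams(algorithm=algo, ridge=0.8, embed_dim=3))
        np.testing.assert_allclose(m_perm.F, m.F[perm], atol=1e-8)


class TestRegularizationLimits:
    @pytest.mark.parametrize("algo", ["pkr", "blm"])
    def test_scores_vanish_monotonically_with_lambda(self, algo, rng):
        # on a fixed unit-spectral-norm kernel scale the ridge shrinkage
        # factor is at most (s+1)/(s+1000) <= 2/1001 per eigencomponent
        def unit_norm(K):
            V = K.values / np.linalg.eigvalsh(K.values).max()
            return KernelMatrix(K.object_ids, V, K.side)

        Kd = unit_norm(rand_pd_kernel(6, rng, "drug"))
        Kp = unit_norm(rand_pd_kernel(5, rng, "protein", "p"))
        net = rand_network(6, 5, rng)
        maxima = [
            np.abs(fit(Kd, Kp, net, ModelParams(algorithm=algo, ridge=lam)).F).max()
            for lam in (1.0, 10.0, 100.0, 1000.0)
        ]
        assert all(a > b for a, b in zip(maxima, maxima[1:]))
        assert maxima[-1] <= 1e-2 * maxima[0]

    def test_interpolation_limit_recovers_labels(self, rng):
        # strictly PD kernels, lambda -> 0: training scores converge to Y
        Kd = rand_pd_kernel(6, rng, "drug")
        Kp = rand_pd_kernel(5, rng, "protein", "p")
        net = rand_network(6, 5, rng)
        m = fit_pkr(Kd, Kp, net, ModelParams(ridge=1e-8))
        assert np.abs(m.F - net.Y).max() <= 1e-4


class TestScoreAllPairsAndThreshold:
    def _scores(self, rng, n_d=4, n_p=3):
        Kd = rand_psd_kernel(n_d, rng, "drug")
        Kp = rand_psd_kernel(n_p, rng, "protein", "p")
        net = rand_network(n_d, n_p, rng)
        m = fit_pkr(Kd, Kp, net)
        return m, Kd, Kp, net

    def test_training_universe_gives_clipped_f(self, rng):
        m, Kd, Kp, net = self._scores(rng)
        S = score_all_pairs(m, Kd.values, Kp.values, net.drug_ids, net.protein_ids)
        np.testing.assert_allclose(S, np.clip(m.F, 0, 1), atol=1e-12)

    def test_clip_disabled_matches_raw_predict(self, rng):
        m, Kd, Kp, net = self._scores(rng)
        S = score_all_pairs(m, Kd.values, Kp.values, net.drug_ids, net.protein_ids, clip=False)
        np.testing.assert_allclose(S, m.predict(Kd.values, Kp.values), atol=1e-12)

    def test_reported_scores_in_unit_interval(self, rng):
        m, Kd, Kp, net = self._scores(rng)
        S = score_all_pairs(m, 5 * Kd.values, 5 * Kp.values, net.drug_ids, net.protein_ids)
        assert S.min() >= 0 and S.max() <= 1

    def test_threshold_at_max_gives_empty_set(self, rng):
        S = rng.random((3, 2))
        edges = threshold_edges(S, S.max(), ["a", "b", "c"], ["x", "y"], ["a"], ["x"])
        assert edges.records == []

    def test_zero_threshold_returns_all_positive_pairs(self, rng):
        S = rng.random((3, 2)) + 0.01
        edges = threshold_edges(S, 0.0, ["a", "b", "c"], ["x", "y"], ["a"], ["x"])
        assert len(edges.records) == 6

    def test_category_counts_match_enumeration(self, rng):
        drugs, prots = ["d1", "d2", "d3", "d4"], ["p1", "p2", "p3"]
        train_d, train_p = ["d1", "d2"], ["p2"]
        S = rng.random((4, 3)) + 0.01
        edges = threshold_edges(S, 0.0, drugs, prots, train_d, train_p)
        counts = edges.count_by_category()
        # exhaustive enumeration oracle
        from collections import Counter

        expect = Counter(
            f"{'training' if d in train_d else 'new'}-{'training' if p in train_p else 'new'}"
            for d in drugs
            for p in prots
        )
        assert counts == dict(expect)

    def test_threshold_monotone(self, rng):
        S = rng.random((5, 4))
        drugs, prots = [f"d{i}" for i in range(5)], [f"p{j}" for j in range(4)]
        prev = None
        for t in np.linspace(0, 1, 11):
            edges = {(r.drug_id, r.protein_id) for r in
                     threshold_edges(S, t, drugs, prots, drugs[:2], prots[:2]).records}
            if prev is not None:
                assert edges <= prev
            prev = edges

    def test_known_edges_only_in_all_view(self, rng):
        S = np.full((2, 2), 0.9)
        known = {("d1", "p1")}
        pred = threshold_edges(S, 0.5, ["d1", "d2"], ["p1", "p2"], ["d1"], ["p1"], known_edges=known)
        assert ("d1", "p1") not in {(r.drug_id, r.protein_id) for r in pred.records}
        allv = threshold_edges(
            S, 0.5, ["d1", "d2"], ["p1", "p2"], ["d1"], ["p1"], known_edges=known, include_known=True
        )
        flags = {(r.drug_id, r.protein_id): r.known for r in allv.records}
        assert flags[("d1", "p1")] is True and len(allv.records) == 4


class TestModelSerialization:
    @pytest.mark.parametrize("algo", ["pkr", "blm", "bge"])
    def test_save_load_predicts_identically(self, algo, tmp_path, rng):
        Kd = rand_pd_kernel(5, rng, "drug")
        Kp = rand_pd_kernel(4, rng, "protein", "p")
        net = rand_network(5, 4, rng)
        m = fit(Kd, Kp, net, ModelParams(algorithm=algo, embed_dim=2))
        m.save(tmp_path / "m.json")
        back = TrainedModel.load(tmp_path / "m.json")
        assert back.params.algorithm == m.params.algorithm
        S1 = m.predict(Kd.values, Kp.values, range(5), range(4))
        S2 = back.predict(Kd.values, Kp.values, range(5), range(4))
        np.testing.assert_array_equal(S1, S2)
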