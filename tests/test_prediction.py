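"""Layer reconstruction, SPM and the LRM score family."""

import numpy as np
import pytest
from scipy.optimize import minimize

from mxlink import (
    ConfigurationError,
    ContractViolation,
    EdgeSet,
    MethodConfig,
    MultiplexLinkPredictor,
    MultiplexNetwork,
    PerturbationConfig,
    backup_duplex,
    correlated_duplex,
    erdos_renyi_gnm,
    gor,
    lrm_scores,
    objective_Z,
    perturbed_lrm_gor_scores,
    perturbed_lrm_scores,
    randomize_auxiliary,
    reconstruct,
    spectral_decompose,
    spm_scores,
)
from mxlink.prediction import _spm_matrix


def _random_adj(n, p, seed):
    rng = np.random.default_rng(seed)
    a = np.triu((rng.random((n, n)) < p).astype(float), 1)
    return a + a.T


class TestReconstruct:
    def test_full_rank_self_reconstruction_is_exact(self, random_adjacency):
        d = spectral_decompose(random_adjacency)
        rec = reconstruct(random_adjacency, d)
        assert np.allclose(rec.matrix, random_adjacency, atol=1e-8)
        assert np.allclose(rec.coefficients, d.eigenvalues, atol=1e-8)

    def test_standard_basis_vector_contributes_nothing(self):
        from mxlink.core import SpectralDecomposition

        a = _random_adj(5, 0.5, 0)
        e1 = np.zeros((5, 1))
        e1[0, 0] = 1.0
        d = SpectralDecomposition(np.zeros(1), e1, 1)
        rec = reconstruct(a, d)
        assert rec.coefficients[0] == 0.0  # mu = A_11 = 0 (zero diagonal)
        assert not rec.matrix.any()

    def test_closed_form_matches_numeric_least_squares(self):
        """Generic optimizer over ||A - sum mu x x^T||_F^2 on 12 nodes."""
        a_target = _random_adj(12, 0.3, 1)
        d_aux = spectral_decompose(_random_adj(12, 0.3, 2))
        rec = reconstruct(a_target, d_aux)
        res = minimize(
            lambda mu: objective_Z(a_target, d_aux, mu),
            x0=np.zeros(12),
            method="L-BFGS-B",
            tol=1e-14,
        )
        assert np.allclose(rec.coefficients, res.x, atol=1e-6)

    def test_dimension_mismatch_rejected(self):
        d = spectral_decompose(np.zeros((4, 4)))
        with pytest.raises(ContractViolation):
            reconstruct(np.zeros((5, 5)), d)


class TestObjective:
    def test_zero_coefficients_give_twice_edge_count(self):
        a = _random_adj(10, 0.4, 3)
        d = spectral_decompose(a)
        m = a.sum() / 2
        assert objective_Z(a, d, np.zeros(10)) == pytest.approx(2 * m)

    def test_closed_form_is_the_global_minimum(self):
        a = _random_adj(10, 0.4, 4)
        d = spectral_decompose(_random_adj(10, 0.4, 5))
        mu_star = reconstruct(a, d).coefficients
        z_star = objective_Z(a, d, mu_star)
        rng = np.random.default_rng(6)
        for _ in range(100):
            assert z_star <= objective_Z(a, d, mu_star + rng.normal(0, 1, 10)) + 1e-12

    def test_second_derivative_is_two(self):
        a = _random_adj(10, 0.4, 7)
        d = spectral_decompose(_random_adj(10, 0.4, 8))
        rng = np.random.default_rng(9)
        mu = rng.normal(0, 1, 10)
        h = 1e-3
        for k in range(10):
            e = np.zeros(10)
            e[k] = h
            second = (
                objective_Z(a, d, mu + e) - 2 * objective_Z(a, d, mu) + objective_Z(a, d, mu - e)
            ) / h**2
            assert second == pytest.approx(2.0, abs=1e-5)


class TestSPM:
    def test_corrected_eigenvalues_equal_reconstruction_coefficients(self):
        """Per iteration, lambda_k(A_R) + x_k^T dA x_k matches mu_k from the
        closed form — the self-reconstruction identity."""
        a_t = _random_adj(15, 0.3, 10)
        rng = np.random.default_rng(11)
        iu, ju = np.triu_indices(15, 1)
        on = a_t[iu, ju] > 0
        edges = list(zip(iu[on], ju[on]))
        drop = rng.choice(len(edges), size=3, replace=False)
        a_r = a_t.copy()
        delta = np.zeros_like(a_t)
        for t in drop:
            i, j = edges[t]
            a_r[i, j] = a_r[j, i] = 0.0
            delta[i, j] = delta[j, i] = 1.0
        d = spectral_decompose(a_r)
        mu = reconstruct(a_t, d).coefficients
        x = d.eigenvectors
        corrected = d.eigenvalues + np.einsum("ik,ij,jk->k", x, delta, x)
        assert np.allclose(mu, corrected, atol=1e-10)

    def test_empty_perturbation_limit_reduces_to_plain_reconstruction(self):
        # p_h small enough that round(p_h * m) = 0: dA = 0, A_R = A_T
        a_t = _random_adj(12, 0.3, 12)
        cfg = PerturbationConfig(p_h=0.001, iterations=1)
        scores = spm_scores(a_t, cfg=cfg, seed=0)
        # full-basis reconstruction of A_T restricted off-training is ~0
        assert np.allclose(scores.values, 0.0, atol=1e-8)

    def test_score_domain_is_exactly_non_observed_pairs(self):
        a_t = _random_adj(10, 0.4, 13)
        scores = spm_scores(a_t, seed=1)
        iu, ju = np.triu_indices(10, 1)
        observed = {(i, j) for i, j in zip(iu, ju) if a_t[i, j] > 0}
        expected = {(int(i), int(j)) for i, j in zip(iu, ju)} - observed
        assert scores.domain() == expected

    def test_excessive_perturbation_fraction_rejected(self):
        with pytest.raises(ContractViolation):
            PerturbationConfig(p_h=1.0)

    def test_too_few_edges_rejected(self):
        a = np.zeros((5, 5))
        a[0, 1] = a[1, 0] = 1.0
        with pytest.raises(ContractViolation):
            spm_scores(a, seed=0)


class TestLRM:
    def test_scores_decompose_into_self_plus_auxiliary_terms(self, small_duplex):
        """LRM = SPM self matrix + per-auxiliary reconstructions, element-wise."""
        from mxlink._seeds import rng_for
        from mxlink import adjacency

        e_t = small_duplex.layer("a")
        cfg = MethodConfig(method="lrm")
        seed = 21
        scores = lrm_scores(small_duplex, "a", e_t, cfg, seed=seed)
        a_train = e_t.to_adjacency(small_duplex.N)
        self_m = _spm_matrix(a_train, None, cfg.perturbation, rng_for(seed, "spm"))
        aux_m = reconstruct(a_train, spectral_decompose(adjacency(small_duplex, "b"))).matrix
        total = self_m + aux_m
        for (i, j), v in zip(scores.pairs, scores.values):
            assert v == pytest.approx(total[i, j], abs=1e-10)

    def test_zero_edge_auxiliary_contributes_nothing(self):
        base = erdos_renyi_gnm(12, 25, seed=1)
        net = MultiplexNetwork(tuple(range(12)), {"t": base, "empty": EdgeSet()})
        cfg = MethodConfig(method="lrm")
        with_aux = lrm_scores(net, "t", base, cfg, seed=2)
        solo = MultiplexNetwork(tuple(range(12)), {"t": base, "e2": EdgeSet()})
        again = lrm_scores(solo, "t", base, cfg, seed=2)
        assert np.allclose(with_aux.values, again.values)

    def test_auxiliary_equal_to_target_is_configuration_error(self, small_duplex):
        with pytest.raises(ConfigurationError):
            MultiplexLinkPredictor(small_duplex, "a", auxiliary=("a",))

    def test_untouched_backup_with_all_eigenvectors_is_perfect(self):
        """Training edges >= N with an exact-copy auxiliary: AUC = 1."""
        from mxlink import auc, split_edges

        edges = erdos_renyi_gnm(40, 120, seed=3)
        net = backup_duplex(edges, 40)
        split = split_edges(edges, 0.4, seed=4, n_nodes=40)
        assert split.train.m >= 40
        scores = lrm_scores(net, "target", split.train, MethodConfig(), seed=5)
        assert auc(scores, split.probe) == 1.0


class TestPerturbedLRM:
    def test_degenerates_to_lrm_at_full_subsample_single_iteration(self, small_duplex):
        e_t = small_duplex.layer("a")
        cfg = MethodConfig(
            method="lrm_p",
            subsample_fraction=1.0,
            perturbation=PerturbationConfig(iterations=1),
        )
        cfg_lrm = MethodConfig(
            method="lrm", perturbation=PerturbationConfig(iterations=1)
        )
        p = perturbed_lrm_scores(small_duplex, "a", e_t, cfg, seed=31)
        l = lrm_scores(small_duplex, "a", e_t, cfg_lrm, seed=31)
        assert np.allclose(p.values, l.values, atol=1e-12)

    def test_fixed_seed_reproducibility(self, small_duplex):
        e_t = small_duplex.layer("a")
        a = perturbed_lrm_scores(small_duplex, "a", e_t, seed=32)
        b = perturbed_lrm_scores(small_duplex, "a", e_t, seed=32)
        assert np.array_equal(a.values, b.values)

    def test_more_iterations_reduce_score_variance(self, small_duplex):
        e_t = small_duplex.layer("a")
        def spread(iterations):
            cfg = MethodConfig(
                method="lrm_p", perturbation=PerturbationConfig(iterations=iterations)
            )
            vals = np.stack([
                perturbed_lrm_scores(small_duplex, "a", e_t, cfg, seed=s).values
                for s in range(8)
            ])
            return vals.std(axis=0, ddof=1).mean()
        assert spread(10) < spread(1)


class TestGOR:
    def test_identical_layers_give_one(self):
        e = EdgeSet.from_pairs([(0, 1), (1, 2)])
        assert gor(e, EdgeSet(e.edges)) == 1.0

    def test_disjoint_layers_give_zero(self):
        assert gor(EdgeSet.from_pairs([(0, 1)]), EdgeSet.from_pairs([(2, 3)])) == 0.0

    def test_hand_counted_overlap(self):
        ea = EdgeSet.from_pairs([(1, 2), (2, 3)])
        eb = EdgeSet.from_pairs([(2, 3), (3, 4)])
        assert gor(ea, eb) == pytest.approx(0.5)

    def test_empty_layers_define_zero(self):
        assert gor(EdgeSet(), EdgeSet()) == 0.0


class TestGORWeighting:
    def test_unit_weights_recover_perturbed_lrm(self, small_duplex):
        e_t = small_duplex.layer("a")
        cfg = MethodConfig(method="lrm_pg", layer_weights={"b": 1.0})
        pg = perturbed_lrm_gor_scores(small_duplex, "a", e_t, cfg, seed=41)
        plain = perturbed_lrm_scores(
            small_duplex, "a", e_t, MethodConfig(method="lrm_p"), seed=41
        )
        assert np.allclose(pg.values, plain.values, atol=1e-12)

    def test_zero_weight_auxiliary_contributes_nothing(self, small_duplex):
        e_t = small_duplex.layer("a")
        cfg = MethodConfig(method="lrm_pg", layer_weights={"b": 0.0})
        pg = perturbed_lrm_gor_scores(small_duplex, "a", e_t, cfg, seed=42)
        from mxlink._seeds import rng_for

        self_only = _spm_matrix(
            e_t.to_adjacency(small_duplex.N), None, cfg.perturbation, rng_for(42, "spm")
        )
        for (i, j), v in zip(pg.pairs, pg.values):
            assert v == pytest.approx(self_only[i, j], abs=1e-12)

    def test_weighted_sum_is_linear_in_auxiliary_terms(self):
        net = correlated_duplex(20, 50, 0.2, seed=43)
        third = erdos_renyi_gnm(20, 50, seed=44)
        net = net.with_layer("c", third)
        e_t = net.layer("a")
        w1, w2 = 0.7, 0.3
        cfg = MethodConfig(method="lrm_pg", layer_weights={"b": w1, "c": w2})
        combined = perturbed_lrm_gor_scores(net, "a", e_t, cfg, seed=45)
        def single(name, w):
            c = MethodConfig(
                method="lrm_pg", auxiliary_layers=(name,), layer_weights={name: w}
            )
            return perturbed_lrm_gor_scores(net, "a", e_t, c, seed=45)
        from mxlink._seeds import rng_for

        self_m = _spm_matrix(
            e_t.to_adjacency(net.N), None, cfg.perturbation, rng_for(45, "spm")
        )
        s_b = single("b", w1)
        s_c = single("c", w2)
        expected = s_b.values + s_c.values - np.array(
            [self_m[i, j] for i, j in s_b.pairs]
        )
        assert np.allclose(combined.values, expected, atol=1e-10)


class TestRandomizedAuxiliary:
    def test_empty_auxiliary_stays_empty(self):
        assert not randomize_auxiliary(np.zeros((10, 10)), seed=0).any()

    def test_expected_edge_count_matches_density(self):
        a = _random_adj(25, 0.3, 50)
        m_orig = a.sum() / 2
        counts = [randomize_auxiliary(a, seed=s).sum() / 2 for s in range(200)]
        assert np.mean(counts) == pytest.approx(m_orig, rel=0.05)

    def test_fixed_seed_reproducibility(self):
        a = _random_adj(15, 0.3, 51)
        assert np.array_equal(randomize_auxiliary(a, seed=7), randomize_auxiliary(a, seed=7))


class TestPredictorModel:
    def test_fit_scores_all_non_observed_pairs(self, small_duplex):
        res = MultiplexLinkPredictor(small_duplex, "a").fit(seed=0)
        n = small_duplex.N
        assert len(res.scores) == n * (n - 1) // 2 - small_duplex.layer("a").m
        frame = res.to_frame()
        assert list(frame.columns) == ["nodeA", "nodeB", "score"]
        assert np.all(np.diff(frame["score"].to_numpy()) <= 1e-12)

    def test_unknown_target_fails_fast(self, small_duplex):
        with pytest.raises(KeyError):
            MultiplexLinkPredictor(small_duplex, "nope")
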