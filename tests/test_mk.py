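import numpy as np
import pytest
import scipy.integrate
import scipy.linalg
import scipy.stats

from conftest import mk_loglik_brute_force, random_matrix, random_tree
from morphobench.mk import (MkConfig, gamma_categories, mk_loglik,
                            mk_transition, ml_search, state_counts)
from morphobench.simulate import (CharacterMatrix, draw_replicate_params,
                                  simulate_matrix)
from morphobench.trees import Tree, enumerate_topologies, random_resolved_tree


class TestMkTransition:
    def test_zero_time_identity(self):
        for k in (2, 3, 4):
            assert np.allclose(mk_transition(0.0, k), np.eye(k))

    def test_long_time_uniform(self):
        assert np.allclose(mk_transition(500.0, 2), np.full((2, 2), 0.5))

    @pytest.mark.parametrize("k", [2, 3, 4])
    @pytest.mark.parametrize("tau", [0.05, 0.5, 2.0])
    def test_matches_matrix_exponential(self, k, tau):
        # normalised Mk generator: off-diagonal rate 1/(k-1)
        Q = np.full((k, k), 1.0 / (k - 1))
        np.fill_diagonal(Q, -1.0)
        assert np.allclose(
            mk_transition(tau, k), scipy.linalg.expm(Q * tau), atol=1e-12
        )

    def test_binary_closed_form(self):
        # k=2, tau=0.5: P_same = 1/2 + 1/2 e^(-1)
        P = mk_transition(0.5, 2)
        assert P[0, 0] == pytest.approx(0.5 + 0.5 * np.exp(-1.0))

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            mk_transition(-1.0, 2)


class TestGammaCategories:
    @pytest.mark.parametrize("alpha", [0.1, 0.5, 1.0, 7.0])
    def test_mean_is_one(self, alpha):
        assert gamma_categories(alpha, 4).mean() == pytest.approx(1.0, abs=1e-8)

    def test_large_alpha_collapses_to_one(self):
        assert np.allclose(gamma_categories(5e4, 4), 1.0, atol=1e-2)

    def test_matches_quadrature_oracle(self):
        alpha, k = 0.5, 4
        qs = scipy.stats.gamma.ppf(np.arange(k + 1) / k, alpha, scale=1 / alpha)
        means = []
        for i in range(k):
            hi = qs[i + 1] if np.isfinite(qs[i + 1]) else np.inf
            v, _ = scipy.integrate.quad(
                lambda x: x * scipy.stats.gamma.pdf(x, alpha, scale=1 / alpha),
                qs[i], hi,
            )
            means.append(v * k)
        assert np.allclose(gamma_categories(alpha, k), means, atol=1e-7)


class TestMkLoglik:
    def test_two_taxon_closed_form(self):
        # identical binary states: L = 0.5 * (1/2 + 1/2 e^(-2 tau));
        # at large tau L -> 0.25
        for tau, expect in [(0.1, 0.5 * (0.5 + 0.5 * np.exp(-0.4))),
                            (400.0, 0.25)]:
            t = Tree.from_newick(f"(A:{tau},B:{tau});")
            m = CharacterMatrix(["A", "B"], np.zeros((2, 1), np.int8),
                                np.ones(1, bool))
            ll = mk_loglik(m, t, alpha=1.0, config=MkConfig(n_gamma_categories=1))
            assert ll == pytest.approx(np.log(expect), abs=1e-9)

    @pytest.mark.parametrize("n_leaves", [4, 5])
    def test_pruning_matches_brute_force(self, n_leaves):
        rng = np.random.default_rng(n_leaves)
        for trial in range(4):
            tree = random_tree(rng, n_leaves)
            m = random_matrix(rng, tree.labels, 4,
                              missing=0.1 if trial == 3 else 0.0)
            ll = mk_loglik(m, tree, alpha=0.8)
            brute = mk_loglik_brute_force(m, tree, alpha=0.8)
            assert ll == pytest.approx(brute, abs=1e-10)

    def test_mkv_matches_brute_force_and_exceeds_mk(self):
        rng = np.random.default_rng(0)
        tree = random_tree(rng, 4)
        m = random_matrix(rng, tree.labels, 3)
        cfg = MkConfig(ascertainment="variable")
        llv = mk_loglik(m, tree, 0.8, cfg)
        assert llv == pytest.approx(
            mk_loglik_brute_force(m, tree, 0.8, mkv=True), abs=1e-9
        )
        assert llv > mk_loglik(m, tree, 0.8)

    def test_invariant_to_rerooting(self):
        rng = np.random.default_rng(1)
        tree = random_tree(rng, 7)
        m = random_matrix(rng, tree.labels, 15)
        base = mk_loglik(m, tree, 1.3)
        for node in (0, 2, 8):
            if node == tree.root:
                continue
            assert mk_loglik(m, tree.rerooted_above(node), 1.3) == \
                pytest.approx(base, abs=1e-9)

    def test_state_count_rules(self):
        states = np.array([[0, 1], [1, 3], [0, 1], [1, 2]], dtype=np.int8)
        m = CharacterMatrix(list("ABCD"), states, np.array([True, False]))
        assert state_counts(m, "observed").tolist() == [2, 3]
        assert state_counts(m, "by_type").tolist() == [2, 4]


class TestMLSearch:
    def _oracle_best_topology(self, matrix, labels, alpha_grid=(0.5, 1.0, 2.0)):
        """Independent oracle: joint scipy optimisation per topology."""
        from scipy.optimize import minimize

        best_ll, best_key = -np.inf, None
        for top in enumerate_topologies(labels):
            t = top.copy()

            def neg(x):
                for i, v in enumerate(w for w in range(t.n_nodes) if w != t.root):
                    t.blen[v] = float(np.exp(x[i]))
                return -mk_loglik(matrix, t, float(np.exp(x[-1])))

            n_edges = t.n_nodes - 1
            res = minimize(neg, np.zeros(n_edges + 1) - 1.5,
                           method="Nelder-Mead",
                           options={"maxiter": 4000, "fatol": 1e-8})
            if -res.fun > best_ll:
                best_ll, best_key = -res.fun, top.topology_key()
        return best_key, best_ll

    def test_quartet_matches_three_topology_oracle(self):
        rng = np.random.default_rng(5)
        gen = Tree.from_newick("((A:0.2,B:0.2):0.15,(C:0.2,D:0.2):0.15);")
        params = draw_replicate_params(7, n_characters=120)
        from morphobench.simulate import SimulationParams
        params = SimulationParams(alpha=2.0, mu=1.0, n_characters=120)
        m = simulate_matrix(gen, params, seed=11)
        res = ml_search(m, seed=0)
        key, oracle_ll = self._oracle_best_topology(m, list("ABCD"))
        assert res.tree.topology_key() == key
        # greedy coordinate search may settle in a nearby local optimum of
        # the continuous parameters; the topology decision is what matters
        assert res.loglik >= oracle_ll - 1.0

    def test_consistency_on_fixed_tree(self):
        # plenty of characters on a 6-taxon tree: topology is recovered
        rng = np.random.default_rng(9)
        gen = random_resolved_tree(list("ABCDEF"), rng, blen=0.3)
        from morphobench.simulate import SimulationParams
        params = SimulationParams(alpha=5.0, mu=1.0, n_characters=3000)
        m = simulate_matrix(gen, params, seed=13)
        res = ml_search(m, seed=1)
        assert res.tree.topology_key() == gen.topology_key()

    def test_result_is_fully_resolved_with_finite_loglik(self):
        rng = np.random.default_rng(3)
        tree = random_tree(rng, 8, max_blen=0.4)
        m = random_matrix(rng, tree.labels, 30)
        res = ml_search(m, seed=2)
        assert res.tree.is_binary()
        assert np.isfinite(res.loglik)
        assert 0.02 <= res.alpha <= 100.0
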