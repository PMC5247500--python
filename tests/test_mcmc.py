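import numpy as np
import pytest

from morphobench.mcmc import (MCMCConfig, convergence_diagnostics, run_mcmc)
from morphobench.mcmc import _alpha_grid
from morphobench.mk import mk_loglik
from morphobench.simulate import CharacterMatrix
from morphobench.trees import Tree, enumerate_topologies


def quartet_matrix(n_clean: int, n_noise: int, seed: int = 0) -> CharacterMatrix:
    """AB|CD signal characters plus random noise characters."""
    rng = np.random.default_rng(seed)
    clean = np.tile(np.array([[0], [0], [1], [1]], np.int8), (1, n_clean))
    noise = rng.integers(0, 2, (4, n_noise)).astype(np.int8)
    states = np.concatenate([clean, noise], axis=1)
    return CharacterMatrix(list("ABCD"), states,
                           np.ones(n_clean + n_noise, bool))


class TestConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            MCMCConfig(n_generations=1000, sample_interval=300)
        with pytest.raises(ValueError):
            MCMCConfig(burn_in_fraction=1.0)
        with pytest.raises(ValueError):
            MCMCConfig(move_weights=(0, 0, 0, 0))

    def test_paper_scale_preset(self):
        cfg = MCMCConfig.paper_scale()
        assert cfg.n_generations == 1_000_000
        assert cfg.n_runs == 2 and cfg.n_chains == 4
        assert cfg.sample_interval == 100


@pytest.fixture(scope="module")
def prior_sample():
    cfg = MCMCConfig(n_generations=60_000, n_runs=1, flat_likelihood=True)
    return run_mcmc(quartet_matrix(2, 0), cfg, seed=1)


class TestPriorRecovery:
    """With the likelihood switched off the sampler must reproduce priors."""

    def test_branch_length_prior_mean(self, prior_sample):
        # Exponential(10) prior: mean edge length 0.1
        mean_edge = prior_sample.tree_length.mean() / 6
        assert mean_edge == pytest.approx(0.1, abs=0.01)

    def test_branch_length_prior_quantiles(self, prior_sample):
        # a wrong multiplier Hastings term would distort the distribution
        edges = np.concatenate(
            [prior_sample.blen[i] for i in range(0, prior_sample.n_samples, 20)]
        )
        edges = edges[edges > 0]
        q50 = np.quantile(edges, 0.5)
        assert q50 == pytest.approx(np.log(2) / 10, rel=0.2)

    def test_topology_prior_uniform(self, prior_sample):
        freqs = prior_sample.split_frequencies()
        assert len(freqs) == 3
        for f in freqs.values():
            assert f == pytest.approx(1 / 3, abs=0.05)

    def test_sample_count_arithmetic(self, prior_sample):
        # runs x floor(gens / interval) x (1 - burn-in)
        assert prior_sample.n_samples == 1 * (60_000 // 100) * 3 // 4


class TestPosteriorCorrectness:
    def test_topology_posterior_matches_enumeration(self):
        """NNI-only chain with frozen branch lengths and shape: the sampled
        topology frequencies must match the normalised likelihoods of the
        three quartet topologies."""
        m = quartet_matrix(6, 6, seed=3)
        cfg = MCMCConfig(
            n_generations=200_000, n_runs=1,
            move_weights=(1.0, 0.0, 0.0, 0.0),
        )
        b = 0.15
        start = Tree.from_newick(f"((A:{b},B:{b}):{b},(C:{b},D:{b}):{b});")
        sample = run_mcmc(m, cfg, seed=4, start_tree=start)
        grid, _, _ = _alpha_grid(cfg)
        alpha0 = float(grid[np.argmin(np.abs(grid - 1.0))])
        lls = {}
        for top in enumerate_topologies(list("ABCD")):
            t = top.copy()
            for v in range(t.n_nodes):
                if v != t.root:
                    t.blen[v] = b
            key = next(iter(t.split_masks()))
            lls[key] = mk_loglik(m, t, alpha0)
        mx = max(lls.values())
        ws = {k: np.exp(v - mx) for k, v in lls.items()}
        z = sum(ws.values())
        expected = {k: w / z for k, w in ws.items()}
        freqs = sample.split_frequencies()
        for k, p in expected.items():
            assert freqs.get(k, 0.0) == pytest.approx(p, abs=0.05)

    def test_strong_data_recovers_generating_split(self):
        m = quartet_matrix(400, 40, seed=5)
        cfg = MCMCConfig(n_generations=30_000, n_runs=1)
        sample = run_mcmc(m, cfg, seed=6)
        order = sorted(m.taxa)
        # canonical mask of AB|CD: side without "A" is {C,D}
        mask_cd = (1 << order.index("C")) | (1 << order.index("D"))
        assert sample.split_frequencies().get(mask_cd, 0.0) > 0.95
        assert sample.consensus().split_masks() == {mask_cd}

    def test_bit_identical_given_seed(self):
        m = quartet_matrix(20, 20, seed=7)
        cfg = MCMCConfig(n_generations=5_000, n_runs=2)
        a = run_mcmc(m, cfg, seed=8)
        b = run_mcmc(m, cfg, seed=8)
        assert np.array_equal(a.left, b.left)
        assert np.array_equal(a.blen, b.blen)
        assert np.array_equal(a.loglik, b.loglik)

    def test_metropolis_coupling_runs(self):
        m = quartet_matrix(50, 10, seed=9)
        cfg = MCMCConfig(n_generations=10_000, n_runs=1, n_chains=3,
                         swap_interval=1000)
        sample = run_mcmc(m, cfg, seed=10)
        assert sample.n_samples == 75
        order = sorted(m.taxa)
        mask_cd = (1 << order.index("C")) | (1 << order.index("D"))
        assert sample.split_frequencies().get(mask_cd, 0.0) > 0.9

    def test_combined_runs_average_frequencies(self):
        m = quartet_matrix(10, 30, seed=11)
        cfg = MCMCConfig(n_generations=20_000, n_runs=2)
        s = run_mcmc(m, cfg, seed=12)
        n1, n2 = s.n_per_run
        f1 = s.split_frequencies(slice(0, n1))
        f2 = s.split_frequencies(slice(n1, n1 + n2))
        fc = s.split_frequencies()
        for k in set(f1) | set(f2):
            mean = (f1.get(k, 0) * n1 + f2.get(k, 0) * n2) / (n1 + n2)
            assert fc.get(k, 0.0) == pytest.approx(mean, abs=1e-12)


class TestConvergenceDiagnostics:
    def test_identical_samples_give_zero_asdsf(self):
        m = quartet_matrix(30, 10, seed=13)
        cfg = MCMCConfig(n_generations=5_000, n_runs=1)
        s = run_mcmc(m, cfg, seed=14)
        rep = convergence_diagnostics(s, s)
        assert rep.asdsf == 0.0 and rep.passed

    def test_strong_data_runs_converge(self):
        m = quartet_matrix(200, 20, seed=15)
        cfg = MCMCConfig(n_generations=20_000, n_runs=1)
        s1 = run_mcmc(m, cfg, seed=16)
        s2 = run_mcmc(m, cfg, seed=17)
        rep = convergence_diagnostics(s1, s2)
        assert rep.asdsf < 0.05

    def test_tiny_noise_runs_flagged(self):
        m = quartet_matrix(0, 25, seed=18)
        cfg = MCMCConfig(n_generations=600, sample_interval=20, n_runs=1)
        s1 = run_mcmc(m, cfg, seed=19)
        s2 = run_mcmc(m, cfg, seed=20)
        rep = convergence_diagnostics(s1, s2, asdsf_threshold=0.02)
        assert not rep.passed

    def test_mismatched_runs_rejected(self):
        m1 = quartet_matrix(5, 5, seed=21)
        m2 = CharacterMatrix(list("WXYZ"), m1.states, m1.is_binary)
        cfg = MCMCConfig(n_generations=1_000, n_runs=1)
        s1 = run_mcmc(m1, cfg, seed=22)
        s2 = run_mcmc(m2, cfg, seed=23)
        with pytest.raises(ValueError):
            convergence_diagnostics(s1, s2)
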