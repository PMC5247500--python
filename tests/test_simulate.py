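import numpy as np
import pytest
import scipy.linalg

from morphobench import io
from morphobench.simulate import (CharacterMatrix, SimulationParams,
                                  draw_replicate_params, hky_rate_matrix,
                                  hky_transition_matrix, recode_characters,
                                  simulate_matrix, simulate_nucleotides)
from morphobench.trees import Tree, make_asymmetric_tree


def star_tree(n: int, blen: float) -> Tree:
    labels = [f"s{i}" for i in range(n)]
    children = [[] for _ in range(n)] + [list(range(n))]
    parent = [n] * n + [-1]
    return Tree(children, parent, [blen] * n + [0.0], labels, n)


class TestReplicateParams:
    def test_fixed_study_constants(self):
        p = draw_replicate_params(5)
        assert p.kappa == 2.0 and p.pi == (0.2, 0.2, 0.3, 0.3)
        assert p.binary_fraction == 0.55

    def test_deterministic_given_seed(self):
        assert draw_replicate_params(11) == draw_replicate_params(11)
        assert draw_replicate_params(11) != draw_replicate_params(12)

    def test_exponential_means(self):
        draws = [draw_replicate_params(s) for s in range(10_000)]
        for attr in ("alpha", "mu"):
            vals = np.array([getattr(d, attr) for d in draws])
            # Exponential(1): se of the mean is 1/sqrt(n)
            assert abs(vals.mean() - 1.0) < 3 / np.sqrt(len(vals))

    def test_validation(self):
        with pytest.raises(ValueError):
            SimulationParams(alpha=1, mu=1, pi=(0.5, 0.5, 0.2, 0.2))
        with pytest.raises(ValueError):
            SimulationParams(alpha=-1, mu=1)
        with pytest.raises(ValueError):
            SimulationParams(alpha=1, mu=1, binary_fraction=1.2)

    def test_yaml_round_trip(self):
        p = draw_replicate_params(3)
        assert SimulationParams.from_yaml(p.to_yaml()) == p


class TestHKY:
    def test_zero_time_is_identity(self):
        assert np.allclose(hky_transition_matrix(0.0), np.eye(4))

    def test_long_time_reaches_stationarity(self):
        P = hky_transition_matrix(500.0)
        assert np.allclose(P, np.tile([0.2, 0.2, 0.3, 0.3], (4, 1)), atol=1e-9)

    @pytest.mark.parametrize("t,rate", [(0.5, 1.0), (0.1, 2.7), (3.0, 0.3)])
    def test_matches_matrix_exponential(self, t, rate):
        Q = hky_rate_matrix(2.0, (0.2, 0.2, 0.3, 0.3))
        expected = scipy.linalg.expm(Q * t * rate)
        got = hky_transition_matrix(t, rate)
        assert np.allclose(got, expected, atol=1e-12)
        assert np.allclose(got.sum(axis=1), 1.0)

    def test_mean_rate_normalisation(self):
        Q = hky_rate_matrix()
        pi = np.array([0.2, 0.2, 0.3, 0.3])
        assert abs(-(pi @ np.diag(Q)) - 1.0) < 1e-12
        assert np.allclose(pi @ Q, 0.0, atol=1e-12)  # stationarity

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            hky_transition_matrix(-0.1)


class TestNucleotideSimulation:
    def test_output_dimensions(self):
        tree = make_asymmetric_tree(8)
        p = draw_replicate_params(0)
        nucs = simulate_nucleotides(tree, p, n_characters=37, seed=1)
        assert nucs.shape == (8, 37)
        assert set(np.unique(nucs)) <= {0, 1, 2, 3}

    def test_star_tree_stationarity(self):
        # long branches: every tip is an independent draw from pi
        tree = star_tree(6, 400.0)
        p = SimulationParams(alpha=1e6, mu=1.0, n_characters=10_000)
        nucs = simulate_nucleotides(tree, p, seed=2)
        freqs = np.bincount(nucs.ravel(), minlength=4) / nucs.size
        se = np.sqrt(np.array(p.pi) * (1 - np.array(p.pi)) / nucs.size)
        assert np.all(np.abs(freqs - p.pi) < 3.5 * se)

    def test_rate_heterogeneity_scales_with_alpha(self):
        # low alpha: many characters effectively frozen -> more invariant cols
        tree = make_asymmetric_tree(16)
        frac_invariant = {}
        for alpha in (0.1, 100.0):
            p = SimulationParams(alpha=alpha, mu=0.3, n_characters=4000)
            nucs = simulate_nucleotides(tree, p, seed=3)
            frac_invariant[alpha] = np.mean(
                [len(np.unique(nucs[:, j])) == 1 for j in range(4000)]
            )
        assert frac_invariant[0.1] > frac_invariant[100.0]


class TestRecoding:
    @pytest.mark.parametrize("n,expected", [(100, 55), (1000, 550), (9, 5)])
    def test_binary_multistate_split(self, n, expected):
        nucs = np.random.default_rng(0).integers(0, 4, (6, n)).astype(np.int8)
        m = recode_characters(nucs, 0.55, seed=4)
        assert int(m.is_binary.sum()) == expected
        assert m.n_characters == n

    def test_all_a_column_becomes_invariant_zero(self):
        nucs = np.zeros((5, 10), dtype=np.int8)  # all A
        m = recode_characters(nucs, 1.0, seed=0)
        assert np.all(m.states == 0) and m.is_binary.all()

    def test_binary_columns_are_ry_image(self):
        tree = make_asymmetric_tree(10)
        m = simulate_matrix(tree, draw_replicate_params(5), seed=6)
        ry = np.isin(m.nucleotides, (1, 3)).astype(np.int8)  # C,T -> 1
        assert np.array_equal(m.states[:, m.is_binary], ry[:, m.is_binary])
        assert np.array_equal(
            m.states[:, ~m.is_binary], m.nucleotides[:, ~m.is_binary]
        )

    def test_binary_state_zero_frequency_is_half(self):
        # pi_A + pi_G = 0.5 exactly, so R/Y states are symmetric
        tree = star_tree(6, 400.0)
        p = SimulationParams(alpha=1e6, mu=1.0, n_characters=10_000,
                             binary_fraction=1.0)
        nucs = simulate_nucleotides(tree, p, seed=7)
        m = recode_characters(nucs, 1.0, seed=8)
        freq0 = np.mean(m.states == 0)
        assert abs(freq0 - 0.5) < 3.5 / (2 * np.sqrt(m.states.size))

    def test_full_determinism(self):
        tree = make_asymmetric_tree(12)
        p = draw_replicate_params(9, n_characters=50)
        a = simulate_matrix(tree, p, seed=10)
        b = simulate_matrix(tree, p, seed=10)
        assert np.array_equal(a.states, b.states)
        assert np.array_equal(a.is_binary, b.is_binary)


class TestMatrixValidationAndIO:
    def test_binary_columns_must_be_01(self):
        states = np.array([[0, 2], [1, 3]], dtype=np.int8)
        with pytest.raises(ValueError):
            CharacterMatrix(["a", "b"], states, np.array([True, True]))

    def test_nexus_round_trip(self):
        tree = make_asymmetric_tree(6)
        m = simulate_matrix(tree, draw_replicate_params(1, n_characters=20))
        back = io.read_nexus(io.write_nexus(m))
        assert back.taxa == m.taxa
        assert np.array_equal(back.states, m.states)

    def test_phylip_round_trip_with_missing(self):
        states = np.array([[0, 1, -1], [1, 2, 3]], dtype=np.int8)
        m = CharacterMatrix(["tax_one", "tax_two"], states,
                            np.array([True, False, False]))
        back = io.read_phylip(io.write_phylip(m))
        assert back.taxa == m.taxa
        assert np.array_equal(back.states, m.states)

    def test_tnt_contains_xread_block(self):
        m = CharacterMatrix(["a", "b"], np.zeros((2, 3), np.int8),
                            np.ones(3, bool))
        text = io.write_tnt(m)
        assert text.startswith("xread") and text.rstrip().endswith(";")

    def test_format_sniffing(self):
        m = CharacterMatrix(["a", "b"], np.zeros((2, 3), np.int8),
                            np.ones(3, bool))
        assert io.read_matrix(io.write_nexus(m)).taxa == ["a", "b"]
        assert io.read_matrix(io.write_phylip(m)).taxa == ["a", "b"]
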