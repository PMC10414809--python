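"""Markov network model: potentials, partition function, probabilities."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from consnet import (
    CommunityMatrix,
    CovariateMatrix,
    MarkovNetworkParams,
    configuration_probabilities,
    log_likelihood,
    log_partition,
    log_potential,
)
from consnet.mrf import enumerate_configurations

from conftest import brute_force_log_partition, brute_force_probabilities, random_params


class TestLogPotential:
    def test_empty_configuration_is_zero(self, two_species_params):
        assert log_potential([0, 0], [1.0], two_species_params) == 0.0

    def test_single_species_linear_term(self):
        p = MarkovNetworkParams([[0.5]], [[0.0]], ["sp1"], ["intercept"])
        assert log_potential([1], [1.0], p) == pytest.approx(0.5)

    def test_hand_evaluated_pair(self, two_species_params):
        # 0.2 - 0.1 + 0.3
        assert log_potential([1, 1], [1.0], two_species_params) == pytest.approx(0.4)

    def test_dimension_mismatch_raises(self, two_species_params):
        with pytest.raises(ValueError, match="shape"):
            log_potential([1, 1, 0], [1.0], two_species_params)
        with pytest.raises(ValueError, match="shape"):
            log_potential([1, 1], [1.0, 2.0], two_species_params)


class TestLogPartition:
    def test_uniform_single_species(self):
        p = MarkovNetworkParams([[0.0]], [[0.0]], ["sp1"], ["x"])
        assert log_partition([1.0], p) == pytest.approx(math.log(2))

    def test_uniform_two_species(self):
        p = MarkovNetworkParams(np.zeros((2, 1)), np.zeros((2, 2)), ["a", "b"], ["x"])
        assert log_partition([1.0], p) == pytest.approx(math.log(4))

    def test_matches_enumeration_oracle(self, two_species_params):
        # frozen from the explicit enumeration oracle
        assert log_partition([1.0], two_species_params) == pytest.approx(
            1.5299757588711793, abs=1e-12
        )

    @pytest.mark.parametrize("S", [1, 2, 3, 4, 5, 6])
    def test_normalization_against_brute_force(self, S):
        rng = np.random.default_rng(S)
        params = random_params(S, 2, rng)
        x = rng.normal(size=2)
        oracle = brute_force_log_partition(params.alpha.tolist(), params.beta.tolist(), x.tolist())
        assert log_partition(x, params) == pytest.approx(oracle, rel=1e-10)

    def test_enumeration_limit_refuses(self):
        S = 21
        p = MarkovNetworkParams(np.zeros((S, 1)), np.zeros((S, S)),
                                [f"s{i}" for i in range(S)], ["x"])
        with pytest.raises(ValueError, match="pseudolikelihood"):
            log_partition([1.0], p)


class TestLogLikelihood:
    def test_uniform_model_gives_minus_s_log2(self):
        S = 3
        p = MarkovNetworkParams(np.zeros((S, 1)), np.zeros((S, S)), list("abc"), ["x"])
        data = CommunityMatrix(["s1"], list("abc"), np.array([[1, 0, 1]]), "occurrence")
        cov = CovariateMatrix(["s1"], ["x"], np.array([[1.0]]))
        assert log_likelihood(data, cov, p) == pytest.approx(-S * math.log(2))

    def test_additivity_over_sites(self, two_species_params):
        data2 = CommunityMatrix(["s1", "s2"], ["sp1", "sp2"],
                                np.array([[1, 0], [1, 0]]), "occurrence")
        cov2 = CovariateMatrix(["s1", "s2"], ["intercept"], np.ones((2, 1)))
        data1 = CommunityMatrix(["s1"], ["sp1", "sp2"], np.array([[1, 0]]), "occurrence")
        cov1 = CovariateMatrix(["s1"], ["intercept"], np.ones((1, 1)))
        assert log_likelihood(data2, cov2, two_species_params) == pytest.approx(
            2 * log_likelihood(data1, cov1, two_species_params)
        )

    def test_matches_enumerated_probability_product(self, small_community):
        data, covars = small_community
        rng = np.random.default_rng(0)
        params = random_params(3, 2, rng)
        expected = 0.0
        for s in range(data.n_sites):
            probs = brute_force_probabilities(
                params.alpha.tolist(), params.beta.tolist(), covars.values[s].tolist()
            )
            expected += math.log(probs[tuple(data.values[s])])
        assert log_likelihood(data, covars, params) == pytest.approx(expected, rel=1e-10)

    def test_nonpositive(self, small_community):
        data, covars = small_community
        params = random_params(3, 2, np.random.default_rng(1))
        assert log_likelihood(data, covars, params) <= 0.0

    def test_abundance_mode_rejected(self, small_community):
        _, covars = small_community
        data = CommunityMatrix(["a", "b", "c", "d"], ["sp1", "sp2", "sp3"],
                               np.array([[2, 0, 1], [0, 1, 1], [1, 1, 0], [0, 0, 3]]),
                               "abundance")
        params = random_params(3, 2, np.random.default_rng(1))
        with pytest.raises(ValueError, match="abundance"):
            log_likelihood(data, covars, params)

    def test_species_permutation_invariance(self, small_community):
        data, covars = small_community
        rng = np.random.default_rng(2)
        params = random_params(3, 2, rng)
        base = log_likelihood(data, covars, params)
        perm = [2, 0, 1]
        data_p = CommunityMatrix(data.site_ids,
                                 [data.species_names[i] for i in perm],
                                 data.values[:, perm], "occurrence")
        params_p = MarkovNetworkParams(
            params.alpha[perm], params.beta[np.ix_(perm, perm)],
            [params.species_names[i] for i in perm], params.factor_names,
        )
        assert log_likelihood(data_p, covars, params_p) == pytest.approx(base, rel=1e-12)


class TestConfigurationProbabilities:
    def test_uniform_quarters(self):
        p = MarkovNetworkParams(np.zeros((2, 1)), np.zeros((2, 2)), ["a", "b"], ["x"])
        df = configuration_probabilities([1.0], p)
        assert np.allclose(df["probability"], 0.25)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_probabilities_sum_to_one(self, seed):
        rng = np.random.default_rng(seed)
        S = int(rng.integers(1, 6))
        params = random_params(S, 2, rng, scale=1.0)
        x = rng.normal(size=2)
        df = configuration_probabilities(x, params)
        assert df["probability"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_strong_positive_association_favours_joint_presence(self):
        p = MarkovNetworkParams(np.zeros((2, 1)),
                                np.array([[0.0, 2.0], [2.0, 0.0]]), ["a", "b"], ["x"])
        df = configuration_probabilities([1.0], p)
        top = df.sort_values("probability").iloc[-1]
        assert top["a"] == 1 and top["b"] == 1
        # frozen from the enumeration oracle at beta=2
        assert top["probability"] == pytest.approx(0.7112345942275938, abs=1e-12)

    def test_monotone_in_beta(self):
        """Raising beta_ij strictly raises P(both present)."""
        probs = []
        for b in (0.0, 0.5, 1.0):
            p = MarkovNetworkParams(np.zeros((3, 1)), np.array(
                [[0, b, 0], [b, 0, 0], [0, 0, 0.0]]), list("abc"), ["x"])
            df = configuration_probabilities([1.0], p)
            probs.append(df.loc[(df["a"] == 1) & (df["b"] == 1), "probability"].sum())
        assert probs[0] < probs[1] < probs[2]


class TestEnumerationOrder:
    def test_species_zero_is_lsb(self):
        configs = enumerate_configurations(3)
        assert configs.shape == (8, 3)
        assert list(configs[1]) == [1, 0, 0]
        assert list(configs[4]) == [0, 0, 1]


class TestParamsValidation:
    def test_asymmetric_beta_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            MarkovNetworkParams(np.zeros((2, 1)),
                                np.array([[0.0, 1.0], [0.5, 0.0]]), ["a", "b"], ["x"])

    def test_nonzero_diagonal_rejected(self):
        with pytest.raises(ValueError, match="diagonal"):
            MarkovNetworkParams(np.zeros((2, 1)),
                                np.array([[0.1, 0.0], [0.0, 0.0]]), ["a", "b"], ["x"])
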