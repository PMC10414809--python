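import itertools
import math

import numpy as np
import pytest

from consnet import CommunityMatrix, CovariateMatrix, MarkovNetworkParams


def brute_force_log_partition(alpha, beta, x):
    """Independent oracle: explicit enumeration with scalar loops."""
    S = len(alpha)
    total = 0.0
    for config in itertools.product([0, 1], repeat=S):
        e = 0.0
        for i in range(S):
            e += sum(alpha[i][f] * x[f] for f in range(len(x))) * config[i]
            for j in range(i + 1, S):
                e += beta[i][j] * config[i] * config[j]
        total += math.exp(e)
    return math.log(total)


def brute_force_probabilities(alpha, beta, x):
    """Oracle probability of every configuration, keyed by tuple."""
    S = len(alpha)
    logZ = brute_force_log_partition(alpha, beta, x)
    out = {}
    for config in itertools.product([0, 1], repeat=S):
        e = 0.0
        for i in range(S):
            e += sum(alpha[i][f] * x[f] for f in range(len(x))) * config[i]
            for j in range(i + 1, S):
                e += beta[i][j] * config[i] * config[j]
        out[config] = math.exp(e - logZ)
    return out


@pytest.fixture
def two_species_params():
    """S=2 toy model: alpha=(0.2, -0.1) on an intercept factor, beta12=0.3."""
    return MarkovNetworkParams(
        alpha=np.array([[0.2], [-0.1]]),
        beta=np.array([[0.0, 0.3], [0.3, 0.0]]),
        species_names=["sp1", "sp2"],
        factor_names=["intercept"],
    )


@pytest.fixture
def small_community():
    """Hand-written 4-site, 3-species occurrence matrix with covariates."""
    data = CommunityMatrix(
        site_ids=["a", "b", "c", "d"],
        species_names=["sp1", "sp2", "sp3"],
        values=np.array([[1, 0, 1], [0, 1, 1], [1, 1, 0], [0, 0, 1]]),
        mode="occurrence",
    )
    covars = CovariateMatrix(
        site_ids=["a", "b", "c", "d"],
        factor_names=["intercept", "moisture"],
        values=np.array([[1.0, 0.2], [1.0, 0.8], [1.0, 0.5], [1.0, 0.1]]),
    )
    return data, covars


def random_params(S, F, rng, scale=0.5):
    alpha = rng.normal(0, scale, size=(S, F))
    b = rng.normal(0, scale, size=(S, S))
    beta = np.triu(b, 1)
    beta = beta + beta.T
    names = [f"sp{i}" for i in range(S)]
    return MarkovNetworkParams(alpha, beta, names, [f"f{k}" for k in range(F)])
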