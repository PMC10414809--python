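"""Pairwise Markov network (binary MRF) over species occupancy.

The model assigns a site with covariate vector x and occupancy vector y
the unnormalized log-probability

    sum_i (alpha_i . x) y_i  +  sum_{i<j} beta_ij y_i y_j

where ``alpha`` captures the direct effect of environmental factors or
microhabitats on each species and ``beta`` the conditional pairwise
association between species.  The pairwise sum runs over unordered pairs
(i < j): there is a single, symmetric link per species pair, so fitted
beta values are directly interpretable as link weights.

Exact operations (partition function, likelihood, configuration table)
enumerate all 2^S occupancy configurations and therefore refuse to run
above :data:`ENUMERATION_LIMIT` species.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .community import CommunityMatrix, CovariateMatrix

__all__ = [
    "ENUMERATION_LIMIT",
    "MarkovNetworkParams",
    "enumerate_configurations",
    "log_potential",
    "log_partition",
    "log_likelihood",
    "configuration_probabilities",
]

#: Hard cap on exhaustive 2^S enumeration; above this, exact operations
#: raise rather than silently approximate.
ENUMERATION_LIMIT = 20


@dataclass
class MarkovNetworkParams:
    """Markov network parameters: alpha (S x F) and symmetric beta (S x S).

    ``beta`` must be exactly symmetric with a zero diagonal; intraspecific
    effects are not part of the occupancy model (they become diagonal
    self-regulation at the dynamics level).
    """

    alpha: np.ndarray
    beta: np.ndarray
    species_names: list
    factor_names: list

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        self.species_names = [str(s) for s in self.species_names]
        self.factor_names = [str(f) for f in self.factor_names]
        S, F = len(self.species_names), len(self.factor_names)
        if self.alpha.shape != (S, F):
            raise ValueError(f"alpha shape {self.alpha.shape} != ({S}, {F})")
        if self.beta.shape != (S, S):
            raise ValueError(f"beta shape {self.beta.shape} != ({S}, {S})")
        finite = np.isfinite(self.beta)
        if not np.array_equal(
            np.where(finite, self.beta, 0.0), np.where(finite.T, self.beta.T, 0.0)
        ):
            raise ValueError("beta must be symmetric")
        diag = np.diagonal(self.beta)
        if np.any(diag[np.isfinite(diag)] != 0):
            raise ValueError("beta must have zero diagonal")

    @property
    def n_species(self) -> int:
        return len(self.species_names)

    @property
    def n_factors(self) -> int:
        return len(self.factor_names)


def enumerate_configurations(n_species: int) -> np.ndarray:
    """All 2^S binary occupancy configurations, shape ``(2^S, S)``.

    Species index 0 is the least-significant bit of the row index, fixing
    a deterministic iteration order.
    """
    if n_species > ENUMERATION_LIMIT:
        raise ValueError(
            f"{n_species} species exceeds the enumeration limit "
            f"({ENUMERATION_LIMIT}); use pseudolikelihood instead"
        )
    idx = np.arange(2**n_species, dtype=np.int64)
    return ((idx[:, None] >> np.arange(n_species)) & 1).astype(np.int8)


def _check_vectors(y, x, params: MarkovNetworkParams):
    y = np.asarray(y)
    x = np.asarray(x, dtype=float)
    if y.shape != (params.n_species,):
        raise ValueError(f"y has shape {y.shape}, expected ({params.n_species},)")
    if x.shape != (params.n_factors,):
        raise ValueError(f"x has shape {x.shape}, expected ({params.n_factors},)")
    return y, x


def log_potential(y, x, params: MarkovNetworkParams) -> float:
    """Unnormalized log-probability of occupancy ``y`` given covariates ``x``."""
    y, x = _check_vectors(y, x, params)
    linear = float((params.alpha @ x) @ y)
    pair = 0.5 * float(y @ params.beta @ y)  # beta symmetric, zero diagonal
    return linear + pair


def _log_weights(x: np.ndarray, params: MarkovNetworkParams) -> np.ndarray:
    """Log-potential of every configuration for one covariate vector."""
    configs = enumerate_configurations(params.n_species).astype(float)
    field = params.alpha @ x
    return configs @ field + 0.5 * np.einsum("ci,ij,cj->c", configs, params.beta, configs)


def log_partition(x, params: MarkovNetworkParams) -> float:
    """Log of the site-specific partition function (sum over 2^S states)."""
    x = np.asarray(x, dtype=float)
    if x.shape != (params.n_factors,):
        raise ValueError(f"x has shape {x.shape}, expected ({params.n_factors},)")
    return float(logsumexp(_log_weights(x, params)))


def log_likelihood(
    data: CommunityMatrix, covars: CovariateMatrix, params: MarkovNetworkParams
) -> float:
    """Exact log-likelihood of occurrence data: sum over sites of
    ``log_potential - log_partition``.  Always <= 0."""
    if data.mode != "occurrence":
        raise ValueError(
            "exact likelihood requires occurrence data; use the abundance "
            "fit (fit_abundance) for count matrices"
        )
    cov = covars.aligned_to(data.site_ids)
    Y = data.values.astype(float)
    X = cov.values
    if Y.shape[1] != params.n_species or X.shape[1] != params.n_factors:
        raise ValueError("data/covariate dimensions do not match params")
    # potential term, all sites at once
    total = float(np.sum((X @ params.alpha.T) * Y)) + 0.5 * float(
        np.einsum("si,ij,sj->", Y, params.beta, Y)
    )
    # partition term, grouped by unique covariate rows
    uniq, inverse, counts = np.unique(X, axis=0, return_inverse=True, return_counts=True)
    for u, c in zip(uniq, counts):
        total -= c * log_partition(u, params)
    return total


def configuration_probabilities(x, params: MarkovNetworkParams):
    """Probability table over all 2^S occupancy configurations.

    Returns a pandas DataFrame with one 0/1 column per species plus a
    ``probability`` column summing to 1.
    """
    import pandas as pd

    x = np.asarray(x, dtype=float)
    if x.shape != (params.n_factors,):
        raise ValueError(f"x has shape {x.shape}, expected ({params.n_factors},)")
    lw = _log_weights(x, params)
    probs = np.exp(lw - logsumexp(lw))
    configs = enumerate_configurations(params.n_species)
    df = pd.DataFrame(configs, columns=params.species_names)
    df["probability"] = probs
    return df


def configuration_distribution(x, params: MarkovNetworkParams):
    """(configs, probabilities) arrays — fast path used internally."""
    x = np.asarray(x, dtype=float)
    lw = _log_weights(x, params)
    return enumerate_configurations(params.n_species), np.exp(lw - logsumexp(lw))
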