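"""Permutation null models for inferred associations.

Inferred parameters are only hypotheses about interactions; before a
link enters a constructive network it is screened against a null model.
Two pairwise nulls are provided, both stratified by environmental
context so the prevalence structure that alpha absorbs is held fixed:
a within-stratum column shuffle (exact test of independence given the
covariates, the screening default) and the classic curveball
*fixed-fixed* null, which additionally preserves each site's richness
(every row and column sum of the matrix is conserved exactly).

Covariate (alpha) effects cannot be screened this way because the
permutation leaves covariates untouched; they are screened instead by
permuting the assignment of covariate rows to sites.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .community import CommunityMatrix, CovariateMatrix
from . import inference

__all__ = [
    "curveball_trades",
    "permute_fixed_margins",
    "permute_within_strata",
    "NullScreenResult",
    "AlphaScreenResult",
    "screen_beta",
    "screen_alpha",
]


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment (flat array of p-values)."""
    from statsmodels.stats.multitest import multipletests

    mask = np.isfinite(p)
    q = np.full_like(p, np.nan, dtype=float)
    if mask.sum():
        q[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return q


def curveball_trades(rows: list, n_trades: int, rng: np.random.Generator) -> None:
    """Apply curveball trades in place.

    ``rows`` is a list of Python sets (species indices present per site).
    Each trade picks two sites and randomly re-partitions the species
    that occur in exactly one of them, preserving both matrix margins.
    """
    n = len(rows)
    if n < 2:
        return
    pairs = rng.integers(0, n, size=(n_trades, 2))
    for a, b in pairs:
        if a == b:
            continue
        ra, rb = rows[a], rows[b]
        a_only = list(ra - rb)
        b_only = list(rb - ra)
        if not a_only or not b_only:
            continue
        pool = a_only + b_only
        rng.shuffle(pool)
        take_a = set(pool[: len(a_only)])
        shared = ra & rb
        rows[a] = shared | take_a
        rows[b] = shared | (set(pool) - take_a)


def _has_trade(rows: list) -> bool:
    """True when some pair of sites admits a non-trivial trade (i.e. the
    margin class contains more than one matrix)."""
    n = len(rows)
    for i in range(n):
        ri = rows[i]
        for j in range(i + 1, n):
            if (ri - rows[j]) and (rows[j] - ri):
                return True
    return False


def permute_fixed_margins(
    data: CommunityMatrix,
    n_permutations: int,
    seed: int | None = None,
    trades_per_draw: int | None = None,
    strata=None,
) -> list:
    """Fixed-fixed null matrices via the curveball algorithm.

    Returns ``n_permutations`` matrices, each preserving every row and
    column sum of ``data`` exactly.  Successive draws are separated by
    ``trades_per_draw`` curveball trades (default: 5x the number of
    presences, which mixes the chain well past its empirical
    autocorrelation time).  A matrix whose margins admit a unique fill
    is returned unchanged with a warning.

    ``strata`` (optional, one label per site) restricts trades to sites
    within the same stratum, additionally preserving per-stratum species
    prevalences.  Screening against covariate-structured data uses the
    unique covariate rows as strata: presences are then shuffled only
    among environmentally identical sites, so the null ensemble is
    exchangeable with the observed matrix when species occur
    independently given the covariates.
    """
    if data.mode != "occurrence":
        raise ValueError("fixed-margin permutation requires occurrence data")
    arr = data.values
    rng = np.random.default_rng(seed)

    if strata is None:
        groups = [np.arange(data.n_sites)]
    else:
        strata = np.asarray(strata)
        if strata.shape[0] != data.n_sites:
            raise ValueError("strata must have one label per site")
        _, inverse = np.unique(strata, axis=0, return_inverse=True)
        groups = [np.flatnonzero(inverse == g) for g in range(inverse.max() + 1)]

    group_rows = []
    tradeable = False
    for idx in groups:
        rows = [set(np.flatnonzero(arr[i])) for i in idx]
        ones = int(arr[idx].sum())
        trades = trades_per_draw if trades_per_draw is not None else max(1, 5 * ones)
        has = _has_trade(rows)
        tradeable |= has
        group_rows.append((idx, rows, trades, has))

    if not tradeable:
        warnings.warn("matrix margins admit a unique fill; permutations equal the input")
        return [
            CommunityMatrix(data.site_ids, data.species_names, arr.copy(), "occurrence")
            for _ in range(n_permutations)
        ]

    out = []
    for k in range(n_permutations):
        mat = np.zeros_like(arr)
        for idx, rows, trades, has in group_rows:
            if has:
                curveball_trades(rows, trades, rng)
            for i, r in zip(idx, rows):
                if r:
                    mat[i, list(r)] = 1
        out.append(CommunityMatrix(data.site_ids, data.species_names, mat, "occurrence"))
    return out


def permute_within_strata(
    data: CommunityMatrix,
    n_permutations: int,
    strata,
    seed: int | None = None,
) -> list:
    """Independence null: shuffle each species column within strata.

    Every species' presences are reassigned uniformly at random among
    the sites of each environmental stratum, independently per species.
    Per-stratum (hence global) species prevalences are preserved
    exactly; site richness is not.  When species occur independently
    given the covariates, the observed matrix is exchangeable with
    these draws, making downstream permutation p-values exact.
    """
    if data.mode != "occurrence":
        raise ValueError("column permutation requires occurrence data")
    strata = np.asarray(strata)
    if strata.shape[0] != data.n_sites:
        raise ValueError("strata must have one label per site")
    _, inverse = np.unique(strata, axis=0, return_inverse=True)
    groups = [np.flatnonzero(inverse == g) for g in range(inverse.max() + 1)]
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_permutations):
        m = data.values.copy()
        for idx in groups:
            for j in range(data.n_species):
                m[idx, j] = m[idx[rng.permutation(idx.size)], j]
        out.append(CommunityMatrix(data.site_ids, data.species_names, m, "occurrence"))
    return out


@dataclass
class NullScreenResult:
    """Null-model screen of the pairwise association matrix."""

    species_names: list
    observed_beta: np.ndarray
    null_mean: np.ndarray
    null_sd: np.ndarray
    z_scores: np.ndarray
    p_values: np.ndarray
    q_values: np.ndarray
    n_permutations: int
    n_failed: int
    method: str
    seed: int | None
    unreliable: bool = False
    null_model: str = "stratified_column"

    def significant(self, fdr: float = 0.05) -> np.ndarray:
        """Boolean matrix of pairs with q < fdr."""
        with np.errstate(invalid="ignore"):
            return np.nan_to_num(self.q_values, nan=1.0) < fdr

    def to_frame(self):
        """Long-format table: one row per unordered species pair."""
        import pandas as pd

        iu, ju = np.triu_indices(len(self.species_names), k=1)
        return pd.DataFrame(
            {
                "species_i": [self.species_names[i] for i in iu],
                "species_j": [self.species_names[j] for j in ju],
                "beta_obs": self.observed_beta[iu, ju],
                "null_mean": self.null_mean[iu, ju],
                "null_sd": self.null_sd[iu, ju],
                "z": self.z_scores[iu, ju],
                "p": self.p_values[iu, ju],
                "q": self.q_values[iu, ju],
                "significant": self.significant()[iu, ju],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class AlphaScreenResult:
    """Site-label permutation screen of species-covariate effects."""

    species_names: list
    factor_names: list
    observed_alpha: np.ndarray
    null_mean: np.ndarray
    null_sd: np.ndarray
    z_scores: np.ndarray
    p_values: np.ndarray
    q_values: np.ndarray
    n_permutations: int
    n_failed: int
    method: str
    seed: int | None
    unreliable: bool = False

    def significant(self, fdr: float = 0.05) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.nan_to_num(self.q_values, nan=1.0) < fdr


def _fit_beta(data, covars, fit_method, penalty):
    if fit_method == "exact_ml":
        res = inference.fit_exact(data, covars, penalty=penalty)
    elif fit_method == "pseudolikelihood":
        res = inference.fit_pseudolikelihood(data, covars, penalty=penalty)
    else:
        raise ValueError(f"unknown fit_method {fit_method!r}")
    return res


def _permutation_stats(obs, null_stack):
    """z, p (two-sided, +1-corrected) and BH q from a null ensemble.

    ``null_stack`` has shape (m, ...) matching ``obs``.  The p-value
    counts null draws whose deviation from the null mean is at least as
    large as the observed deviation; its lower bound is 1/(m+1).
    """
    m = null_stack.shape[0]
    mean = np.nanmean(null_stack, axis=0)
    sd = np.nanstd(null_stack, axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (obs - mean) / sd
    dev_obs = np.abs(obs - mean)
    dev_null = np.abs(null_stack - mean[None])
    b = np.nansum(dev_null >= dev_obs[None] - 1e-12, axis=0)
    p = (b + 1.0) / (m + 1.0)
    p = np.where(np.isfinite(obs), p, np.nan)
    return mean, sd, z, p


def screen_beta(
    data: CommunityMatrix,
    covars: CovariateMatrix,
    fit_method: str = "pseudolikelihood",
    n_permutations: int = 199,
    fdr: float = 0.05,
    seed: int | None = None,
    penalty: float = inference.DEFAULT_PENALTY,
    null_model: str = "stratified_column",
) -> NullScreenResult:
    """Screen fitted beta against a permutation null.

    The model is refitted on each permuted matrix (covariates
    unchanged); per pair, z-scores, two-sided permutation p-values with
    the +1 correction, and BH-adjusted q-values over the S(S-1)/2
    unordered pairs are reported.  Permutations whose refit fails are
    dropped and counted; if more than 10% fail the result is flagged
    unreliable.

    Two null models are available, both stratified by the unique
    covariate rows so that per-stratum species prevalences (and hence
    the prevalence structure alpha accounts for) are preserved exactly:

    * ``"stratified_column"`` (default) — each species' presences are
      shuffled independently among the sites of its stratum.  This is
      an exact test of pairwise independence given the covariates.
    * ``"fixed_fixed"`` — curveball trades within strata, additionally
      preserving every site's richness.  Conditioning on richness makes
      the per-pair null distributions depend on whatever true
      associations shaped the margins, which blunts per-pair
      specificity when a strong association exists elsewhere in the
      pool; it is retained for comparison with classic fixed-fixed
      co-occurrence screens.
    """
    if n_permutations < 99:
        raise ValueError("need n_permutations >= 99")
    obs_fit = _fit_beta(data, covars, fit_method, penalty)
    obs_beta = obs_fit.params.beta
    S = data.n_species

    strata = covars.aligned_to(data.site_ids).values
    if null_model == "stratified_column":
        perms = permute_within_strata(data, n_permutations, strata, seed=seed)
    elif null_model == "fixed_fixed":
        perms = permute_fixed_margins(data, n_permutations, seed=seed, strata=strata)
    else:
        raise ValueError(f"unknown null_model {null_model!r}")
    null = np.full((n_permutations, S, S), np.nan)
    n_failed = 0
    for k, perm in enumerate(perms):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = _fit_beta(perm, covars, fit_method, penalty)
            if not fit.converged:
                n_failed += 1
                continue
            null[k] = fit.params.beta
        except Exception:
            n_failed += 1

    ok = ~np.all(np.isnan(null.reshape(n_permutations, -1)), axis=1)
    null = null[ok]
    mean, sd, z, p = _permutation_stats(obs_beta, null)
    iu, ju = np.triu_indices(S, k=1)
    q_flat = _bh_adjust(p[iu, ju])
    q = np.full_like(p, np.nan)
    q[iu, ju] = q_flat
    q[ju, iu] = q_flat
    np.fill_diagonal(q, np.nan)
    unreliable = n_failed > 0.1 * n_permutations
    if unreliable:
        warnings.warn(f"{n_failed}/{n_permutations} permutation refits failed; "
                      "screen flagged unreliable")
    return NullScreenResult(
        species_names=data.species_names,
        observed_beta=obs_beta,
        null_mean=mean,
        null_sd=sd,
        z_scores=z,
        p_values=p,
        q_values=q,
        n_permutations=int(null.shape[0]),
        n_failed=n_failed,
        method=fit_method,
        seed=seed,
        unreliable=unreliable,
        null_model=null_model,
    )


def screen_alpha(
    data: CommunityMatrix,
    covars: CovariateMatrix,
    fit_method: str = "pseudolikelihood",
    n_permutations: int = 199,
    fdr: float = 0.05,
    seed: int | None = None,
    penalty: float = inference.DEFAULT_PENALTY,
) -> AlphaScreenResult:
    """Screen species-covariate effects by permuting covariate rows.

    Fixed-margin permutation cannot test alpha (covariates are left
    untouched), so the null here shuffles which covariate row belongs to
    which site and refits; BH adjustment runs over all species x factor
    cells.
    """
    if n_permutations < 99:
        raise ValueError("need n_permutations >= 99")
    obs_fit = _fit_beta(data, covars, fit_method, penalty)
    obs_alpha = obs_fit.params.alpha
    S, F = obs_alpha.shape
    rng = np.random.default_rng(seed)
    cov_aligned = covars.aligned_to(data.site_ids)

    null = np.full((n_permutations, S, F), np.nan)
    n_failed = 0
    for k in range(n_permutations):
        order = rng.permutation(data.n_sites)
        shuffled = CovariateMatrix(
            data.site_ids, cov_aligned.factor_names, cov_aligned.values[order]
        )
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = _fit_beta(data, shuffled, fit_method, penalty)
            if not fit.converged:
                n_failed += 1
                continue
            null[k] = fit.params.alpha
        except Exception:
            n_failed += 1

    ok = ~np.all(np.isnan(null.reshape(n_permutations, -1)), axis=1)
    null = null[ok]
    mean, sd, z, p = _permutation_stats(obs_alpha, null)
    q = _bh_adjust(p.ravel()).reshape(p.shape)
    unreliable = n_failed > 0.1 * n_permutations
    if unreliable:
        warnings.warn(f"{n_failed}/{n_permutations} permutation refits failed; "
                      "screen flagged unreliable")
    return AlphaScreenResult(
        species_names=data.species_names,
        factor_names=cov_aligned.factor_names,
        observed_alpha=obs_alpha,
        null_mean=mean,
        null_sd=sd,
        z_scores=z,
        p_values=p,
        q_values=q,
        n_permutations=int(null.shape[0]),
        n_failed=n_failed,
        method=fit_method,
        seed=seed,
        unreliable=unreliable,
    )
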