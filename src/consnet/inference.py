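"""Estimation of Markov network parameters from community matrices.

Three routes:

* :func:`fit_exact` — maximum likelihood with the exact partition
  function (exhaustive 2^S enumeration, species pools up to the
  enumeration limit).  The gradient is the classic exponential-family
  difference *expected minus observed sufficient statistics*, so a
  converged fit satisfies moment matching by construction.
* :func:`fit_pseudolikelihood` — one conditional logistic regression per
  species (response: its occupancy; predictors: covariates plus every
  other species' occupancy), with the two directed pair coefficients
  averaged into a symmetric beta.  Scales to any pool size.
* :func:`fit_abundance` — node-conditional Poisson or negative-binomial
  log-link regressions for count matrices.

A small ridge penalty (default 1e-3) is placed on beta to stabilise
sparse co-occurrence tables; alpha covariate effects are unpenalised.
Species present everywhere or nowhere carry no association information
and are excluded from beta estimation (their rows are NaN-marked).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logsumexp

from .community import CommunityMatrix, CovariateMatrix
from .mrf import (
    ENUMERATION_LIMIT,
    MarkovNetworkParams,
    enumerate_configurations,
)

__all__ = [
    "FitResult",
    "fit_exact",
    "fit_pseudolikelihood",
    "fit_abundance",
    "observed_statistics",
    "expected_statistics",
]

DEFAULT_PENALTY = 1e-3


@dataclass
class FitResult:
    """Outcome of a Markov network fit."""

    params: MarkovNetworkParams
    method: str  # exact_ml | pseudolikelihood | poisson | negbin
    converged: bool
    final_objective: float
    n_iterations: int
    standard_errors: tuple[np.ndarray, np.ndarray] | None = None
    warnings: list = field(default_factory=list)
    extras: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# sufficient statistics (exact ML)
# ---------------------------------------------------------------------------

def _triu_indices(S: int):
    return np.triu_indices(S, k=1)


def observed_statistics(data: CommunityMatrix, covars: CovariateMatrix):
    """Observed sufficient statistics: covariate-weighted occurrences
    (S x F) and pairwise co-occurrence counts (S x S, symmetric)."""
    cov = covars.aligned_to(data.site_ids)
    Y = data.values.astype(float)
    t_alpha = Y.T @ cov.values
    t_beta = Y.T @ Y
    np.fill_diagonal(t_beta, 0.0)
    return t_alpha, t_beta


def expected_statistics(covars: CovariateMatrix, params: MarkovNetworkParams):
    """Model-expected sufficient statistics summed over sites."""
    configs = enumerate_configurations(params.n_species).astype(float)
    pair_term = 0.5 * np.einsum("ci,ij,cj->c", configs, params.beta, configs)
    uniq, counts = np.unique(covars.values, axis=0, return_counts=True)
    S, F = params.n_species, params.n_factors
    e_alpha = np.zeros((S, F))
    e_beta = np.zeros((S, S))
    for x, c in zip(uniq, counts):
        lw = configs @ (params.alpha @ x) + pair_term
        p = np.exp(lw - logsumexp(lw))
        mu = configs.T @ p
        second = (configs * p[:, None]).T @ configs
        e_alpha += c * np.outer(mu, x)
        e_beta += c * second
    np.fill_diagonal(e_beta, 0.0)
    return e_alpha, e_beta


def _degenerate_species(data: CommunityMatrix) -> np.ndarray:
    prev = (data.values > 0).mean(axis=0)
    return (prev == 0.0) | (prev == 1.0)


def fit_exact(
    data: CommunityMatrix,
    covars: CovariateMatrix,
    penalty: float = DEFAULT_PENALTY,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> FitResult:
    """Exact maximum likelihood (quasi-Newton on the penalized objective).

    Requires occurrence data and at most :data:`ENUMERATION_LIMIT`
    species.  At convergence, observed sufficient statistics match their
    model expectations to within ``tol`` (up to the penalty gradient).
    Degenerate data (a species always or never present) trigger a
    warning and a strongly penalized fit rather than an exception.
    """
    if data.mode != "occurrence":
        raise ValueError("fit_exact requires occurrence data; use fit_abundance for counts")
    S = data.n_species
    if S > ENUMERATION_LIMIT:
        raise ValueError(
            f"{S} species exceeds the enumeration limit ({ENUMERATION_LIMIT}); "
            "use fit_pseudolikelihood"
        )
    if data.n_sites < 2:
        raise ValueError("need at least 2 sites")
    cov = covars.aligned_to(data.site_ids)
    F = cov.n_factors
    warns: list[str] = []

    t_alpha, t_beta = observed_statistics(data, cov)
    iu, ju = _triu_indices(S)
    t_beta_u = t_beta[iu, ju]

    configs = enumerate_configurations(S).astype(float)
    uniq, counts = np.unique(cov.values, axis=0, return_counts=True)

    degenerate = _degenerate_species(data)
    # ridge: default on beta; heavy ridge on anything touching a degenerate species
    pen_alpha = np.zeros((S, F))
    pen_beta = np.full(iu.shape, penalty)
    if degenerate.any():
        names = [data.species_names[i] for i in np.where(degenerate)[0]]
        warns.append(
            f"species always or never present ({', '.join(names)}); "
            "their parameters are strongly ridge-penalized"
        )
        warnings.warn(warns[-1])
        pen_alpha[degenerate, :] = 1.0
        pen_beta[degenerate[iu] | degenerate[ju]] = 1.0

    n_alpha = S * F

    def unpack(theta):
        alpha = theta[:n_alpha].reshape(S, F)
        beta = np.zeros((S, S))
        beta[iu, ju] = theta[n_alpha:]
        beta += beta.T
        return alpha, beta

    n = float(data.n_sites)

    def objective(theta):
        # per-site mean of the penalized negative log-likelihood, so the
        # gradient (= expected minus observed frequencies) is O(1) and the
        # convergence tolerance does not depend on sample size
        alpha, beta = unpack(theta)
        pair_term = 0.5 * np.einsum("ci,ij,cj->c", configs, beta, configs)
        nll = -(np.sum(alpha * t_alpha) + np.dot(theta[n_alpha:], t_beta_u))
        e_alpha = np.zeros((S, F))
        e_second = np.zeros((S, S))
        for x, c in zip(uniq, counts):
            lw = configs @ (alpha @ x) + pair_term
            lz = logsumexp(lw)
            nll += c * lz
            p = np.exp(lw - lz)
            mu = configs.T @ p
            e_alpha += c * np.outer(mu, x)
            e_second += c * (configs * p[:, None]).T @ configs
        g_alpha = e_alpha - t_alpha + pen_alpha * alpha
        g_beta = e_second[iu, ju] - t_beta_u + pen_beta * theta[n_alpha:]
        nll += 0.5 * np.sum(pen_alpha * alpha**2) + 0.5 * np.sum(
            pen_beta * theta[n_alpha:] ** 2
        )
        return nll / n, np.concatenate([g_alpha.ravel(), g_beta]) / n

    theta0 = np.zeros(n_alpha + iu.size)
    res = minimize(
        objective,
        theta0,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "gtol": tol * 0.1, "ftol": 1e-15},
    )
    _, grad = objective(res.x)
    converged = bool(np.max(np.abs(grad)) <= tol)
    alpha, beta = unpack(res.x)
    params = MarkovNetworkParams(alpha, beta, data.species_names, cov.factor_names)
    return FitResult(
        params=params,
        method="exact_ml",
        converged=converged,
        final_objective=-float(res.fun) * n,
        n_iterations=int(res.nit),
        warnings=warns,
        extras={"penalty": penalty, "grad_inf_norm": float(np.max(np.abs(grad))),
                "degenerate_species": [data.species_names[i] for i in np.where(degenerate)[0]]},
    )


# ---------------------------------------------------------------------------
# penalized logistic Newton solver (node-conditional models)
# ---------------------------------------------------------------------------

def _ridge_logistic(X, y, pen, tol=1e-8, max_iter=100):
    """Newton–Raphson for a logistic regression with per-coefficient
    ridge weights ``pen`` (0 = unpenalized).  Returns (w, cov, converged,
    n_iter, loglik)."""
    n, p = X.shape
    w = np.zeros(p)
    pen = np.asarray(pen, dtype=float)

    def negll(w):
        eta = X @ w
        return -(y @ eta - np.logaddexp(0.0, eta).sum()) + 0.5 * np.sum(pen * w**2)

    f = negll(w)
    converged = False
    H = np.eye(p)
    for it in range(1, max_iter + 1):
        mu = expit(X @ w)
        g = X.T @ (mu - y) + pen * w
        if np.max(np.abs(g)) <= tol * max(1.0, n * 1e-3):
            converged = True
            break
        W = mu * (1.0 - mu)
        H = X.T @ (X * W[:, None]) + np.diag(pen + 1e-10)
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, g, rcond=None)[0]
        # backtracking line search
        t = 1.0
        for _ in range(40):
            f_new = negll(w - t * step)
            if f_new < f:
                break
            t *= 0.5
        else:
            converged = np.max(np.abs(g)) <= 1e-4 * max(1.0, n * 1e-3)
            break
        w = w - t * step
        f = f_new
    mu = expit(X @ w)
    W = mu * (1.0 - mu)
    H = X.T @ (X * W[:, None]) + np.diag(pen + 1e-10)
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.full((p, p), np.nan)
    eta = X @ w
    ll = float(y @ eta - np.logaddexp(0.0, eta).sum())
    return w, cov, converged, it, ll


def fit_pseudolikelihood(
    data: CommunityMatrix,
    covars: CovariateMatrix,
    penalty: float = DEFAULT_PENALTY,
) -> FitResult:
    """Pseudolikelihood fit: per-species conditional logistic models.

    For species i the conditional log-odds of presence are
    ``alpha_i . x + sum_{j != i} beta_ij y_j``; each node model is fitted
    separately and the two directed estimates of each pair are averaged
    (beta is symmetric by definition).  Perfect separation in a node
    model triggers a ridge-penalized refit with a warning.
    """
    if data.mode != "occurrence":
        raise ValueError("fit_pseudolikelihood requires occurrence data")
    S = data.n_species
    if S < 2:
        raise ValueError("need at least 2 species")
    cov = covars.aligned_to(data.site_ids)
    X = cov.values
    Y = data.values.astype(float)
    F = cov.n_factors
    warns: list[str] = []

    degenerate = _degenerate_species(data)
    active = np.where(~degenerate)[0]
    if degenerate.any():
        names = [data.species_names[i] for i in np.where(degenerate)[0]]
        warns.append(
            f"species always or never present ({', '.join(names)}) excluded "
            "from estimation; their parameter rows are NaN"
        )
        warnings.warn(warns[-1])

    alpha = np.full((S, F), np.nan)
    alpha_se = np.full((S, F), np.nan)
    beta_dir = np.full((S, S), np.nan)  # directed coefficients j -> effect on i
    beta_var = np.full((S, S), np.nan)
    all_ok = True
    total_ll = 0.0
    total_iter = 0

    for i in active:
        others = active[active != i]
        design = np.hstack([X, Y[:, others]])
        pen = np.concatenate([np.zeros(F), np.full(others.size, penalty)])
        w, covw, ok, nit, ll = _ridge_logistic(design, Y[:, i], pen)
        if not ok or np.max(np.abs(w)) > 15.0:
            # likely perfect separation: refit with ridge on everything
            pen_all = np.full(design.shape[1], max(penalty, 1e-2))
            w, covw, ok, nit, ll = _ridge_logistic(design, Y[:, i], pen_all)
            warns.append(
                f"node model for {data.species_names[i]!r} showed separation; "
                "refitted with ridge penalty on all coefficients"
            )
            warnings.warn(warns[-1])
        all_ok &= ok
        total_ll += ll
        total_iter += nit
        alpha[i] = w[:F]
        alpha_se[i] = np.sqrt(np.maximum(np.diag(covw)[:F], 0.0))
        beta_dir[i, others] = w[F:]
        beta_var[i, others] = np.maximum(np.diag(covw)[F:], 0.0)

    beta = 0.5 * (beta_dir + beta_dir.T)
    beta_se = 0.5 * np.sqrt(beta_var + beta_var.T)
    np.fill_diagonal(beta, 0.0)
    np.fill_diagonal(beta_se, 0.0)
    beta[degenerate, :] = np.nan
    beta[:, degenerate] = np.nan
    np.fill_diagonal(beta, 0.0)

    params = MarkovNetworkParams(alpha, beta, data.species_names, cov.factor_names)
    return FitResult(
        params=params,
        method="pseudolikelihood",
        converged=bool(all_ok),
        final_objective=total_ll,
        n_iterations=total_iter,
        standard_errors=(alpha_se, beta_se),
        warnings=warns,
        extras={"penalty": penalty,
                "degenerate_species": [data.species_names[i] for i in np.where(degenerate)[0]]},
    )


# ---------------------------------------------------------------------------
# abundance (count) variant
# ---------------------------------------------------------------------------

def fit_abundance(
    data: CommunityMatrix,
    covars: CovariateMatrix,
    family: str = "poisson",
) -> FitResult:
    """Node-conditional count regressions (log link) for abundance data.

    Each species' counts are regressed on the covariates and the raw
    counts of every other species; directed pair coefficients are
    averaged into a symmetric beta.  ``family="negbin"`` additionally
    estimates one dispersion parameter per species.

    Positive conditional associations under the Poisson family are
    reported with a warning: a joint Poisson Markov field with positive
    pair terms is not normalizable, so estimates are to be read as
    conditional associations, not joint-model parameters.
    """
    import statsmodels.api as sm

    if data.mode != "abundance":
        raise ValueError("fit_abundance requires abundance data")
    if family not in ("poisson", "negbin"):
        raise ValueError(f"unknown family {family!r}")
    S = data.n_species
    cov = covars.aligned_to(data.site_ids)
    X = cov.values
    Y = data.values.astype(float)
    F = cov.n_factors
    warns: list[str] = []

    allzero = Y.sum(axis=0) == 0
    active = np.where(~allzero)[0]
    if allzero.any():
        names = [data.species_names[i] for i in np.where(allzero)[0]]
        warns.append(f"all-zero species dropped from estimation: {', '.join(names)}")
        warnings.warn(warns[-1])

    alpha = np.full((S, F), np.nan)
    alpha_se = np.full((S, F), np.nan)
    beta_dir = np.full((S, S), np.nan)
    beta_var = np.full((S, S), np.nan)
    dispersion = np.full(S, np.nan)
    all_ok = True
    total_ll = 0.0
    total_iter = 0
    n_failed = 0

    for i in active:
        others = active[active != i]
        design = np.hstack([X, Y[:, others]])
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                if family == "poisson":
                    model = sm.GLM(Y[:, i], design, family=sm.families.Poisson())
                    fit = model.fit(maxiter=200)
                    ok = True
                    nit = int(getattr(fit, "fit_history", {}).get("iteration", 0) or 0)
                else:
                    model = sm.NegativeBinomial(Y[:, i], design)
                    fit = model.fit(disp=0, maxiter=500)
                    ok = bool(fit.mle_retvals.get("converged", True))
                    nit = int(fit.mle_retvals.get("iterations", 0) or 0)
                    dispersion[i] = float(fit.params[-1])
        except Exception as exc:  # pragma: no cover - defensive
            n_failed += 1
            all_ok = False
            warns.append(f"node model for {data.species_names[i]!r} failed: {exc}")
            warnings.warn(warns[-1])
            continue
        all_ok &= ok
        total_ll += float(fit.llf)
        total_iter += nit
        coefs = np.asarray(fit.params[: F + others.size])
        ses = np.asarray(fit.bse[: F + others.size])
        alpha[i] = coefs[:F]
        alpha_se[i] = ses[:F]
        beta_dir[i, others] = coefs[F:]
        beta_var[i, others] = ses[F:] ** 2

    beta = 0.5 * (beta_dir + beta_dir.T)
    beta_se = 0.5 * np.sqrt(beta_var + beta_var.T)
    np.fill_diagonal(beta, 0.0)
    np.fill_diagonal(beta_se, 0.0)

    if family == "poisson" and np.any(np.nan_to_num(beta) > 0):
        warns.append(
            "positive pairwise associations under family='poisson': interpret "
            "as conditional associations (the joint Poisson field with "
            "positive pair terms is not normalizable)"
        )
        warnings.warn(warns[-1])

    params = MarkovNetworkParams(alpha, beta, data.species_names, cov.factor_names)
    return FitResult(
        params=params,
        method=family,
        converged=bool(all_ok),
        final_objective=total_ll,
        n_iterations=total_iter,
        standard_errors=(alpha_se, beta_se),
        warnings=warns,
        extras={
            "dispersion": dispersion,
            "dropped_species": [data.species_names[i] for i in np.where(allzero)[0]],
            "n_failed_nodes": n_failed,
        },
    )
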