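# Methods

This note documents the models implemented in `consnet`, the defaults
they ship with, the numerical choices behind them, and what the
synthetic-data experiments do and do not demonstrate.

## The occupancy model

A community of S species observed at independent sites is modelled as a
pairwise Markov random field over binary occupancy vectors y ∈ {0,1}^S.
Given a site's covariate vector x (environmental factors and/or one-hot
microhabitat indicators), the probability of a configuration is

    p(y | x) ∝ exp( Σ_i (α_i · x) y_i  +  Σ_{i<j} β_ij y_i y_j )

* **α** (species × factors) is the direct effect of each environmental
  factor or microhabitat on each species, on the log-odds scale.
  α_if > 0 means species i is associated with factor f; α_if < 0 means
  it avoids or is suppressed by it.
* **β** (species × species, symmetric, zero diagonal) is the
  conditional pairwise association between species, after accounting
  for the environment and for all other species. A positive β_ij makes
  joint presence more likely; a negative one makes it less likely.

Two conventions matter for interpreting magnitudes:

1. **The pairwise sum runs over unordered pairs (i < j)** — no factor
   of two, no self-terms. There is a single symmetric link per species
   pair, and the fitted β_ij is exactly the weight that link carries.
2. **No implicit intercept.** α is strictly "effect of the supplied
   factors"; a baseline prevalence term is obtained by including an
   all-ones covariate column. With a full set of one-hot microhabitat
   columns (as in the nurse scenario) an intercept would be redundant
   and is omitted.

Intraspecific (β_ii) terms are not part of the occupancy model: a
binary y_i makes y_i² = y_i, so a diagonal term is not identifiable
separately from α. Self-regulation instead appears at the dynamics
level as the diagonal of the interaction matrix B.

Exact quantities (partition function, likelihood, configuration table)
enumerate all 2^S configurations and refuse to run above S = 20 rather
than silently approximate. Configurations are ordered with species 0 as
the least-significant bit, which fixes iteration order for
reproducibility.

## Estimation

**Exact maximum likelihood** (`fit_exact`, S ≤ 20). The objective is
the per-site mean penalized negative log-likelihood; its gradient is
the exponential-family difference *expected minus observed sufficient
statistic frequencies*, computed by enumerating configuration
distributions once per unique covariate row. L-BFGS-B drives the
gradient infinity-norm below 1e-6 (default), so a converged fit
satisfies moment matching — expected co-occurrence frequencies equal
empirical ones — up to the penalty gradient. A ridge penalty of 1e-3
on β (none on α) stabilises sparse co-occurrence tables; it shifts
estimates by O(penalty/n) and is a visible, documented parameter.

**Pseudolikelihood** (`fit_pseudolikelihood`, any S). One conditional
logistic regression per species: the response is the species' occupancy,
the predictors are the covariates plus every other species' occupancy.
The node models are solved by a damped Newton iteration with
per-coefficient ridge weights (β columns penalized, α columns not);
with the penalty set to zero the node estimates agree with standard
logistic ML (cross-checked against `statsmodels.Logit` in the tests).
The two directed pair coefficients are averaged — β is symmetric by
definition, and averaging (rather than max or min) is the unbiased
combination when both node models are correct. Perfect separation is
detected (non-convergence or |coefficient| > 15) and answered with a
ridge-penalized refit plus a warning.

Species present everywhere or nowhere carry no association information;
they are excluded from β estimation and their rows are NaN-marked in
the output (exact ML instead keeps them with a strong ridge, since its
joint objective cannot simply drop a node).

**Abundance data** (`fit_abundance`). Count matrices are fitted with
node-conditional log-link count regressions — Poisson GLMs or
negative-binomial ML (one dispersion per species) via statsmodels —
conditioning on the *raw* counts of the other species, then symmetrized
as above. A joint Poisson random field with positive pair terms is not
normalizable, so positive β̂ under the Poisson family triggers a
warning and should be read as a conditional association, not a joint
model parameter. Whether α and β should instead be estimated jointly
for counts is an open modelling question; the node-conditional route is
the one implemented.

## Synthetic data

`gibbs_sample` draws one occupancy configuration per site: every site
runs an independent Gibbs chain (sites are independent observations of
the community distribution), all chains advanced in lockstep with
vectorised single-species conditional updates whose log-odds are
α_i·x + Σ_{j≠i} β_ij y_j. Each site uses a fixed species update order
drawn once from the seed, avoiding order artifacts while staying
bit-for-bit reproducible. Defaults of 250 sweeps (burn-in 200) mix well
for pools up to ~20 species with |β| ≤ 2; at S = 3 and 20 000 sites the
total-variation distance between empirical and exactly enumerated
configuration distributions is below 0.02 (measured ≈ 0.003–0.008).

`make_nurse_scenario` encodes the canonical facilitation setting: two
microhabitats (under a nurse canopy vs. open ground) as one-hot
environment columns, subordinate species Sub1 and Sub2 favoured under
the nurse (α_nurse − α_open = +1.5 on the log-odds scale), Sub3
favoured in the open (−1.5), and β(Sub1, Sub2) = −1 (putative
competition between the two facilitated species). The magnitudes are
modelling choices, not field estimates: they are set so that recovery
and screening succeed from roughly 500 sites, which is a realistic
plot-count for vegetation surveys; they live in `ScenarioSpec`, not in
code.

What the generator does *not* emulate: spatial autocorrelation between
neighbouring sites, temporal turnover, detection error, and abundance
structure within occupied sites. Passing recovery tests therefore show
that the estimators invert the model they assume, on data of realistic
size — not that field co-occurrence data satisfy that model.

## Null-model screening

Fitted associations are hypotheses; before a link enters a network it
must beat a permutation null. The package screens β by refitting the
chosen model on permuted community matrices and comparing each β̂_ij
with its null ensemble: z-scores, two-sided permutation p-values with
the +1 correction ((b+1)/(m+1), so the attainable minimum is
1/(m+1)), and Benjamini–Hochberg q-values across the S(S−1)/2 pairs.

Two nulls are implemented, both stratified by the unique covariate rows
so every species' prevalence is preserved exactly *within each
environmental stratum* (and hence globally):

* **Stratified column shuffle** (default): each species' presences are
  reassigned uniformly among the sites of its stratum, independently
  per species. Under the null hypothesis that species occur
  independently given the covariates, the observed matrix is
  exchangeable with these draws, so the test is exact. Type-I
  calibration at nominal FDR 0.05 measures a false-positive pair rate
  of ≈ 0–0.005 over 20 replicates.
* **Fixed-fixed curveball**: trades within strata, additionally
  conserving site richness (all row *and* column sums). This is the
  classic co-occurrence null, but conditioning on richness couples the
  pairs: when one pair carries a strong true association, its imprint
  on the margins shifts *every* pair's null distribution (observed
  null-mean shifts of −0.3 to −0.5 in the nurse scenario), producing
  spurious flags on truly unassociated pairs. It is retained for
  comparison and for margin-conditioned questions, but it is not the
  screening default precisely because of this leakage.

α effects cannot be tested by permuting the community matrix (the
covariates are untouched), so they are screened by permuting the
assignment of covariate rows to sites and refitting.

## Network assembly

`build_network` collates screened parameters into one signed, weighted
multilayer graph: species and environment factors are nodes; α-links
connect factors to species (rendered factor → species in exports,
since the microhabitat acts on the plant); β-links are undirected with
canonical i < j ordering. A link must pass *both* filters when both are
given — significance (q < FDR) and effect size (|weight| ≥
min_weight) — because a tiny but well-resolved coefficient and a large
noisy one fail for different reasons. Zero-weight and NaN parameters
never become links. In the nurse system, "facilitation by the nurse" is
represented as a positive α-link from the nurse-microhabitat node to
the subordinate: the nurse's effect is mediated by the microhabitat it
constructs, so the environment node carries it.

## Coupled dynamics

Fitted associations can seed a dynamical model:

    dN_i/dt = N_i ( r_i + Σ_j B_ij N_j ) + (Σ_k A_ik E_k) N_i
    dE_k/dt = K_k + Σ_i γ_ki N_i

with B_ij = beta_scale · β_ij (i ≠ j), B_ii = −self_regulation, and
A = alpha_scale · α. The coupling functions are linear — the minimal
assumption — and the chosen form is recorded in `DynamicsSpec` so
saturating alternatives can be added without reshaping the equations.
The rescaling constants (defaults beta_scale = alpha_scale = 0.1,
self_regulation = 1.0) are free parameters: a statistical association
has no dynamical units, so any simulation driven by rescaled
coefficients is a scenario exploration, not a prediction.

Integration is fixed-step RK4 (default dt = 0.01) for exact
reproducibility; adaptive steppers would trade that away for speed the
problem sizes here do not need. Species below 1e-9 are clamped to zero
(extinction); a non-finite state truncates the trajectory and sets a
`diverged` flag rather than raising. Environment variables are
unbounded unless a per-factor [min, max] clip is supplied (for bounded
quantities such as moisture fraction). The integrator reproduces the
exponential, logistic and linear-drift closed forms to relative error
below 1e-6 at dt = 0.01, and halving dt moves endpoints by < 1e-5
relative.

`equilibria` solves the interior community equilibrium at fixed
environment (B N* = −(r + A E)), reports feasibility (N* > 0) and local
stability from the eigenvalues of diag(N*)·B, and flags singular B
(condition number > 1e12) instead of returning nonsense.

## Pipeline and reproducibility

`run_pipeline` chains fit → screen → network → (optional) dynamics from
a YAML config, writing per-stage artifacts and a manifest with the
config echo, seeds, SHA-256 hashes and timings. Every stochastic
routine takes an explicit seed and no global random state is used, so a
rerun with the same config and seed is byte-identical on all CSV/TSV
artifacts. CSV dialect is fixed (comma, UTF-8, "." decimal) to avoid
locale drift.

## Problem sizes used in the shipped experiments

The test-suite and acceptance-script experiments use S = 3–6 species,
500–20 000 sites, 20 replicates and 99–199 permutations. These sizes
are chosen to give the statistics stable sampling distributions (Monte
Carlo standard errors comfortably inside the asserted tolerances) while
keeping a full run in the minutes range on a single core.

## Known limitations

* Pseudolikelihood and node-conditional count fits are consistent but
  not efficient; their symmetrized β has no joint-likelihood
  interpretation at finite n.
* The screening nulls test independence given the *supplied*
  covariates; an omitted environmental gradient will surface as β
  links, which is a property of the inference problem, not of the
  implementation.
* The dynamics layer inherits the sign pattern of the fitted network
  but not its uncertainty; no error propagation from fit to trajectory
  is attempted.
* Third-order interactions, directed effects, spatial structure and
  Gaussian (continuous-response) graphical models are out of scope.
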