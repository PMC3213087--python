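# Methods

## Model

`geobma` fits geostatistical regression models with simultaneous covariate
selection.  Observations are taken at planar coordinates `s_1, …, s_n`.  Two
observation families are supported.

**Gaussian.**  The response is modelled directly as a Gaussian process with a
linear mean:

    y ~ N(X_k β_k, Σ(θ)),
    Σ(θ)_ij = σ² ρ(‖s_i − s_j‖_A) + τ² 1{i = j},

where `σ²` is the partial sill, `τ²` the nugget, and `ρ` an isotropic
correlation function (exponential by default; spherical and Matérn with fixed
smoothness are available).  Geometric anisotropy enters through the
Mahalanobis-type distance `‖h‖_A = sqrt(h'Ah)` with `A = D R D`,
`D = diag(1/d₁, 1/d₂)` holding inverse per-axis ranges and
`R = [[1, ψ], [ψ, 1]]` a correlation matrix with a single unconstrained
parameter `ψ ∈ (−1, 1)` encoding the anisotropy angle.  Placing inverse
ranges in `D` makes the isotropic limit (equal ranges, `ψ = 0`) reproduce the
textbook exponential model `exp(−h/d)`; the spherical family consequently has
support `‖h‖_A < 1` on the effective-distance scale.

**Poisson spatial GLMM.**  Counts are conditionally independent Poisson with
canonical log link over a latent Gaussian field:

    y_i | z_i ~ Poisson(exp(z_i)),    z ~ N(X_k β_k, Σ(θ)).

The Poisson observation layer takes the role of the nugget's micro-scale
variability, so the latent field is typically configured without a nugget.

**Model space.**  Each candidate model `M_k` is a binary inclusion vector γ
over the p candidate covariates.  Forced covariates (the intercept by
default) appear in every model and are excluded from the `2^p_selectable`
count.  The model prior is an independent Bernoulli product
`p(M_k) = Π_j π_j^{γ_j} (1−π_j)^{1−γ_j}` over selectable covariates, which
covers both the uniform prior (`π_j = 1/2`) and informative a-priori
weighting of individual covariates.

The inferential targets are the posterior model probability (PMP) of each
model, the posterior inclusion probability (PIP) of each covariate
`PIP_j = Σ_{k: j ∈ M_k} PMP_k`, and model-averaged coefficient posteriors,
which are spike-and-slab mixtures: a point mass `1 − PIP_j` at zero plus the
conditional posterior of `β_j` given inclusion.

## The partial-analytic reversible-jump sampler

A plain reversible-jump sampler must propose both a model and coefficients
for that model; a poor coefficient proposal stalls the chain, and each
attempt costs a dense `n × n` factorization.  Because the coefficient prior
is conjugate normal, `β_k` integrates out of the Gaussian layer in closed
form:

    p(r | M_k, θ) = N(r; X_k m_k, X_k V_k X_kᵀ + Σ(θ)),

where the Gaussian-layer response `r` is `y` for the Gaussian family and the
current latent field `z` for the Poisson family.  Model moves therefore need
no coefficient proposal at all: a covariate is chosen uniformly at random
and toggled (a symmetric discrete random walk), and the move is accepted
with probability `min{1, p(M' | r, θ) / p(M | r, θ)}`.  On acceptance the
coefficients are refreshed from their exact normal full conditional

    β_k | r, θ ~ N(Bb, B),  B = (X_kᵀΣ⁻¹X_k + V_k⁻¹)⁻¹,  b = X_kᵀΣ⁻¹r + V_k⁻¹m_k.

One sweep of the chain updates, in order: the spatial parameters
(component-wise Metropolis), the model indicator (the partial-analytic move),
the coefficients (Gibbs), and — Poisson family only — the latent field by a
whole-vector Langevin–Hastings (MALA) step

    z* = z + (h/2) ∇_z log p(z | …) + √h ε,
    ∇_z log p = (y − exp(z)) − Σ⁻¹(z − X_k β_k),

accepted with the full Metropolis–Hastings ratio including both asymmetric
proposal densities.

Conditioning the model move on the current `z` in the Poisson branch is what
makes the scheme family-agnostic: the spatial parameters and latent layer
are shared by all models, so the same analytic machinery applies unchanged.

## Priors and parameterization

All variance-like parameters are sampled on log scale.

| parameter | prior | default |
|---|---|---|
| log σ², log τ² | Normal(μ_v, 10) | μ_v = log(var(y)/2) (data heuristic) |
| log d₁, log d₂ | Normal(μ_r, 1) | μ_r = log(max distance / 2) |
| ψ | triangular `1 − |ψ|` on (−1, 1) | — |
| β | N(m, c·I) | m = ȳ for intercept-like columns, 0 for slopes; c = 100 |
| γ_j | Bernoulli(π_j) | π_j = 0.5 (configurable per covariate) |

The prior variance 10 on the log variance parameters covers several orders
of magnitude of sill and nugget around the data heuristic.  The unit
variance on log ranges deliberately concentrates prior mass below the
maximum observed inter-site distance — diffuse range priors put unrealistic
mass on ranges the data cannot inform.  The triangular prior on ψ keeps mass
away from ±1, where the anisotropy matrix approaches singularity; a uniform
prior is a one-line configuration change.  The intercept prior mean is the
response mean (Gaussian) or log mean count (Poisson); slope priors are
mean-zero on standardized covariates, with variance 100 as a vague default
for the "flat" style (smaller values give informative shrinkage).

Because the sill and nugget are strongly anti-correlated in the posterior, a
second proposal parameterization is available
(`variance_param="total_logit"`): a joint random walk on the log total
variance `log(σ² + τ²)` and the logit nugget proportion.  The Jacobian
determinant of the map from (log σ², log τ²) to these coordinates is exactly
1, so no acceptance correction is required; the two parameterizations target
the identical posterior (verified by test).

## Proposals and tuning

Default random-walk scales are 0.3 for the log variances, 0.3 for the log
ranges and half-width 0.2 for the truncated-uniform ψ proposal (the
truncation asymmetry enters the Hastings ratio).  A burn-in auto-tuner
(enabled by default) rescales each block every 100 iterations toward
acceptance 0.35 for random walks and 0.55 for MALA, and freezes all scales
at the end of burn-in, so the post-burn-in kernel is a fixed, valid MCMC
kernel.  The MALA step size starts at 0.1 when not set explicitly; on the
Poisson stream-survey scenario the tuner lands it at roughly 50% acceptance.
No thinning is applied by default; latent-field draws can be thinned when
stored.  Default chain lengths (20,000 iterations, 5,000 burn-in) are chosen
for the package's synthetic problem sizes (n of order 100–150); real
analyses warrant longer runs (chain lengths of 100,000–300,000 iterations
are typical for this model class), judged by standard ESS/trace diagnostics
on the exported draws.

## Numerical choices

- All dense solves use Cholesky factorizations; the only explicit inverse is
  of the (small, diagonal) coefficient prior covariance.
- If a covariance Cholesky fails, `1e−10 · mean(diag)` is added to the
  diagonal once; a second failure raises a descriptive degeneracy error.
  During sampling, a proposal whose covariance is degenerate is simply
  rejected.
- The latent field is guarded at `exp(30)`: simulation fails loudly above
  it, and log-target evaluations return −∞ (rejecting the proposal).
- `q = 0` (empty model) is supported as zero-mean evidence, so the
  enumeration over the model space is complete.
- With the spatial parameters fixed (and in the Gaussian family), conditional
  model posteriors are memoized per inclusion vector; the memo is invalidated
  whenever θ or z changes.

## Synthetic data

The generator draws site locations uniformly on a square (or on a lattice),
covariates as independent standard normals — standardized *exactly* to
sample mean 0 and variance 1, matching the convention of analyzing
standardized covariates — and the response through the exact model the
sampler assumes.  An optional mode draws covariates from their own Gaussian
random field, which reproduces the spurious-inclusion phenomenon where a
spatially smooth covariate proxies for unmodelled spatial correlation.

Three presets fix the study conditions:

- `lizard-like`: Gaussian, n = 149, intercept + 7 selectable covariates
  (128 models), anisotropic exponential field (ranges 2 and 3, ψ = 0.3),
  sill 1, nugget 0.25, two true effects of 0.6 and 0.5.
- `fish-like`: Poisson, n = 150 (a stand-in site count; the original survey
  size is not published), intercept + 9 selectable covariates (512 models),
  isotropic exponential field (range 2, sill 0.5, no nugget), intercept 2.0
  and effects (0.5, −0.4, 0.3) keeping counts in a realistic range.
- `tiny-enum`: Gaussian, n = 20, intercept + 3 selectable covariates — an
  8-model space small enough for exact enumeration, used to validate the
  sampler against exhaustive computation.

What passing tests on these data do **not** show: the generator draws
covariates with idealized correlation structure (independent, or a single
shared field), exactly Gaussian/Poisson responses, and a correctly specified
correlation family.  Real ecological surveys have collinear covariates,
over-dispersion, preferential sampling and misspecified covariance shapes;
performance there must be judged with the usual sensitivity analyses.

## Verification strategy

- The analytic core (integrated likelihood, conditional model posterior,
  coefficient full conditional) is checked against independent numerical
  integration: adaptive quadrature for up to two coefficients, mode-centred
  Gauss–Hermite and Sobol quasi-Monte Carlo for three.
- The sampler is checked two ways: model-visit frequencies against exact
  enumeration on the 8-model problem (total-variation distance < 0.02 at
  200,000 iterations), and a Geweke-style successive-conditional simulation
  showing the full kernel leaves the prior invariant.
- Each Metropolis block reproduces its prior marginal when the likelihood
  term is disabled (a test-harness switch, `prior_only`).
- The MALA gradient is verified against finite differences, and the update
  with its drift zeroed is verified to coincide, draw for draw, with a plain
  random-walk Metropolis chain.

## Design choices where the design was open

- **Anisotropy convention.**  `D` holds inverse ranges and ρ acts on the
  effective distance, because that convention reduces to the standard
  exponential-with-range model in the isotropic limit.  The alternative
  (ranges in `D`) only relabels `d → 1/d`.
- **Matérn smoothness** is a fixed configuration value (default 1.5), never
  sampled — it is weakly identified at these sample sizes.
- **Coefficient bookkeeping** keeps a full-length β vector with exact zeros
  for excluded covariates.  Because the partial-analytic move redraws β from
  its full conditional on every accepted model move, no birth values need to
  be remembered for re-entering covariates; the stationary distribution is
  unaffected by this convention.
- **Ratio summaries** (`coefficient_ratio_posterior`) condition on draws
  where both covariates are included and report |β_denominator| /
  |β_numerator| with the argument order explicit in the result object, since
  the direction of such ratios is otherwise ambiguous.
- **PMP normalization**: reported PMPs are raw visit fractions over visited
  models (they sum to 1 by construction); no mass is imputed to unvisited
  models.
- **Multiple chains** are a CLI convenience (`--chains k`) with seeds offset
  deterministically; inference utilities operate on single chains.

## Known limitations

Dense `O(n³)` covariance algebra limits practical problem sizes to a few
thousand sites.  Model priors are independent across covariates (no heredity
or grouping constraints).  The sampler assumes planar projected coordinates;
geodesic distances are out of scope.  Spatial prediction (kriging surfaces)
is deliberately not provided — the package targets covariate inference.
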