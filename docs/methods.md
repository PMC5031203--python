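# Methods

This note records the models, estimators and numerical choices behind
`voitools`, and what the synthetic test beds do and do not establish.

## Decision-theoretic quantities

All estimators target functionals of the joint distribution of the
per-treatment net benefits `NB_t(θ) = k·E[e|θ;t] − E[c|θ;t]`:

* EVPI — `E_θ[max_t NB_t] − max_t E_θ[NB_t]`, estimated by the plug-in
  combiner (mean of row maxima minus max of column means) on the PSA
  table.
* EVPPI for a focal subset φ — the same combiner applied to the
  conditional expectations `g_t(φ) = E_{ψ|φ}[NB_t]`.

Both are non-negative, EVPPI(φ) ≤ EVPI, and EVPPI is non-decreasing under
focal-set inclusion. Estimates can come out (slightly) negative through
Monte-Carlo or regression noise; they are reported as computed with a
diagnostics flag, never silently clipped, because truncation would mask
estimator failure.

All regression estimators fit the *incremental* net benefits
`NB_t − NB_0` with the reference arm fixed at zero. This halves the work
(T−1 fits instead of T) and is exact for the combiner, which is invariant
to subtracting any common per-draw function from all arms.

## Monte-Carlo estimators

The nested estimator draws `S_φ` outer values of φ and, for each, `S_ψ`
conditional nuisance draws; inner streams are spawned from a seed
sequence so results do not depend on loop order and the outer loop could
be parallelized without changing output. The single-loop estimator
requires the model's closed-form conditional expectation and is then
exact up to outer Monte-Carlo error; it is the oracle against which the
regression methods are validated. The combiner's own sampling noise sets
a floor for any estimator read off `S` draws: for a mean-zero Gaussian
incremental net benefit the relative standard error is
`sd(max(0,X))/(EVPPI·√S) ≈ 1.46/√S`, about 4.6% at S = 1000 — agreement
between a regression estimate at S = 1000 and a long-run oracle can not
be expected to be tighter than that.

## Dense GP regression

Model: `NB_t(θ_s) = g_t(φ_s) + ε_s`, GP prior on `g_t` with mean `Hβ`
(intercept plus linear terms in the standardized φ) and
squared-exponential covariance; 2P+3 hyperparameters (β, per-dimension
smoothness δ_p, marginal variance σ², nugget σ_ε²). Priors: flat on β,
p(σ²) ∝ 1/σ², flat on (log δ, log η) with η = σ_ε²/σ². β and σ² integrate
analytically, leaving the profile objective

    ½ log|Σ̃| + ½ log|H'Σ̃⁻¹H| + ((n−P−1)/2) log(y'Σ̃⁻¹(I − H(H'Σ̃⁻¹H)⁻¹H'Σ̃⁻¹)y)

with Σ̃ = correlation + ηI, minimized by L-BFGS with an analytic gradient
(validated against finite differences and an independent dense
implementation in the tests). Four starts: one moment-based (δ_p = focal
column range, where full correlation across the data is the natural unit)
plus three seeded random perturbations; ties broken by lowest objective.
Hyperparameters are estimated on a seeded 500-draw subsample (a
full-sample option exists, since subsampling can distort hyperparameters)
and fitted values computed on all S draws via
`ĝ = Hβ̂ + C(C + σ_ε²I)⁻¹(y − Hβ̂)` with generalized-least-squares β̂ —
σ² cancels from that expression. Numerical safeguards: jitter 1e-10
escalating ×10 to 1e-6 before Cholesky failure is raised; constant focal
columns are dropped from the covariance (kept in H) with a warning;
degenerate responses short-circuit to a constant fit.

## Principal fitted components

Inverse-regression model `φ = μ + Υ f(NB) + ε` with `f` the centred
powers of the standardized response up to degree h (orthogonalized across
degrees for conditioning; the span is unchanged, and any coefficients
inside `f` are absorbed into Υ as in standard PFC). Error structures:
isotropic, diagonal, and unstructured (full Δ). The first two have
closed-form or near-closed-form fits; diagonal and unstructured use a
short fixed-point iteration (whiten by Δ, rank-d eigenfit of the fitted
covariance, update Δ from the rank-d residuals).

The unstructured structure is essential, not a luxury: when the focal
parameters are correlated, the sufficient reduction is `Υ'Δ⁻¹φ`, and
restricting Δ to a diagonal biases the directions towards the predictor
covariance. On the correlated Gaussian-linear study the isotropic
direction makes an angle of ~37° with the true forward-regression
direction (cos 0.80) and depresses the downstream EVPPI by ~10%; the
unstructured reduction recovers it (cos 0.9997 — a Sherman–Morrison
identity makes this exact in population for linear signals). The default
selection grid therefore includes isotropic and unstructured, the latter
only when n ≥ 10P (full-Δ estimation is fragile when n/P is small);
diagonal remains available.

(d, h, structure) are chosen by AIC with the parameter count
P + d(P−d) + dh + {1, P, P(P+1)/2}: μ, Υ on its Grassmann manifold, basis
coefficients, error scale. The downstream projection always keeps two
coordinates (standardized to zero mean, unit variance): when d* = 1 the
second eigen-direction only adds information; when the AIC-optimal d
exceeds 2 the fit proceeds with `sufficiency_ok = False` and a prominent
warning — the estimate may be biased and residual checking is mandatory.
One projection is fitted per incremental contrast, keeping each
regression's sufficiency self-contained.

## Matérn-SPDE latent Gaussian model

A Matérn (ν = 1) field is the stationary solution of
`τ(κ² − Δ)^{α/2} g = W` with α = ν + 1 in 2-D; piecewise-linear finite
elements on a triangulation give a GMRF on the vertices with sparse
precision `Q = τ²(κ⁴C + 2κ²G + GC⁻¹G)` (α = 1: `τ²(κ²C + G)` for
sensitivity analysis). The mass matrix is lumped (C_ii = one third of the
incident triangle area) — required for `GC⁻¹G` to stay sparse — and the
marginal variance obeys `σ² = 1/(4πκ²τ²)`, verified against the
closed-form Matérn covariance on a fine unit-square mesh (interior
covariances agree within ~5%).

Mesh: data-coordinate convex hull dilated by 10% of the data diameter
(inner boundary, fine triangular lattice) and by 35% (outer boundary,
3× coarser), so that the Neumann conditions implied by the FEM assembly
distort the field only far from the data. Both boundaries are convex, so
an unconstrained Delaunay triangulation of the graded lattice covers the
domain exactly; a fixed-seed 1e-4·edge jitter breaks lattice
cocircularity and collinear ring points. The default inner spacing makes
the vertex count at least the number of data points; vertices are
lexicographically sorted before assembly so runs are bit-reproducible.
Data are interpolated by barycentric weights (rows of the projector A sum
to one). A point outside the mesh is an error; points hugging the inner
boundary trigger the outlier warning.

Fit: `NB ~ N(Hβ + Aω, σ_ε²I)`, `ω ~ N(0, Q⁻¹)`, β zero-mean Gaussian
with precision 1e-6 (effectively flat, keeps the joint precision PD).
H holds the intercept and the two projected coordinates, optionally their
second/third-order polynomial interactions when the linear predictor
needs more flexibility. With a Gaussian likelihood the latent field
integrates exactly, so the marginal likelihood of (log κ, log τ,
log σ_ε²) needs two sparse LU factorizations per evaluation (log-dets via
|diag(U)|, valid for SPD matrices); it is maximized by L-BFGS within
flat-prior bounds tied to the mesh — spatial range between 2× the minimum
edge and 2× the domain diameter, field and noise scales within 1e±3 of
sd(y). Fixing the hyperparameters at this mode is empirical Bayes: the
only thing lost relative to a full integration over the hyperparameters
is the propagation of their uncertainty into the fitted values, which the
EVPPI point estimate does not use. This is the package's one deliberate
simplification of the full nested-Laplace machinery.

With one or two focal parameters no projection is needed: the
standardized parameters themselves are the coordinates (P = 1 pairs the
parameter with its standardized square — a deterministic function adds no
information, and it keeps the mesh two-dimensional).

## Synthetic study models

* **Influenza toy model** — five independent parameters with
  `NB_0 = k(−πλ) − πγλ`, `NB_1 = k(−πρλ) − (ξ + πργλ)`. Defaults:
  π ~ Beta(2,18) (mean risk 10%), λ ~ Gamma(8,1) (≈8 ill days),
  γ ~ Gamma(4,5) (≈£20/day), ρ ~ Beta(4,12) (≈75% risk reduction),
  k = 20000. The implementation cost is calibrated to the decision
  margin: the mean incremental benefit is ≈ E[π]E[λ]E[1−ρ](k+E[γ]) ≈
  12000, so ξ ~ LogNormal(ln 12000, 0.3) keeps both arms genuinely
  competitive and the value of information non-trivial; a ξ orders of
  magnitude smaller would make arm 1 dominant and the EVPI degenerate.
  Multilinearity in independent parameters gives the sum-product
  conditional expectation (nuisance factors replaced by prior means),
  hence an exact single-loop oracle.
* **Gaussian-linear study** — 19 parameters, AR(1)-type correlation 0.6
  with lognormal scale spread, two arms with `NB_t = a_t'θ + b_t`;
  incremental coefficients weighted so the leading five parameters carry
  most decision-relevant variance and scaled so sd(INB) ≈ 1000 money
  units; intercepts set for mean-zero INB, the maximally uncertain
  decision. Constants are generated once from a fixed internal seed and
  shipped as code. Gaussian conditioning gives exact conditional
  expectations (including bilinear net-benefit terms via conditional
  second moments), hence the single-loop oracle used throughout the
  acceptance checks.
* **PFC test bed** — `φ = μ + Υ ξ f(y) + ε` with known subspace for
  recovery and AIC-selection experiments.

What these test beds do *not* show: real PSA output has non-Gaussian,
possibly multimodal posteriors (e.g. MCMC evidence-synthesis output),
net benefits that are strongly non-linear in θ, and focal subsets whose
sufficient dimension genuinely exceeds two. Passing the synthetic checks
validates the machinery and its self-diagnostics, not the sufficiency of
a 2-D projection for any particular real model — that is what the
residual and monotonicity audits are for.

## Diagnostics

Residual check per contrast: lag-1 autocorrelation of residuals ordered
along each projected coordinate, plus a Wald–Wolfowitz runs test about
zero; pass iff every |autocorrelation| < 0.2 and runs p > 0.01 (declared
package defaults — the literature prescribes the check, not the cutoffs).
Monotonicity audit: estimates along strictly nested focal chains, flagging
decreases beyond 2% of the largest-set estimate by default.

## Problem sizes and determinism

The test suite and acceptance script run at desk scale, chosen so the
whole suite completes in minutes on one CPU while keeping Monte-Carlo
noise well inside the asserted tolerances: S = 1000 PSA draws for the
regression estimators (with the 500-draw hyperparameter subsample),
10⁶–10⁷ draws for Monte-Carlo oracles, 8–50 replicates for recovery and
selection-rate experiments, unit-square meshes of ~1400 vertices for the
Matérn agreement checks. Every stochastic step takes an explicit seed;
meshes and optimizer paths are deterministic given the inputs.

## Known limitations

* No standard errors on EVPPI estimates; seed-to-seed spread of the
  S = 1000 estimates (±4–5%) is the practical uncertainty floor.
* The 2-D projection can lose information when the true structural
  dimension exceeds two; the package warns but still reports.
* AIC tends to over-estimate d slightly (visible as d = 2, h = 4
  selections on rank-1 truths); this is conservative for sufficiency.
* The empirical-Bayes mode ignores hyperparameter uncertainty.
* Mesh quality depends on projected-point geometry; extreme outliers
  enlarge the inner zone and coarsen the effective resolution (the
  refinement options exist for exactly that case).
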