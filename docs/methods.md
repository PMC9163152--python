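# Methods

## Problem and model

Environmental exposures — road-traffic noise, particulate and gaseous air
pollution, green space, traffic density — are strongly inter-correlated.
Putting them jointly into a Cox proportional-hazards model inflates
coefficient standard errors (multicollinearity), so true associations are
missed (Type II error). Projecting the exposures onto principal components
removes the collinearity but destroys interpretability: every component
mixes every variable. This package implements the sparse-PCA alternative:
components constrained to load on few variables, with supports forced to be
pairwise disjoint, so a significant component names exactly the exposures
behind it.

### Sparse PCA by variable projection

For a standardized design `X` (n subjects × p exposures) we solve

    min_B  1/(2n) ‖X − X B Aᵀ‖²_F + λ ψ(B)   s.t.  AᵀA = I_k,

where `B` (p × k) maps variables to component scores `Z = X B`, `A` is
orthonormal, and `ψ` is an L1, L2 or elastic-net penalty. The solver
alternates two exact subproblem minimizations:

* **A-step** — orthogonal Procrustes: with `G = XᵀX/n`, the SVD
  `G B = U Σ Vᵀ` gives `A = U Vᵀ`.
* **B-step** — the penalized quadratic decouples across components and is
  solved by exact cyclic coordinate descent (soft-thresholding for the L1
  part, scaled shrinkage for the L2 part), all components updated per
  coordinate in one vectorized step; soft-thresholding produces exact
  zeros and every coordinate update decreases the objective.

Both steps decrease the objective, so the recorded objective trace is
non-increasing; convergence is declared when the relative objective change
drops below `tol` (default 1e-6, max 1000 outer iterations; non-convergence
is flagged on the fit, never silent). Initialization is the top-k
eigenvectors of `G`, so at λ = 0 the iteration is stationary at the dense
PCA solution. Component signs are canonicalized (largest-magnitude weight
positive) to make outputs deterministic.

**Explained variance.** Sparse components are generally correlated, so
naive per-component score variances over-count. We use the adjusted
(sequential-orthogonalization) definition: with `Z = QR`, component j is
credited `R_jj²/(n−1)` divided by the total variance of `X`. At λ = 0 this
reduces exactly to the dense PCA ratios; for disjoint supports over
uncorrelated blocks it reduces to the naive variances.

### Selection rules

* **Component count k**: smallest k whose cumulative explained-variance
  fraction reaches the threshold (default 0.90), evaluated on the dense
  (λ = 0) fit. The alternative order — disjointness first, variance second —
  is exposed in config (`spca.order`), because the two criteria do not
  determine an ordering by themselves; selecting k on the dense fit keeps k
  comparable between the PCA and SPCA arms.
* **Penalty λ**: the grid is 30 log-spaced values spanning four decades
  (1e-3 … 10 on the per-subject objective scale). Sweeping upward, we keep
  the smallest λ whose supports are pairwise disjoint — each variable in at
  most one component — with every component nonempty; an all-zero component
  means the penalty is too strong and the fit is rejected as
  over-penalized. If no grid value qualifies, the error lists the per-λ
  overlap counts. For speed, grid values are screened at a reduced
  iteration budget (supports settle long before the dense components stop
  rotating in the nearly-degenerate subspace); a qualifying λ is refit at
  full precision and kept only if its converged supports still qualify.
  Successive grid fits warm-start from the previous λ's solution.

### Cox regression

The Efron-tie partial likelihood, gradient and observed information are
computed from risk-set suffix sums; the unpenalized model is maximized by
damped Newton (step-halving on likelihood decrease, convergence on both the
likelihood change and the score norm). Standard errors come from the
inverse observed information; CIs are Wald (`exp(β ± 1.95996·SE)`). A
monotone partial likelihood (separation) is detected as a runaway
coefficient (|β| > 10 on standardized terms) and flagged
`converged_ = False` with the coefficients still reported.

The penalized model maximizes `ll(β) − λ·n·Σ_masked |β_j|` by cyclic
coordinate descent with soft-thresholding; the mask covers the exposure /
component terms only — adjustment covariates are never shrunk. The `λ·n`
scaling puts the printed grid (0 … 2e-3 by 5e-5) on the per-subject scale;
the convention is recorded in the fit metadata. The path is fitted in
ascending order with warm starts; per-λ non-convergence (expected under
severe collinearity at small λ) is flagged, and the path is still returned.

### Attribution and units

For a significant component with weights `b` on its support, a one-unit
score increase along the loading direction moves standardized variable i by
`b_i/‖b‖²`, i.e. `s_i·b_i/‖b‖²` raw units (`s_i` = the variable's raw SD
retained by the standardizer). The aggregate (mean over the support) is
reported only when the support shares one physical unit. Hazard ratios
quoted per `d` raw units are restated per `d'` units by raising HR and CI
bounds to the power `d'/d`. Dense components whose support exceeds the
interpretability cap (default 6 variables) are refused with an explicit
non-identifiability error — this is precisely the dense-PCA failure mode
the sparse variant addresses.

### Decile exposure–response

The composite exposure is the unweighted raw-unit mean of its constituent
columns (e.g. day/evening/night noise). Sample deciles use quantile
boundaries with half-open `(a, b]` intervals, ties to the lower decile.
The Cox model contains indicators for deciles 2–10 (lowest decile is the
reference), dense principal components of the remaining exposures up to a
0.92 variance threshold, and the covariates. The 0.92 threshold follows
the source analysis's residual-adjustment choice.

## Synthetic cohort generator

No public individual-level data exist for this analysis, so the generator
emulates the study conditions: 20 exposures in eight named blocks with the
published means and SDs (noise triplet at within-block r = 0.98; five air
pollutants; green-space, natural-environment, garden and water coverage;
coastal distance; three traffic variables), cross-block correlations chosen
to echo the reported correlation structure (pollution/noise/traffic
positively related, green blocks negatively related to them), and
covariates age ~ N(56.88, 8.02), male sex ~ Bernoulli(0.455), deprivation
~ N(−1.42, 3.01). Exposure marginals are Gaussian: the analysis only sees
standardized, winsorized values. The full correlation matrix is validated
positive semi-definite at construction, with the offending block pair named
when a single cross-correlation is inconsistent.

True log-hazard effects are specified per population SD; a block-level
effect loads on the mean of a block's standardized members (default: 0.0169
per unit of the noise-block mean, i.e. HR 1.017 per component unit).
Covariate effects default to 0.45/SD (age), 0.30/SD (male sex — matching
the roughly two-fold male/female event-rate ratio), 0.10/SD (deprivation).
Event times are exponential (Weibull available) under proportional hazards
with administrative censoring at 8.21 years, chosen so mean follow-up is
≈ 8.05 years after deaths; the baseline rate is calibrated by deterministic
Gauss–Hermite quadrature over the linear-predictor distribution so the
expected event fraction is 3.95%. All randomness flows from one seed
through named child streams (exposures, covariates, survival).

What the generator does **not** emulate: spatial exposure assignment,
non-Gaussian exposure marginals (skewed traffic counts), competing risks,
staggered recruitment, time-varying exposures, and residual confounding
structure. Passing tests therefore demonstrate the statistical machinery
under the assumed correlation/outcome structure, not robustness to these
real-data features.

## Study sizes and numerical choices

Replicate studies are scaled down to run on a single CPU:

* **Type II demonstration** — 100 replicates at n = 20,000 with the 3.95%
  event rate and the true component effect 0.0169/unit. Note the implied
  Wald statistic for the component is ≈ 0.0169·√(events) ≈ 0.5 at this
  size, so detection power is intrinsically low at desk scale; the
  demonstration's raw-Cox arm (no individual noise variable significant) is
  the robust half of the contrast.
* **Null Wald calibration** — 1000 replicates, n = 2000, three independent
  null exposures, baseline rate raised to ≈ 15% events so each term rests
  on ≈ 300 events (Wald asymptotics need adequate event counts; at the
  study's 3.95% rate a 2000-subject replicate would carry only ≈ 80).
* **Decile null coverage / trend recovery** — 200 / 100 replicates at
  n = 2000, ≈ 15% events; the trend study uses a clear log-linear composite
  effect of 0.3 per unit of the standardized composite.
* **Penalized-path calibration cohort** — n = 20,000 with the event count
  scaled as n²/N_full so the printed λ grid's penalty-to-score-noise ratio
  (λ·n / √events) matches the full-scale design; this preserves the
  "large λ zeroes every environmental coefficient" behavior at desk scale.

Numerical tolerances: SPCA support tolerance 1e-8 (soft-thresholding
produces exact zeros; the tolerance guards rounding); SPCA convergence
1e-6 relative objective change; Newton convergence 1e-9 relative
likelihood change plus score norm < 1e-6; coordinate descent 1e-9 maximum
coefficient change. Default SPCA penalty is pure L1; elastic net with
mixing 0.95 and pure L2 are available in config.

## Known limitations

* The disjoint-support criterion can fail on data without block structure
  (no λ yields disjoint nonempty supports); the error is informative, but
  no automatic fallback is attempted.
* Alternating minimization converges to a stationary point, not certifiably
  the global optimum; the packaged enumeration test covers only the small
  fixture.
* No proportional-hazards diagnostics, time-varying effects, stratified
  baselines or competing risks.
* Deciles use plain sample quantiles; heavy ties in the composite can make
  decile sizes unequal.
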