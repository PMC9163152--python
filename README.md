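# spcacox

Inference on correlated environmental exposures and survival outcomes via
sparse principal component analysis and Cox regression.

## The problem

Exposures such as road-traffic noise, particulate and gaseous air
pollution, green space and traffic density are strongly inter-correlated.
Entering them jointly into a Cox proportional-hazards model inflates the
standard errors of the coefficients (multicollinearity), so real
associations are missed — a Type II error. Projecting the exposures onto
principal components removes the collinearity but destroys
interpretability, because every component mixes every variable and a
significant component cannot be traced back to the exposures behind it.

`spcacox` implements the sparse alternative. Sparse PCA by variable
projection solves

    min_B  1/(2n) ‖X − X B Aᵀ‖²_F + λ ψ(B)   s.t.  AᵀA = I,

where `X` is the standardized (and ±5-winsorized) exposure matrix, `B` the
sparse weight matrix mapping variables to component scores `Z = X B`, `A`
an orthonormal matrix, and `ψ` an L1 / L2 / elastic-net penalty. The
number of components is chosen to explain 90% of the variance, and λ is
the smallest grid value at which component supports are pairwise disjoint —
each variable contributes to at most one component. A Cox model on the
component scores (plus covariates) then yields hazard ratios whose
significant terms name a handful of exposures, which the package converts
back to raw units (e.g. "HR 1.07 per 10 dB of average daily noise").

The package provides, as scikit-learn-style estimators and thin functional
wrappers:

* `ClippedStandardizer` / `standardize` / `winsorize` — z-scoring with
  retained raw moments, ±5 clamping;
* `SparsePCA`, `PCA` — the variable-projection solver (alternating
  orthogonal-Procrustes and penalized coordinate-descent updates, exact
  zeros, adjusted explained variance) and a sign-canonicalized dense PCA;
* `select_n_components`, `select_lambda_disjoint` — the two selection rules;
* `CoxPH`, `CoxL1Path` — Efron-tie Cox regression by damped Newton with
  Wald inference, and a masked L1 path (exposures penalized, covariates
  not) over the λ grid 0…2e-3 by 5e-5;
* `trace_attribution`, `pc_unit_in_raw_units`, `rescale_hr`,
  `make_composite`, `decile_exposure_response` — the interpretability layer
  and the decile exposure–response stage;
* `run_comparison`, `run_decile_stage`, `apply_exclusions` — end-to-end
  orchestration of the four-way model comparison (raw Cox, penalized Cox,
  PCA-Cox, SPCA-Cox) with audit logging;
* a calibrated synthetic-cohort generator (`paper_like_spec`,
  `generate_cohort`): 20 block-correlated exposures (noise triplet at
  r = 0.98, air-pollution, green-space, traffic blocks …) with published
  means/SDs, covariates, and proportional-hazards mortality at a 3.95%
  event fraction over ≈ 8.05 years of mean follow-up.

See `docs/methods.md` for the model details and design choices.

## Worked example

```python
from spcacox import paper_like_spec, generate_cohort, run_comparison

spec = paper_like_spec(n_subjects=20_000)    # calibrated synthetic cohort
table = generate_cohort(spec, seed=1)
report = run_comparison(table, seed=1)
print(report.run_summary())
```

prints (abridged):

```
pca_n_components: 11
spca_lambda_star: 0.004893900918477494
block raw_cox: ok
block penalized_cox: ok
block pca_cox: ok
  attribution_refusal: component PC5 is significant (p=0.0292) but loads on
  20 variables (cap 6); the association cannot be disentangled into
  individual exposures
block spca_cox: ok
  supports: SPC1=no2,nox,pm10,pm_coarse,pm2_5; ...
            SPC4=noise_day_db,noise_evening_db,noise_night_db; ...
attribution: 1 significant component(s)
```

Eleven components explain 90% of the variance of this cohort's exposure
matrix; at the selected penalty (λ* ≈ 0.0049) the components partition the
exposures into their generating blocks — the three noise variables form
one component. The dense-PCA arm has a significant component too, but its
support is all 20 variables, so attribution is refused; the SPCA arm's
significant component is traced to exactly the noise triplet, and

```python
from spcacox import rescale_hr
hr, ci = rescale_hr(1.017, (1.004, 1.030), per=2.47, target=10.0)
# (1.0706..., (1.0163..., 1.1271...))  ->  1.07 (1.02-1.13) per 10 dB
```

restates a hazard ratio per component unit (2.47 dB of average daily
noise) as per 10 dB.

The command line mirrors the library:

```sh
spcacox simulate --n-subjects 20000 --seed 1 --out cohort.csv
spcacox compare --input cohort.csv --seed 1 --outdir results/
spcacox decile  --input cohort.csv --outdir results/
spcacox audit --start 502527 --remove consent=158 --remove left_uk=1102 \
    --remove death_reg=38 --remove missing=69268 --remove moved=52271
```

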