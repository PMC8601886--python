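# neighborgrowth

Neighborhood-competition models of tree growth for repeat-censused mapped
forest plots (ForestGEO-style data). The package computes annualized stem
growth from two censuses, builds focal-vs-competitor neighborhoods within a
competitive radius, fits a species-structured Bayesian linear regression
with exact Normal/Inverse-Gamma conjugate posteriors, and asks the two
questions forest ecologists bring to these models:

1. **Does competitor identity matter?** — a permutation test that reshuffles
   competitor species labels *within each neighborhood*.
2. **How well does the model really predict?** — spatially blocked
   cross-validation with a fold buffer, which respects the spatial
   autocorrelation that makes ordinary CV optimistic on mapped plots.

## The model

For focal stem *i* of species (or group) *j*, average annual DBH growth
(cm·yr⁻¹) between two censuses is

```
y_ij = β₀_j + β_dbh,j · dbh_ij + Σ_k λ_jk · x_ijk + ε_ij,   ε_ij ~ N(0, σ²)
```

where `dbh_ij` is the focal stem's DBH (cm) at the earlier census and
`x_ijk` is the summed explanatory value (by default basal area,
π(DBH/2)²/10⁴ m²) of all competitor stems of group *k* within the
competitive radius (default 7.5 m). `λ_jk` measures how group-*k* neighbors
change the growth of group-*j* stems; negative values are competition.

With a Normal/Inverse-Gamma prior — σ² ~ InvGamma(a₀, b₀),
β|σ² ~ N(μ₀, σ²Λ₀⁻¹) — the posterior is available in closed form
(Λₙ = Λ₀ + XᵀX, μₙ = Λₙ⁻¹(Λ₀μ₀ + Xᵀy), aₙ = a₀ + n/2,
bₙ = b₀ + ½(yᵀy + μ₀ᵀΛ₀μ₀ − μₙᵀΛₙμₙ)); coefficient marginals and the
posterior predictive are Student-t. No MCMC anywhere.

Stems near the plot edge have censored neighborhoods, so an edge **buffer**
band is flagged: buffer stems act only as competitors, never as focal
responses. In cross-validation a **fold buffer** of the same radius around
the test block is dropped from the training set so no training neighborhood
touches the test set.

## Worked example

Everything is testable without field data: the `simulate` module draws a
plot from a homogeneous Poisson process, grows it with known parameters,
and the rest of the pipeline treats it like any census pair.

```python
from neighborgrowth import (
    SyntheticTruth, build_synthetic_focal_table, ModelSpec, PriorSpec,
    build_design, fit_conjugate, posterior_predict, rmse,
    run_permutation_test, run_cv,
)

truth = SyntheticTruth(extent=(120, 120), intensity=0.05, seed=3)
table, partition, growth = build_synthetic_focal_table(truth)
print(len(growth), len(table))           # 708 growth records, 548 focal stems

spec = ModelSpec.from_focal_table(table)
prior = PriorSpec.default(spec.p)
X, y = build_design(table, spec)
post = fit_conjugate(X, y, prior, spec=spec)
print(rmse(y, posterior_predict(post, X)))   # 0.0988  (truth.sigma = 0.1)

res = run_permutation_test(table, prior, n_perm=19, rng_seed=1)
print(res.observed_rmse, res.p_value)        # 0.0988, p = 0.05

cv = run_cv(table, partition, prior)
print(cv.overall_rmse)                       # 0.1020
```

The in-sample RMSE (0.0988) sits just below the true residual sd (0.1) —
mild overfitting — and the spatially cross-validated RMSE (0.1020) sits just
above it, which is the honest out-of-sample number. The permutation test
rejects (p = 1/20 at 19 permutations): this scene was generated with
species-specific λ, and shuffling competitor identities measurably degrades
the fit.

The same pipeline runs from the shell on CSV/GeoJSON artifacts:

```sh
neighborgrowth simulate -c config.yml
neighborgrowth growth   -c config.yml
neighborgrowth focal    -c config.yml
neighborgrowth fit      -c config.yml
neighborgrowth permute  -c config.yml
neighborgrowth cv       -c config.yml
```

For real censuses, point `census1`/`census2` in the config at your plot's
CSV files and use `schema`/`dbh_unit` to map site-specific column names and
units (some ForestGEO sites record DBH in millimeters).

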