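# Methods

## Growth from two censuses

The response is average annual DBH growth, `(dbh2 − dbh1)/Δt` in cm·yr⁻¹,
for stems that are alive with a measured DBH at both censuses. Δt uses each
stem's own pair of census dates, in days/365.25; when a date is missing the
user must supply a nominal inter-census interval in years, and a
non-positive interval is an error naming the stem. Resprouted stems (census
code `R` in the later census) are regrown tissue, not continuous growth, and
are discarded. Negative growth is kept by default — DBH shrinkage and
measurement error are real — with an optional user-set bounds filter.
Multi-stem trees contribute one record per stem; the join key is
configurable for sites that need a composite tree/stem id. All exclusions
(dead, resprout, unmeasured, out-of-bounds) are counted in the log, because
those filters are part of the method's semantics.

## Neighborhoods

A focal stem must be interior (outside the edge-buffer band), have a valid
growth value, and have at least one neighbor within the competitive radius
`comp_dist` (default 7.5 m, the mid-range of radii used across temperate
neighborhood-competition studies). Its competitors are *all* other stems
within the radius — buffer stems and stems of every CV fold included; the
buffer band exists precisely so its stems can compete without being modeled.
Per-competitor records carry distance, group label, and the explanatory
value; per-group sums `x_ijk` feed the design matrix.

Numerical choices:

* radius comparisons use `≤` on exact squared distances, so a competitor at
  exactly 7.5 m is included regardless of square-root rounding; the k-d tree
  only proposes candidates (radius inflated by 1e-9), the exact comparison
  decides;
* the edge-buffer flag uses strict `<` — a stem exactly `comp_dist` from the
  boundary is still focal. Both conventions act on measure-zero tie sets;
* self-exclusion is by stem id only: other stems of the same tree do count
  as competitors, since conspecific competition is part of the model (a
  config-level choice; the alternative of excluding same-tree stems can be
  had by pre-filtering the growth table);
* competitor entries are sorted by stem id within each neighborhood, and
  the group level set K is fixed once from the full table, so design
  matrices are identical across folds and permutation replicates.

## The conjugate regression

One joint regression with a single shared σ² across focal groups — the
model has one error term, not per-species variances. The coefficient vector
is j-major: for each focal group, intercept, DBH slope, then K competition
terms (p = J(2+K)). DBH enters uncentered in cm. All-zero columns
(focal × competitor pairs never observed in a training split) are retained;
the proper prior keeps Λₙ positive definite and the coefficient index
stable.

Default prior: a₀ = b₀ = 1, μ₀ = 0, Λ₀ = I/100. The conditional prior sd of
each coefficient is 10σ — diffuse on the cm·yr⁻¹ growth scale while still
proper; all hyperparameters are user-overridable, and every headline number
is, like in any Bayesian analysis, mildly sensitive to this choice. Updates
go through a Cholesky factorization of Λₙ (never an explicit inverse); on a
factorization failure a jitter of 1e-10·trace/p is added once and logged.
The empty update (n = 0) returns the prior exactly, and batch conditioning
equals sequential row-by-row conditioning to 1e-10 — both are tested.

Point predictions are the posterior-predictive location `X μₙ`; the full
predictive is Student-t with df 2aₙ and squared scale
`(bₙ/aₙ)(1 + x Λₙ⁻¹ xᵀ)`. Marginal coefficient densities are emitted as a
tidy table (role ∈ {intercepts, dbh_slopes, competition}, df, location,
scale) rather than figures; any plotting layer can consume it.

## Permutation test of competitor identity

Null hypothesis: λ_jk = λ_j for all k — competition depends on how much
neighborhood there is, not on who it is. Under H0 the response depends on a
neighborhood only through its total x, which is invariant to relabeling
competitors within that neighborhood, so labels are exchangeable
*within neighborhoods* and the test permutes them there and only there
(global counts and each neighborhood's label multiset are conserved —
asserted per replicate in tests). Each replicate refits and recomputes the
in-sample RMSE; small observed RMSE is evidence identity matters, and the
p-value uses the add-one convention p = (1 + #{null ≤ observed})/(n_perm+1),
which is never zero and exact under exchangeability. Default n_perm = 49,
giving the p-value grid {1/50, …, 1}.

## Spatial cross-validation

Folds are contiguous spatial blocks (user polygons via GeoJSON, or the
built-in nx × ny rectangular partitioner; fold ids row-major from 1, points
on shared edges deterministically assigned to the lowest adjacent id). For
each test fold, training drops (a) the fold's own records and (b) all
records within `comp_dist` of the test block — the fold buffer — so no
training neighborhood overlaps the test region. "In the test block" is
interior containment: at buffer distance 0 only points exactly on the block
boundary are excluded, and the excluded set grows monotonically with the
distance (tested). The overall error is the unweighted mean of per-fold
RMSEs. Folds with an empty training or test set are skipped with a warning
and reported, not fatal. Under the shuffled (null) variant both training
and test neighborhoods are permuted — the null hypothesis holds everywhere,
not just in training — with fresh per-fold permutations derived from the
root seed.

## Synthetic plots

The generator draws a Poisson(intensity·area) number of stems uniformly on
a rectangle, multinomial species labels, and lognormal DBH, then grows each
stem by the model mean (computed from its own simulated neighborhood) plus
Gaussian noise. The second census is *derived*: DBH₂ = DBH₁ + growth·Δt
with Δt computed from the generated dates exactly as the census stage
computes it, so the pipeline is exercised end-to-end and noise-free scenes
recover β and λ to solver precision — the strongest single oracle for the
whole package.

Default scene: 300 × 300 m at 0.09 stems/m² (≈8,000 stems, a desk-scale
analog of a 9-ha plot subsection), three species with abundances
(0.5, 0.3, 0.2), DBH ~ lognormal(2.3, 0.6) cm (median ≈10 cm), intercepts
0.10–0.25 cm·yr⁻¹, small positive DBH slopes, negative λ of order 0.1–1
per m² of neighboring basal area, σ = 0.1 cm·yr⁻¹ (the magnitude of
residual annual growth error typical of temperate ForestGEO plots), censuses
6 years apart. The generator does **not** emulate clustered spatial
patterns, habitat structure, mortality, recruitment, or DBH measurement
error; passing tests demonstrate correctness of the estimator and resampling
machinery under the model's own assumptions, not robustness to their
violation on real plots.

Seeding is counter-based: every stochastic operation derives its generator
from (root seed, operation tag, counter), so partial reruns are stable and
permutation replicates are independent but reproducible.

## Test problem sizes

The statistical guarantees in `tests/test_acceptance.py` run at sizes chosen
to make their Monte-Carlo bands tight while keeping the default suite quick
on one CPU: calibration of the permutation test uses 200 independent plots
of ≈250 focal stems with 49 permutations each (rejection rate at α = 0.1
within [0.05, 0.15]); power uses 100 low-noise plots; interval coverage
uses 200 plots of ≈2,000 focal stems. The noise-free identifiability check
uses a near-flat prior (Λ₀ = 1e-10·I) because exact recovery is only defined
in the no-shrinkage limit.

## Known limitations

* Only the hard-radius summed explanatory variable — no distance-decay or
  size-ratio kernels.
* Planar Euclidean geometry in plot meters; no geodesy.
* No allometric biomass: any per-stem numeric column can serve as the
  explanatory variable, but computing it is the user's job.
* Single-plot layouts; spatially separated inventory-plot designs are out
  of scope.
* Closed-form conjugacy only; trait-structured λ or non-Gaussian errors
  would need a different fitting backend.
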