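# Methods

## Model

Counts `D[i, j]` on an `a × p` Lexis grid (rows: 5-year age groups,
youngest first; columns: 5-year periods, earliest first) are modelled as
independent Poisson variables with mean

    E[i, j] = P[i, j] · exp(μ + α_i + β_j + γ_k),   k = a − i + j,

where `P` is person-years of exposure, entering as an offset with fixed
coefficient one, so the linear predictor models the log rate. Cohort
`k` runs 1 … a+p−1 along the anti-diagonals; `k = 1` is the eldest age
group in the first period (the oldest birth cohort). Birth-interval
labels derive from the grid: cohort `k` is born in the 5-year interval
starting at `period_start[0] − age_start[a−1] − 5 + 5(k−1)`; on the
default grid (ages 10–79, periods 1985–2010) this gives 1905-09 through
1995-99.

The model assumes: a complete rectangular grid with equal 5-year
intervals on both axes (unequal widths change the identification
structure and are rejected); exposures known and positive; no
overdispersion (no quasi-Poisson or negative-binomial option); strata
such as country × sex fitted as separate models.

## Design and identification

The design matrix uses effect (sum-to-zero) coding with the **last**
category of each block dropped, rows ordered age-major, columns ordered
intercept, age, period, cohort; `m = 2(a+p) − 3` columns in total. The
dropped category's effect is reconstructed as the negative block sum, so
reported blocks sum to zero exactly.

Because age, period and cohort indices satisfy one exact linear
relation, `rank(X) = m − 1` and `ker(X)` is one-dimensional. The kernel
vector `B0` is computed numerically (SVD, `scipy.linalg.null_space`)
rather than from a closed form, with its linear-in-category-index block
structure verified as a cross-check in the test suite; its sign is fixed
by making the first component exceeding 1e-8 positive, so `B0` is
deterministic. The intercept component of `B0` is numerically zero (the
intercept is estimable). Adding `t·B0` to any coefficient vector leaves
every fitted count unchanged — the linear-trend indeterminacy at the
heart of APC analysis.

**Intrinsic estimator.** An orthonormal basis `U` of the orthogonal
complement of `B0` is taken from the SVD; the Poisson GLM with design
`X·U` and offset `log P` is fitted by IRLS (statsmodels `GLM`,
`family=Poisson`, dispersion fixed at 1); estimates and covariance map
back as `θ = U·b`, `Σ = U Σ_b U′`. The returned `θ` satisfies
`θ·B0 = 0` (checked to 1e-8).

**CGLIM.** An adjacent-pair equality constraint (`block`, categories
`c = c+1`, including pairs touching the reconstructed last category) is
written as a functional `c′θ = 0` and the same subspace machinery fits
the GLM in an orthonormal basis of that hyperplane — algebraically
equivalent to merging the two categories into one design column. A
constraint whose functional annihilates `B0` cannot identify the model
and is rejected (cannot occur for adjacent pairs, whose `B0`-difference
is the block's constant slope). Only adjacent-pair equality is
supported; arbitrary linear constraints are out of scope.

**Uncertainty.** Covariances are inverse expected information on the
identified scale; reconstructed last-category variance is
`1′ Σ_block 1`; intervals are Wald, `estimate ± 1.96·SE`, on the
log-rate scale. Note `Σ` is singular by construction (rank m−1): it is
the covariance of the identified estimator, not of an unconstrained one.

## Numerical choices

* IRLS stops when the deviance change falls below `1e-10` relative (or
  100 iterations). statsmodels applies an absolute deviance criterion,
  so the relative rule is re-checked on the iteration trace; genuine
  non-convergence raises with the trace attached.
* Zero-count cells are retained (Poisson likelihood handles zeros); no
  continuity correction. A category whose counts are zero in *every*
  cell is fitted but flagged on the fit object — its effect estimate
  diverges toward −∞ in principle and should not be interpreted.
* Ties/degeneracies: grids need `a, p ≥ 2`; a kernel dimension other
  than 1 raises rather than silently re-identifying.
* Rates default to per 100,000 person-years lived (configurable).
  Marginal rates pool deaths over pooled exposure (ratio of sums), the
  person-years weighting implied by "per 100,000 PYL" — not the mean of
  cell rates; the two differ when exposures vary across pooled cells.
  Direct standardization is the weighted mean of age-specific rates
  under a normalized reference age distribution.

## Synthetic generator

`SyntheticSpec` draws `D ~ Poisson(P · exp(η))` from chosen effect
curves. Defaults mirror a national two-country mortality study design:
14 age groups (10–79) × 6 periods (1985–2010), 19 cohorts, constant
exposure 1e6 person-years per cell (national 5-year × 5-year cells run
roughly 1e5–1e7), baseline rate 20 per 100,000. The exposure surface is
configurable, e.g. to mimic population aging.

Because estimates are identified only orthogonally to `B0`, the stored
truth is **projected onto the identifiable subspace by default** —
otherwise "recovery" would be ill-posed. The unprojected mode exists to
demonstrate the indeterminacy: truths differing by `t·B0` generate
identical Poisson surfaces (a property test asserts this).

Two stylized presets encode contrasting temporal regimes for
demonstrations and tests: `japan-like` (age peak in the fifties, a
period step in the late 1990s that then stabilizes, elevated oldest
cohorts with a mid-century trough) and `korea-like` (flat age profile
from the 20s through the 50s then a steep old-age rise peaking at
75–79, period effects growing fastest after 2000, a cohort hump for
mid-century births). They are qualitative shapes, not fitted to any
country's data: the generator does not emulate real demographic
evolution, migration, cohort attrition, changing sex ratios, or
overdispersion, so passing recovery tests show correctness of the
estimator under the model's own assumptions, not robustness to
violations of them on real data.

Seeding: one master seed; per-replicate generators are spawned via
`numpy.random.SeedSequence`, so experiments are reproducible and
replicates independent. Fitting itself is deterministic.

## Experiment sizes

The recovery experiment used by the acceptance checks runs 200
replicates of the 14×6 grid at exposure 1e6 (about 2 s on one core);
the coverage property test uses 500 replicates, at which the per-category
binomial granularity of an empirical coverage proportion (1/500) is fine
enough for the (0.92, 0.98) acceptance band around the nominal 0.95.
At 200 replicates the granularity is 1/200, and a perfectly calibrated
interval falls outside that band in roughly 7% of categories by chance —
worth remembering when reading per-category coverage from small
simulation runs.

## Known limitations

* Wald intervals and IRLS standard errors are asymptotic; at cell means
  below ~5 events the corner-cohort effects (estimated from a single
  cell) show visible small-sample bias, as `examples/04` demonstrates at
  exposure 1e4.
* The intrinsic estimator is one canonical identification, not a
  resolution of the APC problem: quantities that load on the kernel
  direction (overall linear trends split between age, period and
  cohort) remain convention-dependent, and only estimable functions
  should be compared across software with different conventions.
* No smoothing/spline or hierarchical APC variants; no model selection
  among CGLIM constraints.
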