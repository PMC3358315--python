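# Methods

## Model family

The baseline object is the marginal hazard of a multistage process in a
heterogeneous population.  An individual's hazard is `z · μ₀(x)` with
Weibull baseline `μ₀(x) = (m/c)(x/c)^(m−1)` and a frailty `z ≥ 0` of
mean 1 and variance `σ²` drawn from the power-variance family (PVF)
indexed by `n`.  Averaging over survivors gives the population rate

    λ(x) = (m/c)(x/c)^(m−1) [1 + n σ² (x/c)^m]^(−1/n).

Anchor cases, each verified in the test suite:

- `n = 1` — gamma frailty: λ = μ₀ / (1 + σ²H) with `H = (x/c)^m`,
  checked against numerical marginalization of a mean-1 gamma mixture;
- `n = 2` — inverse-Gaussian frailty: λ = μ₀ (1 + 2σ²H)^(−1/2),
  checked the same way;
- `n → 0` — exponential attenuation λ = μ₀ e^(−σ²H); evaluated by an
  explicit limit branch for `n < 1e-6`, continuous against small-n
  evaluation to 1e-6 relative;
- `σ = 0` — the homogeneous Weibull hazard, identical to the
  Armitage–Doll power law `a·x^(m−1)` under `a = m/c^m`.

Differentiating `log λ` gives the interior maximum
`x* = c[(m−1)/(σ²(m − n(m−1)))]^(1/m)`, which exists iff `m > 1`,
`σ > 0` and `m − n(m−1) > 0`; otherwise `mode_age` returns `None`
(monotone hazard).  Beyond the mode the hazard declines — the
selection-driven downturn of registry incidence at advanced ages that
homogeneous multistage models cannot produce.

`m` is a population-level count of rate-limiting transitions per
*person*, not a count of somatic mutations per cell; `c` is reported as
the Weibull age scale.  An alternative convention reads the age of
maximal incidence as the scale parameter; since the mode is a
deterministic function of `(m, c, σ, n)`, the shape parameter `m` — the
quantity of scientific interest — is invariant to that choice, and we
keep the plain Weibull scale.

## Covariates and APC extension

The generalized rate multiplies λ by
`R_sex^f · R_race^b · (1 + F_year/100)^((year − year₀)/10)`; `f` and `b`
are female and African-American indicators, `F_year` is a percent
change per decade, and the anchor `year₀` defaults to 1988 (midpoint of
the 1973–2003 window; configurable).  Ages are 1-year bins evaluated at
midpoints `a + 0.5`; for coarser bins the half-width is inferred from
the bin spacing.

The APC variant removes `F_year` (it would be confounded with period
effects) and multiplies λ by `g_cohort(year − age) · g_period(year)`,
with 10-year, calendar-decade-aligned cohort bins and 5-year period
bins (the trailing period bin absorbs a short remainder, e.g.
1998–2003).  Multipliers are estimated as `log g` to enforce
positivity, with the bins containing the panel midpoint fixed at
exactly 1 — the normalization that removes the `k`-vs-`1/k`
cohort/period rescaling indeterminacy; uniqueness under this constraint
is verified by refitting from different multistart seeds.

## Weights and estimation

Rates are `count / person-years`.  Because 1-year bins at young ages
legitimately contain zero counts, plain binomial/Poisson variance
estimates would give infinite weights; we use the Wilson score-interval
variance `p̃(1−p̃)/(N+z²)` with `p̃ = (count + z²/2)/(N + z²)`,
strictly positive for all counts.  The z-level defaults to 1.96 and is
configurable.  Counts above exposure are rejected (outside the
proportion domain).

Two estimators share one optimizer (bounded trust-region-reflective
least squares):

- **WNLS** minimizes `Σ wᵢ (rateᵢ − λᵢ)²` with `wᵢ` the reciprocal
  Wilson variance of the observed cell.  Standard errors come from the
  Jacobian curvature `inv(JᵀJ)` scaled by χ²/d.o.f.
- **MLE** maximizes the Poisson likelihood of the counts given
  `μᵢ = person-yearsᵢ · λᵢ`, implemented as least squares on signed
  square-root deviance residuals — the same optimum, but conditioned
  like a residual problem and immune to log-of-zero underflow.  SEs
  come from `inv(JᵀJ)` of the deviance residuals, the inverse Fisher
  information at the optimum.

The objective is multimodal in `(σ, n)`, so every fit is a multistart
(default 8 for production fits; unit tests use 2): start 1 is
data-driven (`m` from the log-log slope of the rising limb plus 1, `c`
at the empirical rate maximum, `σ = n = 1`, neutral covariates), the
rest are Latin-hypercube draws within bounds seeded by the
configuration, so identical config + data give bit-identical results.
Ties break on objective, then on smaller `m`.  Default bounds:
`m ∈ [1, 30]`, `c ∈ [10, 300]` years, `σ ∈ [0, 500]`, `n ∈ [0, 3]`
(`n` is fitted freely, not selected from {0, 1, 2}), relative risks in
`[0.01, 20]`, `F_year ∈ [−95, 400]` %/decade.  Relative risks that a
panel cannot identify (single-sex or single-race input) are fixed at 1
with a recorded message rather than estimated.

Finite-sample note: with observed-count Wilson weights the WNLS `m̂`
carries a small upward bias (the Wilson variance over-states the
Poisson variance at low counts, down-weighting sparse cells
asymmetrically); at 2×10⁵ person-years per cell it is a few tenths of a
stage for the sparsest cancers and well inside the recovery tolerance.
The Poisson MLE is near-unbiased and is the default route for the
cross-cancer library analysis.

Goodness of fit is the Wilson-weighted χ² per degree of freedom
(≈ 1 for data consistent with the model); residual diagnostics are the
moment-based omnibus normality test, a Spearman rank regression of
squared residuals on fitted values (heteroscedasticity), and the
Durbin–Watson statistic over age ordering.  Note DW has standard
deviation ≈ 2/√nₚₒᵢₙₜₛ (≈ 0.27 at 55 points), so individual fits
legitimately wander within roughly [1.5, 2.5] under white noise.
Candidate families (Armitage–Doll, Weibull, frailty-Weibull) are ranked
by χ²/d.o.f., with F-tests on weighted residual sums of squares for the
nested pairs; with the true `σ = 0` on the boundary the F-test is
conservative (observed type-I rate ~1–5% at nominal 5%).

## Synthetic registry panels

The generator emulates the structure of registry incidence extracts:
1-year age bins, a 1973–2003 window, two sexes, two races, and cell
counts drawn Poisson with mean `person-years × model rate` (rates are
≪ 1, so Poisson and binomial sampling coincide, and Poisson matches the
MLE objective).  Default exposure is a constant 2×10⁵ person-years per
cell — chosen so recovered-parameter standard errors are comparable in
magnitude to published registry-scale ones — with an optional linear
taper above age 80 mimicking registry thinning.  The bundled library
(`table2_parameters.csv`, a versioned data file rather than hard-coded
constants) holds the 26 published parameter rows (14 ACs, 12 SCCs) with
their minimum analysis ages (30 for most sites, 15 for cervical/anal/
vulvar/head-and-neck SCCs, 20 breast ductal, 25 ovarian, 40 prostate).

What the generator does *not* emulate: real population pyramids and
registry coverage changes, more than two race categories, cohort
effects unless explicitly specified, stage-specific incidence, and
overdispersion beyond Poisson.  Passing recovery tests therefore
demonstrates estimator correctness under the model's own assumptions,
not robustness to the misspecifications real registry data contain.

One caution surfaced by the simulations: the uterine AC row with
`σ ≈ 100` has its incidence mode below the minimum fitting age, so only
the declining limb is observed and `(m, c, σ)` are barely identified —
recovered `m` swings by several stages across seeds, consistent with
its published standard error of ±1.4.  The recovery benchmarks
therefore use the well-identified uterine AC row (`m = 8.80`).

## Analysis pipeline

Per-histotype group statistics use the arithmetic mean and the SE of
the mean (sample SD with `n−1` denominator over √count); the AC
subgroup "non-reproductive organs" excludes both breast rows, ovary,
prostate and the uterine AC row, leaving nine cancers.  Histotype
means are compared with a two-sided z-test treating group SEs as known
— appropriate for summary-level comparisons without case-level data.
Stage-at-diagnosis fractions are averaged per cancer over available
years with equal weight (the averaging rule is not otherwise
determined); correlations with `m̂` are Pearson's r with the t-transform
p-value, optionally after proportional redistribution of unstaged cases
across the staged categories within each year.

The sensitivity suite refits one simulated panel under seven
perturbations — minimum age +5 years, dropping the top age bin, adding
a quadratic period-trend term `exp(q·((year−year₀)/10)²)`, 5-year age
bins, MLE instead of WNLS, restricting to the middle third of calendar
years, and the APC substitution — and flags a scenario as stable when
the `m` estimate moves by at most 1.5 stages (configurable).

## Problem sizes and defaults used in validation

Validation runs are sized for a single CPU: calibration properties
(χ²/d.o.f. band, SE coverage, F-test type-I rate, APC stability) use
100 Poisson replicates of a 55-age reference panel; consistency checks
use 15 replicates at two exposure scales; the cross-cancer ordering
check fits one replicate of each of the 26 library panels (6 820–8 680
cells each) by Poisson MLE with 3 multistarts; the headline recovery
benchmarks fit 6 820-cell panels by WNLS with 8 multistarts.

## Known limitations

- No bootstrap or profile-likelihood intervals; SEs are curvature-based.
- The APC fit estimates one multiplier per bin with no smoothing
  penalty; sparse cohort bins at the panel edges inherit wide SEs.
- Two-stage clonal-expansion-type models are out of scope; the
  comparator set is Armitage–Doll / Weibull / frailty-Weibull.
- Single-disease model: cancers that are mixtures of early- and
  late-onset forms (e.g. lobular breast) are captured only as larger
  `m` or `σ`, not as explicit mixtures.
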