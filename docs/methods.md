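# Methods

## The model

`shc` implements a discrete-time compartmental model of smoking habits in a
closed population, stratified by sex, single year of age (0–100), smoking
status, smoking intensity, and — for former smokers — years since cessation.
The living compartments are never smokers `N(t; a)`, current smokers
`C_i(t; a)` and former smokers `F_i(t; a, c)`, with intensity
`i ∈ {l, m, h}` (under 10, 10–19, and 20+ cigarettes/day) assigned at
initiation and immutable. Each model year, in one simultaneous update:

* everybody ages one year; a constant number of births `ν` enters `N` at age 0;
* each compartment loses its deaths with annual probabilities `δ_N(a)`,
  `δ_{C_i}(a)`, `δ_{F_i}(a, c)`;
* surviving never smokers start with probability `γ(a)`, split across
  intensities by the simplex vector `π`;
* surviving current smokers quit with probability `ε(a)`, entering `F_i` with
  cessation clock `c = 0`;
* surviving former smokers relapse into `C_i` with probability `η(c)`,
  otherwise their clock advances;
* survivors of their year at age 100 leave the grid and are tracked in an
  `exited` ledger, so that the accounting identity
  `alive(t+1) + deaths(t+1) + exits(t+1) = alive(t) + ν` holds exactly
  (asserted to 1e−6 relative in tests; in practice it holds to machine
  precision).

Deaths are stored annually by compartment of origin and age at exposure;
cumulative death counts are recoverable by summation. Rates convert to
annual probabilities by `p = 1 − exp(−rate)`.

### Transition curves

`γ` and `ε` are age functions only; `η` depends only on time since cessation
(no dependence on intensity or calendar time). On the logit scale, `γ(a)` is
a natural cubic regression spline of age on 14–34 (zero outside) and `ε(a)`
one on 20–100 (zero below 20), each with two equidistant internal knots and
therefore four coefficients including the intercept (`ψ` and `φ`). The basis
is the truncated-power natural-spline construction; it is evaluated on the
age range rescaled to [0, 1], which leaves the function family unchanged but
keeps all coefficients on a comparable scale for the optimizer. The relapse
*rate* is `η*(c) = ω₀ω₁ exp(−ω₁ c)` for `1 ≤ c ≤ 15`, zero at `c = 0`,
constant at its `c = 15` value from `c ≥ 16`; `ω₀, ω₁ > 0` are enforced by
optimizing on the log scale.

### State support

Quitting is impossible before age 20, so the youngest former smoker is 21
with `c = 0` and the admissible former-smoker cells are exactly
`{a ≥ 21, c ≤ a − 21}`. This set is closed under the dynamics. Survey
baselines can report former smokers in classes that straddle or sit below
age 21; `init_state` places each class's former-smoker mass on the
admissible ages of the class (compensating from the never compartment so the
class-aggregated prevalence still reproduces the survey cell exactly) and
folds the mass of all-younger classes into never smokers. Allowing `c = 0`
at any age instead would let baseline mass age into cells the difference
equations never service and silently leak population.

## Two-step estimation

**Step 1 (mortality).** Never-smoker mortality is back-calculated per year
from population mortality and observed class prevalences,
`δ_N(t; a) = δ_pop(t; a) / (p_N + RR_C p_C + RR_F p_F)`, each single age
using its enclosing survey class, then averaged (unweighted) over the
calibration window. Ages 0–13 hold no smokers, so `δ_N = δ_pop` there.
The aggregate `RR_C` and `RR_F` used in the ratio are prevalence-weighted
means of the intensity- and cessation-specific tables, using the baseline
intensity and cessation distributions — this keeps step 1 internally
consistent with the tables used in the expansion
`δ_{C_i} = RR_{C_i} δ_N`, `δ_{F_i}(a, c) = RR_{F_i}(c) δ_N(a)` (clipped to
1 with a logged warning; RR tables shorter than the cessation axis carry
their last value forward).

**Step 2 (calibration).** The remaining unknowns `θ = (ψ, φ, ω)` minimize
the mean Hellinger distance between observed and model-implied
(never, current, former) prevalences over all (year, age-class) cells,
including the first year (whose model prevalence equals the initial state's).
Cells with missing surveys or empty classes are excluded and the divisor
reduced. The optimizer is multi-start Nelder-Mead with a restart polish per
start (defaults: 20 starts, 2000 iterations per round, objective tolerance
1e−8); start intercepts are drawn uniform on [−4, 0], remaining spline
coefficients on [−2, 2] and log ω on [−2, 1], covering probability scales
from under 2% to 50%. Each sex is calibrated independently. With ~4000
respondents per cell and 27 survey years, the starting curve is recovered
within 0.02 and the quitting curve within 0.05 at every supported age;
the relapse parameters are weakly identified (many `(ω₀, ω₁)` pairs produce
nearly identical prevalence paths), which surfaces as a wide bootstrap
spread rather than a biased point curve.

## Parametric bootstrap

Sampling variability is quantified by resampling each survey cell from a
Dirichlet centered at the fitted prevalences with the survey denominator as
concentration mass (components floored at 1e−6 to keep the distribution
proper), then re-running the *full* two-step estimation per replicate —
including step 1, since the resampled prevalences enter the mortality ratio.
Replicates reuse the point fit as one optimizer start (with a small initial
simplex) plus optionally fresh starts; failed replicates are flagged and
excluded. Intervals are 5th/95th percentiles (linear interpolation),
pointwise for curves. At the scaled-down study conditions used in the tests
(8 survey years, 500 respondents per cell, B = 100, 100 datasets), the 90%
intervals for the peak starting probability and its age cover the truth in
roughly 85–90 of 100 datasets.

## Rolling cross-validation

Expanding training windows start at 3 years; each window is recalibrated
(step 1 restricted to the window as well) and scored on the next `q` years
by MAPE over all (year, class, status) cells with equal weight, pooled over
splits. Cells with observed prevalence zero are excluded (logged). Default
horizons are q = 3, 6, 9, 12; for the study period 1993–2019 this yields 22
splits at q = 3 and 13 at q = 12. CV calibrations default to fewer starts
(10) than the main fit and accept an optional warm start.

## Global sensitivity analysis

Total-order Sobol indices of the mean Hellinger distance are computed for
six mutually independent input blocks — `ψ`, `φ`, `ω`, `π`, `ν`, and the RR
tables (as two multiplicative factors on the current/former excess risks) —
with population mortality treated as known. The design uses scrambled Sobol
sequences: one 2d-dimensional draw split into base matrices A and B plus one
hybrid matrix per block, evaluated through the full pipeline
(K·(blocks + 2) model runs); indices use the Jansen estimator with
bootstrap-over-rows standard errors, and first-order indices are computed
internally only as a diagnostic (S_i ≤ S_tot within Monte-Carlo error).
Block distributions default to the calibration start boxes for `θ`, ±25%
uniforms for `ν` and the RR factors, and a Dirichlet spread (κ = 100) around
the nominal `π` via inverse-CDF gamma transforms that preserve the
low-discrepancy structure; these are assumptions, configurable per run.
On synthetic study-like data the ranking is starting > quitting > relapse,
with the fixed blocks each below 0.05.

## Health impact and policies

Smoking-attributable deaths apply the excess risk over never smokers to the
current and former compartments:
`SAD(t; a) = Σ_i C_i(δ_{C_i} − δ_N) + Σ_i Σ_c F_i(δ_{F_i}(·, c) − δ_N)`,
summable over ages; PAF divides SAD by the model-predicted total deaths of
the same year/sex/age range (both computed from the same year's state and
risks). Policies modify the starting/stopping *rates* multiplicatively —
`p' = 1 − (1 − p)^m` — which differs from scaling probabilities when they
are large: TCP1 scales the starting rate by `1 − 0.025 j` in policy year `j`
(ages 14–34, capped at 0.75 from year 10), TCP2 the stopping rate by
`1 + 0.025 j` (ages 25–100, capped at 1.25), TCP3 zeroes initiation for
cohorts born in or after 2009 (complete compliance), all from 2023.
Scenario runs share every input except the policy; avoided deaths are SAD
differences against the status-quo run.

## Synthetic data generator

The generator emulates the study's data landscape: two sexes, survey years
1993–2019, the ten canonical age classes, a ~1.7M-person baseline population
per sex with a realistic age profile, Gompertz-type never-smoker mortality,
literature-style relative risks decaying with time since cessation, constant
births, and a truncated-geometric baseline cessation distribution (mean ≈ 8
years). True transition curves are drawn per seed (starting peaked near age
20 at 5–10%, quitting rising after 50, high early relapse) and projected
onto the model's own spline family, so truth is exactly representable.
Population mortality is assembled from `δ_N` and the aggregate RRs through
the same mixing identity step 1 inverts, making the noiseless limit an
exact-recovery test for both steps. Surveys are multinomial draws per
(year, class) cell — the natural sampling model for survey counts; the
Dirichlet appears only in the bootstrap — with default cell sizes around
300–900 respondents.

What the generator does *not* emulate: survey design effects and weighting,
migration, time-varying transition curves or births, intensity switching,
age-dependent relapse, and cause-specific mortality. Passing tests therefore
demonstrate the correctness and calibration of the *procedures* under the
model's own assumptions, not the adequacy of those assumptions for real
survey data.

## Numerical choices

* The annual update is a compiled (numba) kernel looping only over
  admissible cessation cells; a plain-numpy transcription of the same
  equations is kept as an independent cross-check, and an agent-level
  simulator (one Bernoulli draw per person-year) in the test suite verifies
  compartment totals within Monte-Carlo error.
* Problem sizes in tests are scaled to desk conditions (10-year windows for
  most experiments, 27 years for the recovery run; bootstrap coverage at
  8 years × 100 datasets × B = 100 with warm-started replicates). The
  scaled-down settings are stated next to each experiment.
* `log ω` coordinates are clamped to ±30 during optimization so exploratory
  steps cannot underflow `ω` to zero.
* Percentiles use numpy's linear-interpolation convention.
* Degenerate inputs: empty age classes yield flagged NaN prevalences and are
  excluded from objectives; one-year calibration windows run but are flagged
  weakly identified; a zero Dirichlet concentration is floored; CSV bundles
  are validated cell-by-cell with file/row context on failure, and reading
  uses round-trip float parsing so write → read → write is byte-identical.

## Known limitations

* The relapse block is weakly identified from prevalence data alone; report
  its uncertainty via the bootstrap bands, not the point values.
* PAF uses model-predicted deaths as the denominator; against external death
  registries the ratio would differ by the model's mortality misfit.
* The bootstrap treats the fitted model as the data-generating process
  (parametric); misspecification is not reflected in the intervals.
* Percentile intervals are pointwise; no simultaneous bands.
* Likelihood-based or ABC inference is out of scope.
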