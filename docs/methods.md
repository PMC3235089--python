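# Methods

This note documents the model as implemented: its assumptions, the
parameters that matter, the synthetic-data generator that stands in for
the real conditioning data, and the numerical choices a user re-deriving
results will want pinned down.

## Population process

The state is numbers-at-age (thousands of fish) by stock × age × area,
censused at the start of each calendar quarter (Q1 = Jan–Mar). Two stocks
share five areas: the western stock ranges over areas 1–4 (Gulf of Mexico,
Gulf of St. Lawrence, western Atlantic, eastern Atlantic), the eastern
stock over areas 3–5 (adding the Mediterranean); areas 3–4 are mixed.
Weights are in kg, so biomasses come out in tonnes.

Within one quarter the update order is fixed and documented so that every
oracle in the test suite can reproduce it:

1. **Mortality.** Quarterly total mortality `Z = M/4 + Σ_f F_f s_{f,a}`
   per stock/age/area. Fleet F's are solved from the observed quarterly
   catch-by-fleet-by-area (tonnes) via the Baranov catch equation, jointly
   across fleets in an area (they are coupled through Z).
2. **Movement.** Survivors move by the stock × age-group × quarter matrix.
3. **Recruitment.** In a stock's spawning quarter, age-0 recruits enter
   the spawning area. Recruitment is computed from spawning biomass at the
   *start-of-quarter census* and the recruits added after movement are
   discounted by one quarter of age-0 natural mortality, `R·e^{−M₀/4}`.
   This convention makes the quarterly discretization reproduce the annual
   per-recruit survivorship `l_a` exactly (for age-flat M), so the
   unfished spun-up state agrees with the analytic S0 and the spin-up is a
   fixed point to numerical precision. With age-varying M the agreement is
   approximate at the age-0/1 boundary (three quarters at M₀, one at M₁);
   the shipped defaults use flat M.
4. **Aging.** After Q4, ages shift with plus-group accumulation
   `N_A ← N_A + N_{A−1}` (both already survived the year).

Spawning-stock biomass is mature biomass summed over **all** areas at the
spawning-quarter census, not only the spawning area — under mixing, mature
fish may be elsewhere in the spawning quarter, and stock-level SSB is the
quantity of management interest. (Spawning-area-only SSB would be a
configuration away but is not exposed; noted as a limitation.)

### Catch conditioning

Fishing mortality is not estimated freely: catches are data, and F is the
value that removes them. Per area and quarter the solver runs a joint
multivariate Newton over the active fleets with the analytic Jacobian of
the Baranov equation, with a safeguarded per-fleet Gauss–Seidel fallback
(bracketing Newton) for capped or degenerate cases, to a relative
tolerance of 1e-8. F is capped at 2.0 per quarter; catch that cannot be
taken even at the cap is recorded as a shortfall on the trajectory rather
than raising, mirroring assessment practice where impossible removals
indicate data, not code, problems. Tests verify the solver against an
independent `scipy.optimize.brentq` bisection oracle and require realized
catches to match inputs to 0.1% wherever uncapped.

## Management-oriented initialization

Leading parameters per stock are MSY (tonnes/yr) and Fmsy (/yr). With an
aggregate selectivity s̄ (fleet-weighted mean; equal weights by default):

- survivorship `l_a = Π_{a'<a} e^{−(M+F s̄)}`, plus group closed as
  `l_A/(1 − e^{−Z_A})`;
- `φ_E(F) = Σ l_a m_a w_a`, `φ_q(F) = Σ l_a w_a s̄_a (1−e^{−Z})/Z`
  (the Baranov exploitation fraction per unit F; with rates constant
  within a year the four-quarter discretization telescopes to this
  annual form);
- Beverton–Holt in compensation form:
  `R_eq(F)/R0 = (κ − φ_E(0)/φ_E(F))/(κ − 1)`,
  `Y_eq(F) = F φ_q(F) R_eq(F)`.

κ solves `dY_eq/dF = 0` at Fmsy by bisection on (1+1e-6, 300] with a
central-difference derivative (h = 1e-5·Fmsy); the derivative is monotone
in κ on the bracket, and pairs with no sign change are reported as
infeasible leading-parameter pairs (this genuinely happens, e.g. when
selection acts so far after maturation that no compensation level puts the
yield maximum at Fmsy). R0 then scales the curve so Y_eq(Fmsy) = MSY,
giving S0 = R0·φ_E(0), B0, and B_MSY = R_eq(Fmsy)·φ_E(Fmsy). A brute-force
2-D grid oracle over (κ, R0) confirms the solution in the tests.

The derivation is deliberately non-spatial; space enters through a
25-year unfished spin-up. The spin-up seeds each stock's spawning area
with the unfished age structure translated to a Q1 census (ages carried
back (q_spawn − 1) quarters; no age-0 at Q1, since ages increment at the
year boundary) — seeding the spawning-quarter structure directly would
leave a plus-group transient that decays only at e^{−M} per year.

## Movement

Gravity base case: one retention probability µ_jj per (stock, age-group,
quarter, area), off-diagonals uniform at `(1−µ_jj)/(n−1)`. The estimation
surface optionally shares one retention per (stock, area) across age
groups and quarters (`gravity_sharing="area"`), which is what the reduced
recovery experiments use. A bulk-transfer mode (full row weights,
normalized) exists at the module level for simulation and sensitivity
work; the estimator itself uses the gravity form, the base case.

Spawning override: in the spawning quarter each row sends probability *m*
to the spawning area, where *m* is maturity at the age group's mid age
(movement is by age group but maturity by age; the mid-age value is the
minimal reconciliation, configurable in principle to per-age matrices).
The remaining 1−m follows the base row renormalized over non-spawning
destinations; the override *replaces* the base retention for fish already
in the spawning area rather than compounding with it. It applies to both
age groups — juveniles with m ≈ 0 are essentially unaffected, so no
special case is needed.

## Observation models

- **CPUE** (lognormal, concentrated): for series with observations I_t and
  predicted vulnerable biomass V_t (both stocks, the linked fleet's
  selectivity, the series' area/quarter census),
  `z_t = ln I_t − ln V_t`, `ln q̂ = mean(z)`, and
  `NLL = (n/2)·ln Σ(z_t − ln q̂)²` up to constants — catchability and the
  error variance are both concentrated out, so the fit is invariant to
  rescaling a series.
- **Catch-at-age** (multinomial): predicted proportions come from the
  solved F, selectivity and numbers, aggregated over the western (areas
  1–3) or eastern (areas 4–5) region and the year's four quarters, ages
  1–10+. `NLL = −N_eff Σ obs·ln pred` with N_eff = 50 per annual record by
  default (configurable; standard assessment practice, since composition
  records overstate their nominal sample sizes). A lognormal-by-age
  alternative was considered and left out; multinomial is the conventional
  choice for proportions that sum to one.
- **Otolith microchemistry** (binomial): n_west of n_total, with p the
  predicted western share of vulnerable numbers in that area/age-group
  (school ≤ 4, medium 5–9, giant 10+) at that time.
- **Conventional tags** (negative binomial): cohorts (same release area,
  quarter and assigned age) are propagated with the same survival,
  movement and quarterly shedding (λ = 0.02 default) as the population;
  expected recaptures are tags-present × per-fleet exploitation ×
  reporting rate. NB is parameterized by mean and dispersion r
  (var = m + m²/r), one dispersion per tag program, estimated; r → ∞
  recovers Poisson (verified against scipy in tests). Unknown-origin
  cohorts (85% in the emulated program) are mixed:
  `NLL = −ln Σ_i w_i e^{−NLL_i}` with weights w_i the vulnerable-numbers
  ratios in the release area at release time, held fixed within the
  cohort to avoid circular reweighting. Reporting rates take a normal
  prior by default (mean 0.2, sd 0.1 — a placeholder magnitude, since the
  published reporting-rate analysis is external); beta(3,3) and
  N(0.1, 0.065) alternates are config options.
- **Electronic tags** (hidden Markov): states alive-in-area (local to the
  stock's accessible areas) plus absorbing captured / natural-death /
  shed. From alive-in-j: captured with the all-fleet exploitation u_j,
  natural death with d_j = (M/4 / Z)(1−e^{−Z}), shed with λ, remainder
  distributed by the movement row. Pop-up satellite tracks have complete
  quarterly positions (observation probability 1); archival tags yield a
  position with a single estimated probability p_obs, and a missing
  quarter contributes the scalar factor (1 − p_obs) to *every* state — a
  Bernoulli observation failure carrying no area information. Track end
  (pop-off or recovery) is treated as right-censoring, not as an observed
  event. Tag age crosses the juvenile/adult movement boundary at calendar
  year ends exactly as the population does. The forward recursion is
  verified against exhaustive path enumeration for tracks of length ≤ 4.

Proportion-type predictions are clamped to [1e-6, 1−1e-6] before logs so
structural zeros (e.g. a western cohort "recaptured" in the Mediterranean)
penalize heavily but never produce infinities during optimization.

## Estimation

Free parameters (selected per fit): log MSY and log Fmsy per stock; logit
gravity retentions (full, or shared per stock × area); log logistic
selectivity (a50, slope) per fleet; logit reporting rates; logit archival
p_obs; log NB dispersion; optional recruitment deviations (σ_R config,
default 0 — deviations off — with 0.4 the suggested value when fitting
variable synthetic data). All transforms round-trip to 1e-12.

MAP uses L-BFGS-B in the transformed space; non-finite objective values
during line search are replaced by a large penalty, and failure to improve
sets a non-converged flag rather than raising. MCMC is adaptive
random-walk Metropolis: a joint Gaussian proposal scaled by a diagonal
curvature estimate at the mode, global step size adapted toward 0.3
acceptance during the first half of each chain, six chains by convention,
initialized by 5% multiplicative jitter around the MAP, thinned by 10.
Convergence uses classic Gelman–Rubin PSRF per parameter plus the
Brooks–Gelman multivariate (maximum-eigenvalue) version with the < 1.05
stopping rule; identical constant chains report 1 by convention. Posterior
summaries are boxplot statistics (median, quartiles, 1.5·IQR whiskers)
with type-7 (linear) quantile interpolation, pinned so test expectations
are exact.

## Projections

Scenarios fix future annual catches west and east of the 45° meridian
(west = areas 1–3, east = areas 4–5, which nest within the split) from the
year after the data horizon to 2025: (i) 0/0, (ii) 1750/12,900 t,
(iii) as (ii) with the Gulf of Mexico closed and its share moved to the
western Atlantic (area 3 only — the Gulf of St. Lawrence is not named by
the closure), (iv) 1750/25,800 t, (v) 1750/60,000 t. Annual side totals
are distributed over fleet/area/quarter cells by the mean allocation of
the last five data years (uniform fallback with a warning if a side has no
history). Each posterior draw projects from its own terminal state with
catch-conditioned dynamics and its own stock-recruit curve; future
recruitment deviations are off by default (median-deterministic
projections per draw), with a lognormal option. B_MSY is computed per draw
from that draw's parameters, not a point estimate.

## Synthetic data

The generator defines the package's study conditions. `default_truth`:

- **paper-like**: 1950–2008 horizon, MSY 3.9 kt (west) / 25 kt (east),
  Fmsy 0.15 / 0.20, ~600 electronic tags.
- **reduced** (the test scale): 20 years (1989–2008), plus group at 12,
  ~10× smaller tag programs (60 electronic tags, two conventional cohorts
  per program-year of 400 releases), chosen so a full
  simulation–estimation replicate fits in tens of seconds.

The effort history is a two-phase ramp — western fishing rising to an
annual peak of 0.35/yr mid-horizon then declining, eastern fishing rising
late to 0.4/yr — which depletes the stocks to roughly 0.15–0.3 of initial
SSB and gives the estimator the contrast a real assessment relies on. The
truth run uses specified F; its realized Baranov catches become the
conditioning data, so catch-conditioned re-estimation is exactly
consistent. Observation noise: CPUE lognormal σ = 0.2 with mean-one
bias correction (six annual series across the five areas); multinomial
catch-at-age with N_eff = 100; binomial otolith samples of 25 in the mixed
western Atlantic for all three age groups every third year; NB recapture
counts at dispersion 2; archival tracks with p_obs = 0.9 gaps. 85% of tag
cohorts and tracks carry unknown stock of origin, matching the real
program's composition. Truth specifications serialize to YAML and
round-trip exactly.

What the generator does **not** emulate: CPUE standardization artifacts
and catchability trends, age-reading error, time-varying selectivity or
weight, discards, daily-scale tag geolocation error, and environmental
movement variability. Passing recovery tests therefore demonstrate
internal consistency of the estimator under the model's own assumptions,
not robustness to the misspecifications real data carry.

The shipped default biology (flat M = 0.14/yr, ~400 kg asymptotic weight,
maturity a50 of 9 west / 4 east) is a clearly-labelled placeholder with
bluefin-like magnitudes: growth, mortality and maturity inputs are
conventionally taken from external studies and must be supplied by the
user for any real application. All shipped tests use synthetic biology.

## Numerical choices and degenerate inputs

- Movement rows are validated to sum to 1 within 1e-12; movement conserves
  numbers to 1e-9 over a full unfished horizon.
- The eastern-catch under-reporting adjustment scales Mediterranean (area
  5) cells only — the under-reporting is attributed to the Mediterranean —
  by one factor per year so the areas 4+5 total hits the assumed level
  (50 kt for 1998–2006, 60 kt for 2007); it is exact, idempotent, and
  errors when the Mediterranean catch is zero but the target is above the
  remaining eastern total (the factor is undefined). Whether to scale the
  whole eastern side instead is a data-preparation choice left to the
  caller via the `east_areas`/`med_area` arguments.
- Catches for the final data year are taken from the table as supplied;
  assumptions equating recent catches with quotas belong to data
  preparation, not the model.
- CPUE residual sums of squares are floored at 1e-12 inside the log so a
  perfectly proportional series stays finite.
- Simulation–estimation at the reduced scale (10 replicate seeds, MAP with
  the area-shared gravity surface, 50 quasi-Newton iterations) recovers
  MSY, Fmsy and gravity retentions with pooled median absolute relative
  error around 7%, within the 15% acceptance bound; individual parameters
  (notably Fmsy, which trades off against MSY along the yield curve) can
  err by 25–30% on single replicates.

## Known limitations

- Recruitment deviations are implemented but default off; the reduced
  recovery suite fits deterministic-recruitment truths.
- Reporting-rate eras: a single era (one rate per fleet) in the base case;
  the era structure is a config extension point, not exercised by tests.
- Three-stock (intra-Mediterranean) structure, management strategy
  evaluation, environment-dependent movement and raw geolocation
  processing are out of scope.
- The equilibrium derivation assumes the aggregate selectivity; when fleet
  selectivities are estimated, the aggregate moves with them, which is the
  intended coupling but means κ and B0 are conditional on the selectivity
  weighting chosen.
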