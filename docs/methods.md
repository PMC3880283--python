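# Methods

`aidequity` implements, end to end, an equity analysis of health aid on
household-survey microdata: does an additional dollar of health aid per
capita reduce under-5 mortality more among poorer households than among
wealthier ones?  Because the microdata that motivate the design (pooled
Demographic and Health Surveys joined to a development-assistance panel) are
access-restricted, the package centres on a synthetic-data generator with
known truth, so that every stage of the analysis — wealth stratification,
rate estimation, panel regression — can be validated by parameter recovery.

## The statistical model

The estimating equation is a two-way fixed-effects interaction regression on
(country `c`, calendar year `t`, wealth quintile `q`) cells:

```
M_ctq = Σ_q β_q W_q + γ A_{c,t-ℓ} + Σ_q δ_q (W_q · A_{c,t-ℓ})
        + θ E_cq + φ G_ct + ψ U_ct + α_c + τ_t + ε_ctq
```

where `M` is the under-5 mortality rate (deaths per 1,000 child-years, or
its natural log), `W_q` are wealth-quintile indicators with quintile 1
(wealthiest) as the reference stratum, `A` is health aid per capita in
constant 2010 USD lagged `ℓ` years (default 1), `E` is the median years of
maternal education in the stratum, `G` government health spending per
capita, `U` the urban population share, and `α_c`, `τ_t` country and year
fixed effects.  The coefficients of interest are the interactions `δ_q`: the
extra change in mortality per aid dollar in quintile `q` relative to the
wealthiest.  In the log model `100·δ_q` reads as a semi-elasticity (percent
mortality difference per dollar); output reports `100·(exp(δ)−1)` alongside.

Estimation is OLS with the fixed effects entered as explicit dummies (at
≤ 49 countries and ~20 years this is cheap, and equality with the
within-transformation is a test, not an option).  Inference uses the
cluster-robust sandwich covariance grouped by country,

```
V = (XᵀX)⁻¹ (Σ_c X_cᵀ ê_c ê_cᵀ X_c) (XᵀX)⁻¹ · G/(G−1) · (N−1)/(N−K)
```

with p-values from t(G−1), the convention of mainstream econometric
software, so that standard errors are comparable with published panel
analyses of this design.  The regression is unweighted by default (survey
weights are consumed at the rate-estimation stage, not the regression
stage); exposure weighting is available as an option.  R² is the overall R²
of the dummy regression.  Robustness variants: aid lag 0–3, log outcome,
malaria-specific aid in place of total aid, and a lagged-dependent-variable
term (plain OLS, not a GMM dynamic-panel estimator).

## Under-5 mortality from birth histories

The rate denominator is the number of full months lived under age five
inside the 120-month recall window preceding each survey interview, summed
with survey weights and divided by 12; the numerator is the weighted count
of under-5 deaths in the same window.  Month conventions (months are DHS
century month codes, January 1900 = 1):

* a child contributes exposure for months `m` with
  `birth ≤ m < min(birth+60, death month, interview)` and
  `m ≥ interview − 120`;
* the interview month contributes nothing (partial month discarded);
* the death month is `birth + age_at_death_months` and contributes no
  exposure (death placed at month start) — age at death is month-granular,
  so some convention is required, and this one keeps the exposure
  arithmetic exactly enumerable;
* months are bucketed into calendar years by their own year; a death is
  counted in the year of its death month when that month is in-window.

Cells with zero exposure are omitted.  When several surveys of one country
overlap in calendar time, their children pool into the same cells (weighted
union), preserving the deaths/exposure definition of the rate.  Median
maternal education is the weighted median (lower of two middle values on
ties) per (country, quintile, survey), carried to that survey's years.

## The pooled wealth index

Households are scored by the first principal component of ten binary
asset/service indicators (improved water, improved sanitation, finished
floor, electricity, radio, television, phone, refrigerator, motorcycle, car)
plus rooms per person, pooled across all surveys so scores are comparable
across countries ("absolute" rather than survey-relative wealth).  The
implementation standardizes each variable by its weighted mean and SD
(eigen-decomposition on the weighted correlation matrix, the standard DHS
construction), weights households by the share of the pooled national
population their survey represents (so very large surveys do not dominate),
and removes per-year weighted means of the standardized variables before
the decomposition — the "year effects" — to absorb common secular drift in
asset ownership.  Residualizing per-year means was chosen over appending
year dummy columns to the PCA input as the simplest construction that
removes common wealth drift without letting survey timing load on the
index; rooms per person is treated as continuous and standardized like the
binary indicators.  Loadings are sign-normalized so the score increases
with wealth (positive electricity loading).  Quintiles (1 = wealthiest,
5 = poorest) come from weighted 20/40/60/80 percentile cutpoints; ties at a
cutpoint go to the poorer quintile.

## The synthetic-data generator

The generator emulates the study conditions end to end; its defaults are
the package's reference scenario, not tuning knobs.

* **Study frame.** 30 countries observed 1993–2012; two surveys per country
  (survey years 2002 and 2012), each interviewed in the January following
  the survey year so its 120-month recall window covers exactly ten
  calendar years; 600 households per survey at the default scale, giving
  roughly 50,000 births per run.
* **Wealth and assets.** Latent wealth z ~ Normal(0, 1); each asset owned
  with probability logistic(a + b·z), with (a, b) per asset chosen to
  reproduce published ownership gradients (electricity ~1% among the
  poorest fifth and ~100% among the wealthiest; car rare everywhere but
  concentrated at the top).  The analysis never sees z: quintiles are
  recomputed from assets, so wealth-index misclassification is part of
  every downstream experiment by design.
* **Fertility.** Births per household are Poisson with quintile-specific
  means (0.9 … 1.9, poorer households more births), reproducing the
  empirical pattern that exposure falls with wealth; birth months are
  uniform over the recall window.
* **Mortality.** Survival is simulated month by month: in each lived month
  the child dies with probability `rate(c, year, q)/12000`, where the
  expected cell rate is `12000·h_q + shift_c + trend·(year−y0) +
  (γ + δ_q)·A_{c,year−1}` under the linear form, with baseline monthly
  hazards `h_q` set from published period rates (7.9 … 36.9 per 1,000
  child-years), country shifts ~ Normal(0, 2), a common secular trend of
  −0.15 per year, and the aid terms as configured.  A proportional form
  (terms act on log rate) supports semi-elasticity experiments.  Rates are
  floored at 0; the defaults keep the floor inactive for >99% of country
  draws so the linear estimand stays well defined.  The generator applies
  aid with a 1-year lag, aligning its truth with the default estimator lag.
* **Aid and covariates.** Country aid trajectories are level + trend + noise
  (total aid: levels U(1,12) $/capita, trends U(0,1) $/yr, noise sd 0.8;
  malaria aid about a quarter of that scale), reflecting the strong
  cross-country heterogeneity of the 1993–2012 aid scale-up.  After country
  and year effects are absorbed, it is precisely this trend heterogeneity
  that identifies δ_q.  Education, government health spending and
  urbanization vary across countries and quintiles but have no causal role,
  so their regression coefficients have expectation 0.

What the generator does **not** emulate: within-country cluster sampling
(survey weights are i.i.d. around 1), recall bias and survey non-response,
HIV-specific mortality, and within-household correlation of sibling
deaths beyond the shared hazard.  Passing recovery tests therefore
demonstrates the correctness of the estimation chain under the stated
design, not robustness to those real-data complications.

## Parameter-recovery experiments and problem sizes

The package's acceptance surface is recovery of the poorest-quintile
interaction δ₅ through the full pipeline (assets → index → quintiles →
cells → FE fit), with published coefficient sets as generator truth:

* **linear / total aid** (truth δ₅ = −0.57) and **linear / malaria aid**
  (truth δ₅ = −5.36): 30 countries × 20 years, ~50,000 births per
  replicate.  Per-replicate sampling error is large at this scale (cells
  hold ~60 child-years each), so results are reported as replicate means
  with Monte-Carlo standard errors; the test criterion is agreement within
  3 MC SEs plus ≥85% coverage of the nominal 95% clustered CIs (clustered
  inference with 30 clusters is mildly anti-conservative, hence the 85%
  bar rather than 95%).
* **log / total aid** (truth 100·δ₅ = −1.9% per dollar): run at ~2,700
  child-years per cell (27,000 households per survey, ~2.2M births per
  replicate).  The log of a small-count rate is biased (Jensen curvature
  plus the exclusion of zero-death cells), and at ~60 child-years per cell
  this artifact, not the estimand, dominates; real pooled cell tables of
  this design have ~1,700 child-years per cell, so the high-exposure
  regime is the faithful one.  Measured recovery at this scale is
  −0.0199 ± 0.0008 (oracle quintiles) and −0.0188 ± 0.0006 (full pipeline).

Quintile misclassification from the asset-based index (deliberate, see
above) attenuates the linear δ₅ by roughly 4–5% toward zero — the assigned
poorest quintile is a ~3:1 mixture of truly-poorest and fourth-quintile
households whose interaction truths are adjacent (−0.57 vs −0.51).  This is
a property of the study design itself, visible in the recovery means
(≈ −0.545 for total aid), and sits well inside the Monte-Carlo tolerance.

## Numerical and reporting choices

* Zero-mortality cells are dropped (not offset-shifted) under the log
  transform; rows whose lagged aid year precedes the panel are dropped with
  a logged count; the LDV variant drops rows without a prior-year cell.
* Rank deficiency raises an error naming the collinear columns (QR with
  column pivoting); a single cluster is rejected.
* Trend curves use an Epanechnikov-kernel local polynomial fit (default
  degree 6) of the raw annual cell rates per quintile; the bandwidth is not
  canonical and defaults to leave-one-out cross-validation over a small
  grid; pointwise bands use the linear-smoother variance with a global
  residual-variance estimate.  Grid points whose kernel window contains
  fewer than degree+1 distinct years return NaN, and quintiles with fewer
  than degree+2 distinct years are skipped with a warning.
* Weighted quantiles are type-1 (lower); quintile cutpoint ties go to the
  poorer quintile; the weighted median takes the lower of two middle values.
* All randomness flows from a single integer seed through per-operation
  streams, so any table is reproducible in isolation; identical
  configurations produce byte-identical output files.

## Known limitations

* The generator's i.i.d. survey weights understate real design effects;
  clustered SEs here reflect only country-level serial correlation.
* The log-model experiments require large per-cell exposure; at small
  scales the package will faithfully reproduce the small-count bias of the
  log specification rather than hide it.
* The education covariate is quasi-collinear with quintile dummies when its
  quintile gradient is identical in every country; the generator's
  country-level variation avoids this, but degenerate user configurations
  can trigger the collinearity error by design.
* No Brass-type indirect estimation, no jackknife sampling errors on the
  rates, and no dynamic-panel (GMM) estimation — the LDV check is plain OLS.
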