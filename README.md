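# aidequity

**Does health aid reach the poor?**  `aidequity` is a reusable pipeline for
an equity analysis of health aid on household-survey microdata: it estimates
under-5 mortality by wealth stratum from complete birth histories, builds a
pooled asset-based wealth index that is comparable across countries, and
fits two-way fixed-effects regressions of mortality on the interaction of
lagged health aid per capita with wealth quintile.  It is aimed at
epidemiologists and health economists working with DHS-style survey data
joined to country-year aid panels — and, because such microdata are
access-restricted, it ships a synthetic-data generator with known ground
truth so the entire chain is testable by parameter recovery.

## The model

For country *c*, year *t* and wealth quintile *q* (1 = wealthiest, the
reference stratum, … 5 = poorest):

```
M_ctq = Σ_q β_q W_q + γ A_{c,t-1} + Σ_q δ_q (W_q · A_{c,t-1})
        + θ E_cq + φ G_ct + ψ U_ct + α_c + τ_t + ε_ctq
```

* `M_ctq` — under-5 deaths per 1,000 child-years of exposure in the cell,
  estimated from birth histories over the 10-year recall window of each
  survey, with survey weights;
* `A` — health aid per capita (constant 2010 USD), lagged one year; total
  or malaria-specific;
* `W_q` — quintiles of a pooled wealth index: the first principal component
  of ten household asset indicators plus rooms per person, weighted by each
  survey's share of the pooled national population, with year effects
  removed before the decomposition;
* `E, G, U` — median maternal education, government health spending per
  capita, urban share;
* `α_c, τ_t` — country and year fixed effects; standard errors are
  cluster-robust by country with a small-sample correction and t(G−1)
  inference.

The interactions `δ_q` are the quantities of interest: the extra mortality
change per aid dollar in quintile *q* relative to the wealthiest.  A log
outcome turns them into semi-elasticities (percent per dollar).  See
`docs/methods.md` for conventions, the generator design and its limits.

## Worked example

Generate a 30-country synthetic study whose true poorest-quintile
interaction is −0.57 deaths per 1,000 child-years per aid dollar, then run
the whole pipeline in memory:

```python
from aidequity import FEModelSpec
from aidequity.pipeline import run_synthetic_analysis
from aidequity.recovery import linear_total_config

res = run_synthetic_analysis(linear_total_config(seed=7), FEModelSpec())
print(res.fit.format_report())
```

```
Two-way fixed-effects regression of under-5 mortality
outcome: rate per 1,000 child-years, aid: total, lag 1

Wealth quintile (vs 1 - wealthiest):
  2                        3.096   2.860 (p=0.288)
  3                       12.351   4.011 (p=0.005)
  4                       24.751   4.976 (p=0.000)
  5 - poorest             20.046   5.010 (p=0.000)
Aid                        0.778   0.325 (p=0.023)
Wealth*aid (vs 1 - wealthiest):
  2                       -0.115   0.167 (p=0.497)
  3                       -0.181   0.232 (p=0.441)
  4                       -0.721   0.228 (p=0.004)
  5 - poorest             -0.443   0.209 (p=0.043)
Maternal education        -1.073   1.188 (p=0.374)
Gov't health spending     -0.135   0.103 (p=0.202)
Urbanization              13.050   26.743 (p=0.629)

Observations            3000
R^2                     0.10
Clusters (countries)    30
```

Reading this: mortality levels rise steeply toward the poorest quintile
(the β rows), and each aid dollar is associated with a *larger* mortality
decline among the poorer quintiles (negative δ rows) — here the single
replicate estimates δ₅ = −0.44 ± 0.21 against a simulated truth of −0.57;
one ~50,000-birth study is noisy, which is why the validation experiments
average many replicates.  The quintile-level fixture summary
(`aidequity.pipeline.fixture_period_summary()`) shows the corresponding
descriptive pattern in the packaged reference table: a 37.7% mortality
decline among the poorest against 10.1% among the wealthiest between
1993–2000 and 2005–2012.

The same run is available from the shell, staged and fully logged:

```sh
aidequity all --seed 7 --out runs/demo          # generate → index → rates → fit → report
aidequity fit --out runs/demo                   # re-fit from the written tables
```

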