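# healthmarkov

Latent Markov health-state models, morbidity scenarios and health-expenditure
projections for ageing populations.

Whether population ageing drives health-care spending up depends on whether
extra life years are lived in good or poor health — and different dimensions
of health (chronic disease, disability, mental health) are trending in
different directions. `healthmarkov` implements, end to end, the modelling
pipeline that studies this question: a hidden-Markov ("latent Markov") model
of health in older adults estimated on intermittently observed panel data,
three classic morbidity hypotheses (expansion of morbidity, compression of
morbidity, dynamic equilibrium) encoded as calibrated adjustments to the
model's transition probabilities, and a cohort-component projection of the
65+ population and its hospital, home-care and institutional long-term-care
(LTC) expenditures from 2010 to 2050.

It is intended for health economists and epidemiologists who want to run
morbidity-scenario analyses, and ships with a fully synthetic data generator
emulating a linked survey–registry panel, so every stage runs and is tested
without any restricted data.

## The model

An unobserved health state η<sub>i,t</sub> ∈ {good, moderate, poor, death}
evolves by annual first-order Markov transitions,
P(η<sub>t</sub> = m | η<sub>t−1</sub> = l; x<sub>t</sub>), modelled as a
separate multinomial logit per origin state with covariates sex, partner
status, age and education; death is absorbing. Given the state, the
measurement component emits

* seven categorical health indicators y<sup>1</sup>…y<sup>7</sup>
  (self-perceived health, mobility, a timed performance test, GALI activity
  limitation, chronic-disease count, CES-D depression, MMSE cognition), each
  an intercept-only multinomial logit per state; and
* annual per-service costs c through a two-part model — a use logit times a
  Gamma GLM with log link for positive amounts — with sex, partner, age,
  education and calendar-year dummies as covariates.

The observed-data likelihood of one individual sums over all state paths:

P(c, y | x, θ) = Σ<sub>m₀…m_T</sub> P(η₀=m₀) ∏<sub>t</sub> P(η_t=m_t | η_{t−1}=m_{t−1}; x) ∏<sub>t</sub> g<sub>m_t</sub>(c_t, y_t | x_t)

Indicators are observed only every third year (and death is observed
exactly, through vital status); in the intervening years the emission term
g<sub>m</sub> reduces to the cost density alone. Estimation is by EM:
forward–backward recursions compute smoothed state posteriors, and the
M-step re-fits all component models by posterior-weighted maximum
likelihood. Home-care and LTC costs, observed only in a late registry
window, are fitted ex post against the converged posteriors.

Scenarios start from a target remaining life expectancy (LE) at 65 in 2050
— 21.1/24.6 years (men/women) in the standard variant, 24.1/27.6 in the
optimistic one — and reach it through different mechanisms, each a single
annual proportional adjustment (1 − x)<sup>year − 2010</sup> applied to
selected transition probabilities and solved for x by bisection on the
period life table. The dynamic-equilibrium scenarios solve a second rate so
that expected years in poor health stay at their baseline value; the
compression and dynamic variants with a "+" additionally ramp the entrant
health profile at 65 linearly to 100 % good health (or 45 % moderate) by
2050.

## A worked example

```python
import healthmarkov as hm
from healthmarkov.scenarios import ScenarioModel

truth = hm.make_default_truth(seed=1)          # synthetic ground-truth model
specs, reports = hm.calibrate_all(truth, ["baseline", "1o", "2o"])

for sid in ("baseline", "1o", "2o"):
    lt = ScenarioModel(truth, specs[sid]).life_table(sex=0, year=2050)
    lc = hm.lifetime_costs(ScenarioModel(truth, specs[sid]), sex=0, year=2050)
    print(sid, lt.total, lt.by_state, lc.total("hospital"), lc.total("ltc"))
```

prints (men, cost units, LE in years):

```
baseline LE 14.97 = good 5.91 + moderate 5.55 + poor 3.51;  lifetime hospital  32005  ltc  46858
1o       LE 21.10 = good 6.42 + moderate 7.14 + poor 7.54;  lifetime hospital  63741  ltc 140451
2o       LE 21.10 = good 10.17 + moderate 8.31 + poor 2.62;  lifetime hospital  41543  ltc  56225
```

Both scenarios hit the same 2050 life expectancy of 21.1 years, but they get
there differently: under expansion of morbidity (`1o`, mortality falls with
health unchanged) the extra years are spent disproportionately in poor
health and lifetime LTC costs triple relative to baseline, whereas under
compression (`2o`, health improves) poor-health years *fall* below baseline
and costs rise only modestly. Projected aggregate expenditure growth over
2010–2050 tells the same story:

```
baseline growth %/yr: hospital 0.08  homecare 0.15  ltc 0.16
1o       growth %/yr: hospital 1.44  homecare 1.95  ltc 2.21
2o       growth %/yr: hospital 0.34  homecare 0.40  ltc 0.06
```

The full pipeline — simulate a panel, fit the model by EM, calibrate all
nine scenarios, project and report — is also available from the shell:

```bash
healthmarkov simulate --config config.yaml --out run/
healthmarkov fit run/panel.csv --config config.yaml --out run/
healthmarkov scenarios run/fitted_model.json --config config.yaml --out run/
```

## Layout

| module | contents |
| --- | --- |
| `healthmarkov.synthetic` | seeded panel generator and the default ground truth |
| `healthmarkov.panel` | panel container, CSV round-trip, observation schedules |
| `healthmarkov.emissions`, `.likelihood` | emission models, forward–backward, brute-force oracle |
| `healthmarkov.model` | `LatentHealthModel` / `LatentHealthResults` (EM, labelling, ex-post cost fits, model selection) |
| `healthmarkov.scenarios` | morbidity operators, period life tables, LE calibration |
| `healthmarkov.projection` | cohort-component projection and microsimulation cross-check |
| `healthmarkov.outcomes` | lifetime costs, aggregate expenditure series, report bundle |
| `healthmarkov.cli`, `.config` | `healthmarkov` command-line pipeline and YAML configuration |

See `docs/methods.md` for the modelling conventions, default parameters and
known limitations.
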