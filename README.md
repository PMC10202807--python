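# maternalsim

A monthly-cycle microsimulation of women's reproductive life courses and
maternal mortality, with simulated-annealing calibration and posterior
predictive checks.

## The problem

Maternal deaths are hard to measure: they are rare relative to births,
spread over many clinical causes, and systematically underreported by
vital-registration systems.  Structural simulation offers a way through —
model each woman's pathway (fertility preferences, contraception,
conception, pregnancy loss, delivery care, obstetric complications,
death reporting) and fit the whole mechanism to the reported data that do
exist.  `maternalsim` is a desk-scale, fully testable toolkit of that
design, aimed at methodologists who want to study the estimation
machinery itself: every input is synthetic with recorded ground truth, so
calibration and coverage claims can be verified rather than assumed.

## The model in brief

Women age in monthly cycles in an open population.  Each cycle applies,
in fixed order: background mortality (with injury exclusion and indirect
maternal classification inside the risk window), aging, family-planning
updates, conception, pregnancy progression, and the postpartum year.
Deliveries pass through a three-delays care cascade over five sites
(Home < Home-SBA < nonEmOC < BEmOC < CEmOC): complication → recognition →
transport → referral, with preventive and curative interventions whose
applied effect is

    RR_applied = 1 − availability · quality · (1 − RR_efficacy).

Parameters carry five-level hierarchical priors (global → income group →
continent → region → country), composed additively on a transformed scale
(logit/log/identity), with damped linear time trends
`b + c·(1 − α^t)/(1 − α)`, `α ≤ 1`.

Six indicators are computed per country-year with 95% uncertainty
intervals (2.5/97.5 percentiles across iterations): MMR, pregnancy
mortality ratio, proportional mortality ratio, maternal mortality rate,
total maternal deaths, and lifetime risk of maternal death
(Σ age-specific rates, ages 15–49).

Calibration minimizes a posterior score — squared Poisson-scaled
distances to reported-death targets plus the prior's squared standardized
deviation — by simulated annealing with Metropolis acceptance, archiving
every evaluated parameter set; the best-100 sets are resampled over fresh
first-order seeds to propagate both stochastic and parameter uncertainty,
and posterior predictive checks report interval coverage, MAE and ME on a
held-out test split.  See `docs/methods.md` for assumptions, parameter
conventions and problem sizes.

## Worked example

```python
from maternalsim import (generate_synthetic_world, simulate_country,
                         tally_frame, indicator_suite, aggregate_tallies,
                         lifetime_risk)

world, truth, lifetables = generate_synthetic_world(
    n_countries=2, seed=7, years=(1986, 2000), report_from=1990, n_agents=1500)

tallies = [simulate_country(truth[c], lifetables[c], world.settings_for(c, seed=1))
           for c in world.countries]
pooled = aggregate_tallies(tallies, "both")
ind = indicator_suite(tally_frame(pooled).query("year >= 1991"))
print(ind[["mmr", "pregnancy_mortality_ratio"]].mean())
```

prints (seed 7, two synthetic high-burden countries of 1,500 agents,
burn-in 1986–1989 discarded):

```
country-pooled indicators, 1991-2000 mean:
  MMR                    574 per 100,000 live births
  pregnancy mortality    740 per 100,000 live births
  maternal mortality rate 95.1 per 100,000 women 15-49
  total maternal deaths  23 over the decade
  lifetime risk          3.33%
```

Read: at this world's true parameters, 574 of every 100,000 live births
cost the mother's life within 42 days of the end of pregnancy; counting
deaths from *any* cause in that window raises the ratio to 740; and a
15-year-old facing these rates for life has a 3.3% chance of eventually
dying of a maternal cause — levels typical of the highest-burden
settings.  The pregnancy mortality ratio can never fall below the MMR,
and total deaths equal the sum over the eight grouped causes; both
identities are enforced by tests.

The same workflows run from the shell via the CLI
(`maternalsim synth|simulate|calibrate|ppc|project --config cfg.yaml`),
which writes `indicators.csv`, `deaths_by_cause.csv`, `archive.json`,
`ppc_report.json` and a reproducibility manifest.

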