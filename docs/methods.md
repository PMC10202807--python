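# Methods

## Model overview

`maternalsim` is an individual-based microsimulation of women's
reproductive life courses and maternal mortality.  The engine follows an
open population of women in monthly cycles: new women enter each cycle at
age 10 (before any modeled event), age through sexual debut, contraception,
conception, pregnancy and its losses, delivery with an emergency-obstetric-
care pathway, and the postpartum year, while facing competing background
mortality at every age.  Indicators are aggregated per country-year and
reported with 95% uncertainty intervals after a burn-in period.

Within each cycle the event order is fixed and documented, because it
affects results at monthly resolution:

1. background (non-obstetric) mortality,
2. aging,
3. family-planning update,
4. conception attempt,
5. pregnancy-month update (ectopic resolution → induced abortion →
   miscarriage → antepartum stillbirth → delivery),
6. postpartum update,
7. new entrants.

## Geography and parameters

Countries sit at the bottom of a five-level tree (global → income group →
continent → region → country).  Every tunable quantity is a named scalar
on a declared transformed scale — logit for probabilities, log for rates
and relative risks, identity for coefficients — and its country value is
the inverse transform of the sum of a mean and an independent normal
offset at each level of the ancestor path.  Dispersions shrink at finer
levels, giving standard hierarchical pooling.  Age-structured rates are
stored per 5-year band (ages 10–50); compositional quantities
(contraceptive method mix, delivery-month distribution) are simplex
constrained and are not given independent normal offsets.

Secular trends are linear on the transformed scale in an effective time
`t_eff = (1 − α^t)/(1 − α)` with damping `α ∈ (0, 1]` — the partial
geometric sum, which equals `t` undamped, is weakly monotone, and
saturates at `1/(1 − α)`, so damped projections cannot extrapolate to
unreasonable levels.  Trends are flat before the reference year 2000.

## Demography

Background mortality uses female lifetables (annual probability by single
age and year, converted to monthly via `m = 1 − (1 − q)^(1/12)`).  A
fixed share of background deaths are injuries, which are never maternal
(accidental and incidental causes are excluded from the maternal
definition).  Non-injury background deaths of women who are pregnant or
within the first postpartum cycle are classified indirect maternal with
probability `demog.p_indirect`; all deaths in that window count as
pregnancy-related regardless of cause.  The 42-day maternal window is
approximated at monthly resolution as pregnancy plus one full postpartum
cycle; the late maternal window is postpartum cycles 2–12.

Poststratification weights (iterative proportional fitting / raking) are
available to re-weight simulated subgroup × age composition toward
external marginal targets, absorbing migration and differential mortality
the simulator does not model explicitly.  Raking is exposed as a module
(`raking_weights`, general IPF over any non-negative table) together with
tallied per-year subgroup and single-age person-month margins; the
default engine run does not consume migration targets (the synthetic
world defines none), subgroup-only reweighting is the supported default,
and a caller supplying a joint subgroup × age table can rake both
dimensions at once.

## Reproduction and family planning

Unprotected conception follows age-banded fecundability, multiplied by a
lactational-amenorrhea factor for up to nine months postpartum
(exclusive breastfeeding suppresses more strongly); contraceptive users
face only their method's monthly failure probability.  At conception the
number of fetuses (monozygotic constant plus age-banded dizygotic
twinning) and sexes (primary sex ratio) are drawn, along with an ectopic
flag (age-banded naive incidence, elevated by a prior ectopic) and the
scheduled delivery month (categorical over gestational months 7–10).
Miscarriage hazard applies in gestational months 1–5 (doubled boundary
documented: the sources distinguish early loss from stillbirth but give
no month cut), antepartum stillbirth from month 6 with a male excess risk.
Menopause is a per-woman truncated-normal draw within 40–60 years;
hemoglobin is normal by subgroup, with anemia below 11 g/dL in pregnancy
and 12 g/dL otherwise (standard WHO cut-offs).

Fertility intention each cycle: women at or above their desired family
size (inflated-Poisson draw) are *limiting*; below it they are *spacing*
within a 24-month window of the last birth and *want a birth soon*
otherwise.  Wanting a birth soon discontinues any non-permanent method.
Women with need (spacing or limiting) and no method adopt at a monthly
hazard derived from the met-need level (annual-to-monthly conversion, so
the met-need trend acts as an adoption propensity rather than an imposed
prevalence); methods have exponential spell durations with a
switch-versus-discontinue decision at expiry, and permanent methods are
absorbing.  Unintended pregnancies (conceived while limiting or under a
failing method) face a single abortion decision at gestational month 2
(within the documented months 1–4 window): abortion probability follows a
logistic year trend, elevated for all-female pregnancies by exactly the
amount that maps the primary to the secondary sex ratio in expectation
(`p_f = 1 − (1 − p)·SR₁/SR₂`); the unsafe fraction follows its own trend,
with anemia-modified case fatality and an infertility risk for unsafe
abortion survivors.

## Care pathway

Antenatal care is a two-part model (any-visit Bernoulli, then positive
Poisson); visits raise hemoglobin and complication recognition linearly.
Deliveries start at one of five sites ordered by emergency obstetric care
capability (Home < Home-SBA < nonEmOC < BEmOC < CEmOC), drawn from a
year- and subgroup-specific multinomial; elective C-sections occur only
at BEmOC/CEmOC and raise subsequent sepsis risk.

Five direct complications are drawn independently per delivery with
individual risk multipliers (pre-eclampsia/eclampsia: age, anemia,
multiple gestation, history; obstructed labor: age; hemorrhage: anemia;
sepsis: anemia and C-section), a severity split, and preventive
interventions applied to incidence (uterotonic third-stage management for
hemorrhage, clean delivery for sepsis) while the partograph boosts
recognition of obstructed labor.  The three-delays cascade then runs per
complication: recognition (site-, severity- and ANC-dependent) →
transport availability → referral target allowing bypass to CEmOC and
horizontal transfer, capped at two hops (unbounded chains are
unrealistic).  Case fatality depends on type, severity and treatment site
(a fixed site gradient times a calibratable severe-case CFR, with
non-severe cases a fixed fraction), reduced by curative interventions via

    RR_applied = 1 − availability · quality · (1 − RR_efficacy),

a linear interpolation between no effect and full efficacy; site quality
κ scales fatality reduction only, never incidence.  At most one maternal
death is recorded per woman; simultaneous fatal draws resolve in a fixed
priority order (hemorrhage, sepsis, hypertensive, obstructed, other
direct) for deterministic cause bookkeeping.  Severe complications that
never reach adequate care, and maternal deaths, impose an intrapartum
stillbirth risk per fetus.  A monthly late-maternal hazard acts in
postpartum cycles 2–12.

Reported deaths are true maternal deaths thinned by a capture
probability (logistic in year, by site of death), with survey capture
(active case finding) constrained at least as high as vital-registration
capture by a non-negative logit boost and nested uniform draws, so
reported counts never exceed true counts and survey counts never fall
below registration counts for the same deaths.

## Indicators

Six indicators per country-year: MMR (maternal deaths within the 42-day
window per 100,000 live births, late excluded), pregnancy mortality ratio
(all-cause deaths in the window per 100,000 live births — a superset, so
PMR ≥ MMR identically), proportional mortality (% of deaths of women
15–49 that are maternal), maternal mortality rate (per 100,000
woman-years 15–49), total maternal deaths (maternal + late), and lifetime
risk (sum of single-age maternal mortality rates over ages 15–49).
Maternal deaths outside 15–49 count in the MMR numerator but not in the
rate or lifetime-risk computations, mirroring the quoted definitions.
Uncertainty intervals are empirical 2.5/97.5 percentiles across
iterations, with linear interpolation between order statistics; counts
aggregate exactly across countries (regional additivity is integer
arithmetic).

## Synthetic world

The generator stands in for national data systems: Gompertz-like female
lifetables with a secular decline (level log-normally varied by country),
Dirichlet urban/rural × education composition around a rural-heavy
profile, and all behavioral/clinical parameters drawn from the
hierarchical priors with the truth recorded exactly.  Default parameter
levels describe a high-burden setting (MMR on the order of several
hundred per 100,000).  Calibration targets are reported CRVS deaths
(total and by the eight grouped causes) per country-year plus periodic
survey-source totals, generated by running the engine under the truth
with underreporting applied; they are tagged train (≤ 2015) / test
(2016+).

What the generator does *not* emulate: real age-schedule shapes (bands,
not splines), country-to-country correlation beyond shared upper-level
prior offsets, census-style target sources, COVID-era shocks, or
migration flows.  Passing tests therefore demonstrate internal
consistency and recoverability under the model's own assumptions, not
agreement with any real country's data.

## Calibration

Goodness of fit is the weighted sum of squared scaled distances between
predictions and targets.  Because desk-scale targets are small death
counts, the per-target scale in the recovery study is the Poisson
standard deviation √(obs + 1), making the score chi-square-like;
`goodness_of_fit` also offers the magnitude-normalizing `max(obs, 10)`
default and the unnormalized `s = 1` reading.  Cause-specific annual
counts are pooled into 5-year windows to keep per-target counts
informative; totals stay annual.

The fit score in the recovery study is a *posterior* score: the data
term plus the prior's squared standardized deviation per free
coordinate.  The parameters are random variables with hierarchical
priors, and with only a handful of reported deaths per cause the
likelihood alone is weak — an unpenalized fit would chase Monte-Carlo
noise along flat directions instead of shrinking to the prior.

Simulated annealing uses Metropolis acceptance `exp(−Δscore/T)` with
geometric cooling, proposals that perturb a Poisson-sized random subset
of coordinates plus 10% fresh prior draws, common random numbers (a
fixed first-order seed) across evaluations, and an archive of every
evaluated set.  The initial temperature is auto-set from probe moves to
target ~0.8 acceptance.  Most of the recovery-study run happens at a
temperature floor: at T = 2 a Metropolis chain samples the posterior of
a chi-square-scaled score exactly, but keeping only the 100 *best*
scores of a finite chain under-disperses relative to a posterior sample,
and common random numbers add realization noise the intervals must
absorb; the floor is therefore set at T = 8 (a tempering factor of 4,
proposal sd one prior dispersion), which makes the best-100 archive
deliberately conservative — marginals of roughly ±2 posterior standard
deviations.  Over-dispersion is the safe failure mode: it widens
prediction intervals rather than fabricating precision.  The best-100
sets are resampled uniformly with fresh first-order seeds for the
posterior iterations.  Posterior predictive checks report coverage of
the 95% intervals, mean absolute error and mean error, by train/test
split.

### Recovery-study problem sizes

Three countries × 800 agents each, years 1988–2019 (reporting from 1990,
train ≤ 2015), 12 free coordinates (four severe-case CFR logits per
country), targets averaged over 2 replicate runs, 600 annealing
evaluations with per-country memoization (unchanged countries are not
re-simulated), 40 posterior iterations.  These sizes keep a full study
under ~10 minutes on one CPU; they are the package's defaults, and all
statistical claims (≥80% truth recovery inside the central 80% of the
best-100 archive, test coverage within [88, 100]%) are evaluated at
these sizes.

## Numerical choices

* Monthly conversion of annual probabilities: `1 − (1 − q)^(1/12)`.
* Truncated-normal draws by inverse CDF (no rejection), important for
  small monthly entrant batches.
* Zero-truncated Poisson by inverse CDF conditioned on k ≥ 1.
* Per-run randomness: one PCG64 stream consumed in the fixed event
  order over stable array slots; reruns with the same configuration and
  seed are bit-identical.
* Probabilities pushed past 1 by stacked relative risks are clipped.
* Degenerate inputs raise: zero denominators (undefined indicators),
  non-normalized simplexes, negative dispersions, infeasible raking
  margins.

## Known limitations

### Information limits of desk-scale calibration

At the default problem sizes, several grouped causes yield only a few
*reported* deaths per country over the whole training window (sepsis and
abortive deaths especially, after severity splits and underreporting).
For those parameters the posterior is essentially the prior, so archive
intervals cannot be expected to bracket truths that happen to be drawn
far into the prior tails — and because upper-level prior offsets are
shared, such a draw moves all countries together.  Recovery fractions
across the free coordinates therefore fluctuate seed to seed around the
nominal interval coverage rather than sitting safely above it; this is a
property of the information content of small-count targets, not of the
annealing machinery, and it disappears at population scales orders of
magnitude larger than a desk run.  The posterior predictive coverage of
held-out targets is the robust summary at this scale.


* A new conception ends the postpartum state, truncating late-window
  exposure; closed-form checks account for this competing risk.
* Women who lose all fetuses antepartum skip the delivery care cascade
  (documented simplification; their late window still opens).
* Ectopic pregnancies route through the generic referral cascade with a
  severe profile and the ectopic-management intervention at CEmOC.
* Indirect deaths are a proportion of background mortality in the risk
  window; pregnancy does not itself raise background mortality.
* "Other direct" complications have no severity split and no curative
  intervention.
* Initial-cohort parity is a coarse Poisson assignment smoothed by the
  burn-in years.
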