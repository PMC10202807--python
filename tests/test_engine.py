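"""Monthly loop: determinism, conservation, stripped-down oracles."""

import numpy as np

from maternalsim.engine import (
    RunSettings, classify_nonobstetric_death, simulate_country,
)
from maternalsim.params import CAUSE, BAND_SUFFIX
from tests.conftest import constant_lifetable, flat_fecundity, stripped_pset


def run(pset, lt, **kw):
    settings = RunSettings(years=(int(lt.years[0]), int(lt.years[-1])), **kw)
    return simulate_country(pset, lt, settings, return_population=True)


class TestClassification:
    def test_outside_window_never_indirect(self, rng):
        cause = classify_nonobstetric_death(np.zeros(10**4, bool), 0.0, 0.9, rng)
        assert not np.any(cause == CAUSE["indirect"])

    def test_certain_injury_never_maternal(self, rng):
        cause = classify_nonobstetric_death(np.ones(10**4, bool), 1.0, 0.9, rng)
        assert np.all(cause == CAUSE["injury"])

    def test_indirect_fraction_in_window(self, rng):
        cause = classify_nonobstetric_death(np.ones(10**5, bool), 0.0, 0.4, rng)
        frac = (cause == CAUSE["indirect"]).mean()
        se = np.sqrt(0.4 * 0.6 / 10**5)
        assert abs(frac - 0.4) < 3 * se


class TestDegenerateRuns:
    def test_empty_population_runs_without_events(self):
        lt = constant_lifetable("X", (2000, 2001), 0.0)
        tally, pop = run(stripped_pset(), lt, n_initial=0, entrants_per_year=0)
        assert tally.deaths_cause.sum() == 0 and tally.births.sum() == 0
        assert pop.n == 0

    def test_zero_hazards_only_age(self):
        lt = constant_lifetable("X", (2000, 2000), 0.0)
        pset = flat_fecundity(stripped_pset(), 0.0)
        tally, pop = run(pset, lt, n_initial=200, entrants_per_year=0, seed=3)
        assert tally.deaths_cause.sum() == 0
        assert tally.conceptions.sum() == 0
        assert np.all(pop.alive[pop.exists])

    def test_rerun_is_bit_identical(self):
        lt = constant_lifetable("X", (2000, 2004), 0.01)
        pset = flat_fecundity(stripped_pset(), 0.15)
        t1, _ = run(pset, lt, n_initial=300, entrants_per_year=10, seed=9)
        t2, _ = run(pset, lt, n_initial=300, entrants_per_year=10, seed=9)
        for name in ("births", "deaths_cause", "conceptions", "person_months",
                     "reported_crvs"):
            np.testing.assert_array_equal(getattr(t1, name), getattr(t2, name))


class TestConservation:
    def test_each_woman_dies_at_most_once_and_stays_dead(self):
        lt = constant_lifetable("X", (2000, 2009), 0.05)
        pset = flat_fecundity(stripped_pset(), 0.15)
        tally, pop = run(pset, lt, n_initial=500, entrants_per_year=20, seed=1)
        dead = pop.exists & ~pop.alive
        assert tally.deaths_cause.sum() == dead.sum()
        assert np.all(pop.death_cause[dead] >= 0)
        assert np.all(pop.death_cause[pop.alive] == -1)
        assert not np.any(pop.pregnant[dead])

    def test_deaths_plus_survivors_equal_cohort(self):
        lt = constant_lifetable("X", (2000, 2009), 0.03)
        tally, pop = run(stripped_pset(), lt, n_initial=400, entrants_per_year=15, seed=2)
        cohort = int(pop.exists.sum())
        assert int(pop.alive.sum()) + int(tally.deaths_cause.sum()) == cohort

    def test_pregnancy_outcomes_partition_conceptions(self):
        lt = constant_lifetable("X", (2000, 2009), 0.01)
        pset = stripped_pset()  # defaults for losses back on
        for suf in BAND_SUFFIX:
            pset[f"bio.miscarriage.{suf}"] = 0.03
            pset[f"bio.ectopic.naive.{suf}"] = 0.01
            pset[f"bio.stillbirth.antepartum.{suf}"] = 0.003
        pset["fp.abortion.logit0"] = -1.0
        pset = flat_fecundity(pset, 0.15)
        tally, _ = run(pset, lt, n_initial=600, entrants_per_year=20, seed=4)
        ended = (tally.miscarriages + tally.ectopics + tally.abortions_safe
                 + tally.abortions_unsafe + tally.deliveries
                 + tally.stillbirth_only_endings + tally.pregnancy_end_death).sum()
        assert tally.conceptions.sum() == ended + tally.open_pregnancies_end

    def test_no_conception_after_menopause(self):
        lt = constant_lifetable("X", (2000, 2004), 0.0)
        pset = flat_fecundity(stripped_pset(), 0.3)
        pset["bio.menopause.mean_years"] = 42.0
        pset["bio.menopause.sd_years"] = 0.51
        tally, _ = run(pset, lt, n_initial=500, entrants_per_year=0, seed=5,
                       init_age_range=(46 * 12, 54 * 12))
        assert tally.conceptions.sum() == 0


class TestStrippedOracles:
    def test_ten_year_survival_matches_lifetable(self):
        # constant annual q, all obstetric processes off: survival over 10
        # years should match (1-q)^10 within 3 binomial SEs
        q, n = 0.02, 50_000
        lt = constant_lifetable("X", (2000, 2009), q)
        pset = flat_fecundity(stripped_pset(), 0.0)
        tally, pop = run(pset, lt, n_initial=n, entrants_per_year=0, seed=11)
        surv = pop.alive[pop.exists].mean()
        expected = (1 - q) ** 10
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(surv - expected) < 3 * se

    def test_twin_share_matches_configured_probability(self):
        lt = constant_lifetable("X", (2000, 2007), 0.0)
        pset = flat_fecundity(stripped_pset(), 0.2)
        pset["bio.twin.mono"] = 0.04
        tally, _ = run(pset, lt, n_initial=4000, entrants_per_year=0, seed=12,
                       init_age_range=(20 * 12, 30 * 12))
        deliveries = tally.deliveries.sum()
        twins = tally.twin_deliveries.sum()
        p_hat = twins / deliveries
        se = np.sqrt(0.04 * 0.96 / deliveries)
        assert abs(p_hat - 0.04) < 3 * se

    def test_monthly_mortality_rate_matches_conversion(self, rng):
        # one month of exposure at annual q=0.05 across 1e5 women
        q = 0.05
        lt = constant_lifetable("X", (2000, 2000), q)
        pset = flat_fecundity(stripped_pset(), 0.0)
        settings = RunSettings(years=(2000, 2000), n_initial=100_000,
                               entrants_per_year=0, seed=13)
        tally = simulate_country(pset, lt, settings)
        # derive the one-month death probability from total deaths over 12
        # months: survival = (1-m)^12 with m = 1-(1-q)^(1/12), i.e. 1-q
        total_dead = tally.deaths_cause.sum()
        expected_dead = 100_000 * q
        se = np.sqrt(100_000 * q * (1 - q))
        assert abs(total_dead - expected_dead) < 3 * se


class TestMaternalWindowRules:
    def test_late_death_rate_matches_survival_weighted_hazard(self):
        f, h = 0.2, 0.002
        lt = constant_lifetable("X", (2000, 2009), 0.0)
        pset = flat_fecundity(stripped_pset(), f)
        pset["comp.late.monthly_hazard"] = h
        tally, _ = run(pset, lt, n_initial=2000, entrants_per_year=0, seed=6,
                       init_age_range=(20 * 12, 30 * 12))
        late = tally.deaths_cause[:, CAUSE["late"]].sum()
        deliveries = tally.deliveries.sum()
        # the late hazard acts in postpartum cycles 2-12, but a new
        # conception (monthly probability f) ends the postpartum state, so
        # cycle k is reached with probability (1-f)^(k-1)
        p = h * sum((1 - f) ** (k - 1) for k in range(2, 13))
        se = np.sqrt(deliveries * p * (1 - p))
        assert abs(late - deliveries * p) < 3 * se + 3

    def test_single_death_with_two_certain_fatal_complications(self):
        lt = constant_lifetable("X", (2000, 2004), 0.0)
        pset = flat_fecundity(stripped_pset(), 0.2)
        pset.update({"comp.inc.pph": 1.0, "comp.inc.sepsis": 1.0,
                     "comp.sev.pph": 1.0, "comp.sev.sepsis": 1.0,
                     "comp.cfr.pph": 1.0, "comp.cfr.sepsis": 1.0})
        tally, _ = run(pset, lt, n_initial=500, entrants_per_year=0, seed=7,
                       init_age_range=(20 * 12, 30 * 12))
        deliveries = tally.deliveries.sum()
        deaths = tally.deaths_cause[:, [CAUSE["hemorrhage"], CAUSE["sepsis"]]].sum()
        assert deliveries > 0
        assert deaths == deliveries  # exactly one death per delivery
        # fixed priority: hemorrhage outranks sepsis
        assert tally.deaths_cause[:, CAUSE["sepsis"]].sum() == 0

    def test_maternal_deaths_excluding_late_are_pregnancy_related(self):
        lt = constant_lifetable("X", (2000, 2009), 0.01)
        pset = flat_fecundity(stripped_pset(), 0.15)
        pset.update({"comp.inc.pph": 0.2, "comp.sev.pph": 1.0, "comp.cfr.pph": 0.3})
        tally, _ = run(pset, lt, n_initial=2000, entrants_per_year=50, seed=8)
        maternal_42d = tally.deaths_cause[:, :7].sum()
        assert np.all(maternal_42d <= tally.pregnancy_related.sum())

    def test_reported_never_exceed_true_deaths(self):
        lt = constant_lifetable("X", (2000, 2009), 0.01)
        pset = flat_fecundity(stripped_pset(), 0.15)
        pset.update({"comp.inc.pph": 0.2, "comp.sev.pph": 1.0, "comp.cfr.pph": 0.3})
        tally, _ = run(pset, lt, n_initial=2000, entrants_per_year=50, seed=8)
        true_by_cause = tally.deaths_cause[:, :8]
        assert np.all(tally.reported_crvs <= true_by_cause)
        assert np.all(tally.reported_survey <= true_by_cause)
        assert np.all(tally.reported_survey.sum(0) >= tally.reported_crvs.sum(0))


class TestCareMonotonicity:
    def test_higher_quality_never_more_deaths(self):
        # two-arm comparison: same seed, quality raised everywhere
        lt = constant_lifetable("X", (2000, 2007), 0.0)
        base = flat_fecundity(stripped_pset(), 0.2)
        base.update({"comp.inc.pph": 0.3, "comp.sev.pph": 1.0, "comp.cfr.pph": 0.3,
                     "int.hemorrhage_mgmt.avail0": 0.9,
                     "hs.site.logit.bemoc": 0.0})  # half home, half BEmOC
        for s in ("home", "home_sba", "nonemoc", "bemoc", "cemoc"):
            base[f"hs.recog.logit.{s}"] = 40.0
        hi = dict(base)
        for s in ("home", "home_sba", "nonemoc", "bemoc", "cemoc"):
            base[f"hs.quality.logit.{s}"] = -2.0
            hi[f"hs.quality.logit.{s}"] = 3.0
        kw = dict(n_initial=4000, entrants_per_year=0, seed=21,
                  init_age_range=(20 * 12, 30 * 12))
        t_lo, _ = run(base, lt, **kw)
        t_hi, _ = run(hi, lt, **kw)
        d_lo = t_lo.deaths_cause[:, CAUSE["hemorrhage"]].sum()
        d_hi = t_hi.deaths_cause[:, CAUSE["hemorrhage"]].sum()
        se = np.sqrt(max(d_lo, 1.0))
        assert d_hi <= d_lo + 3 * se
        assert d_hi < d_lo  # effect is large by construction
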