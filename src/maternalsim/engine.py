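"""Monthly-cycle population engine.

The engine follows an open population of individual women in one country.
State is held as flat numpy arrays (one slot per woman, never compacted);
each calendar month applies a fixed event order to every living woman:

    1. background (non-obstetric) mortality, with injury exclusion and
       indirect-maternal classification inside the risk window
    2. aging
    3. family-planning update (intention, adoption, switching, stopping)
    4. conception attempt
    5. pregnancy-month update: ectopic resolution, induced abortion,
       miscarriage, antepartum stillbirth, delivery with the full care
       pathway (site, complications, referral, interventions, deaths)
    6. postpartum update (late maternal hazard, breastfeeding clock)
    7. new entrants appended (age 10, pre-debut)

All randomness comes from a single generator consumed in this fixed
order, so a rerun with the same configuration and seed is bit-identical.
Event counts are accumulated into an :class:`EventTally` per calendar
year; women dying of any cause while pregnant or within the first
postpartum cycle count as pregnancy-related deaths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import care_pathway as care
from . import family_planning as fp
from . import reproduction as rep
from .care_pathway import FATAL_PRIORITY, N_COMP, OBSTRUCTED, PE_E
from .lifetables import LifeTable
from .params import (
    CAUSE, CAUSES, N_MATERNAL_CAUSES, REQUIRED_SITE_NONSEVERE, REQUIRED_SITE_SEVERE,
    SITE, CompiledParams, annual_to_monthly,
)

PP_WINDOW = 1       # pregnancy + 1 full postpartum cycle ≈ the 42-day window
LATE_LO, LATE_HI = 2, 12               # late maternal window, postpartum cycles
COMP_CAUSE_IDX = np.array([CAUSE["hypertensive"], CAUSE["obstructed_labor"],
                           CAUSE["hemorrhage"], CAUSE["sepsis"], CAUSE["other_direct"]])


@dataclass
class EventTally:
    """Per country-year event counts for one simulation run."""

    country: str
    start_year: int
    n_years: int
    births: np.ndarray = None
    female_births: np.ndarray = None
    deaths_cause: np.ndarray = None          # [year, 10 causes]
    maternal_deaths_age: np.ndarray = None   # [year, 35], ages 15-49, excl. late
    pregnancy_related: np.ndarray = None
    allcause_15_49: np.ndarray = None
    person_months: np.ndarray = None         # [year, 35 single ages 15-49]
    person_months_sg: np.ndarray = None      # [year, 6 subgroups]
    reported_crvs: np.ndarray = None         # [year, 8 maternal causes]
    reported_survey: np.ndarray = None
    conceptions: np.ndarray = None
    miscarriages: np.ndarray = None
    ectopics: np.ndarray = None
    abortions_safe: np.ndarray = None
    abortions_unsafe: np.ndarray = None
    stillbirths: np.ndarray = None
    deliveries: np.ndarray = None
    twin_deliveries: np.ndarray = None
    stillbirth_only_endings: np.ndarray = None   # pregnancies ending with all
    pregnancy_end_death: np.ndarray = None       # fetuses lost antepartum /
    open_pregnancies_end: int = 0                # by maternal death mid-pregnancy

    def __post_init__(self):
        y = self.n_years
        z = lambda *shape: np.zeros(shape, dtype=np.int64)
        if self.births is None:
            self.births = z(y)
            self.female_births = z(y)
            self.deaths_cause = z(y, len(CAUSES))
            self.maternal_deaths_age = z(y, 35)
            self.pregnancy_related = z(y)
            self.allcause_15_49 = z(y)
            self.person_months = z(y, 35)
            self.person_months_sg = z(y, 6)
            self.reported_crvs = z(y, N_MATERNAL_CAUSES)
            self.reported_survey = z(y, N_MATERNAL_CAUSES)
            for name in ("conceptions", "miscarriages", "ectopics", "abortions_safe",
                         "abortions_unsafe", "stillbirths", "deliveries",
                         "twin_deliveries", "stillbirth_only_endings",
                         "pregnancy_end_death"):
                setattr(self, name, z(y))

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.start_year, self.start_year + self.n_years)


class Population:
    """Struct-of-arrays state for every woman ever instantiated in a run."""

    FIELDS = [
        ("exists", bool), ("alive", bool), ("age_m", np.int32), ("subgroup", np.int8),
        ("debut_m", np.int32), ("menopause_m", np.int32), ("desired", np.int16),
        ("living_children", np.int16), ("months_since_birth", np.int32),
        ("method", np.int8), ("spell_end", np.int32),
        ("pregnant", bool), ("gest_m", np.int8), ("n_fetus", np.int8),
        ("n_female", np.int8), ("ectopic", bool), ("unintended", bool),
        ("sched_del", np.int8), ("abortion_decided", bool), ("anc_visits", np.int16),
        ("postpartum_m", np.int16), ("bf_remaining", np.int16), ("bf_exclusive", bool),
        ("hb", np.float64), ("infertile", bool),
        ("hist_miscarriage", bool), ("hist_ectopic", bool), ("hist_pe_e", bool),
        ("had_csection", bool), ("death_cause", np.int8),
    ]

    def __init__(self, n: int):
        self.n = n
        for name, dtype in self.FIELDS:
            setattr(self, name, np.zeros(n, dtype=dtype))
        self.postpartum_m[:] = -1
        self.months_since_birth[:] = fp.NO_BIRTH_YET
        self.spell_end[:] = -1
        self.death_cause[:] = -1

    def init_women(self, idx: np.ndarray, age_m: np.ndarray, subgroup: np.ndarray,
                   cp: CompiledParams, rng: np.random.Generator) -> None:
        """Draw per-woman invariants (debut, menopause, preferences, Hb)."""
        self.exists[idx] = True
        self.alive[idx] = True
        self.age_m[idx] = age_m
        self.subgroup[idx] = subgroup
        self.debut_m[idx] = fp.draw_debut_age_months(subgroup, cp, rng)
        self.menopause_m[idx] = rep.draw_menopause_age_months(cp, rng, len(idx))
        self.desired[idx] = fp.draw_desired_children(subgroup, cp, rng)
        self.hb[idx] = rep.draw_hemoglobin(subgroup, cp, rng)
        # mid-life initial cross-section: parity consistent with age exposure
        started = age_m > self.debut_m[idx]
        frac = np.clip((age_m / 12.0 - 18.0) / 17.0, 0.0, 1.0)
        mean_kids = self.desired[idx] * frac * started
        self.living_children[idx] = rng.poisson(mean_kids).astype(np.int16)


def classify_nonobstetric_death(in_window: np.ndarray, p_injury: np.ndarray,
                                p_indirect: float,
                                rng: np.random.Generator) -> np.ndarray:
    """Cause codes for women dying of non-obstetric (background) causes.

    Injuries are never maternal (accidental/incidental causes are excluded
    from the maternal definition).  Non-injury deaths inside the risk
    window (pregnant or within 42 days of the end of pregnancy) are
    indirect maternal with probability ``p_indirect``; everything else is
    other non-maternal.  All such deaths still count in the all-cause and
    (if in window) pregnancy-related tallies.
    """
    in_window = np.asarray(in_window, bool)
    n = in_window.size
    injury = rng.random(n) < np.broadcast_to(np.asarray(p_injury, float), (n,))
    indirect = ~injury & in_window & (rng.random(n) < p_indirect)
    cause = np.full(n, CAUSE["other_nonmaternal"], np.int8)
    cause[injury] = CAUSE["injury"]
    cause[indirect] = CAUSE["indirect"]
    return cause


@dataclass
class RunSettings:
    years: tuple[int, int]            # inclusive calendar range incl. burn-in
    n_initial: int = 2000
    entrants_per_year: int | np.ndarray = 60
    seed: int = 0
    subgroup_shares: np.ndarray | None = None   # 6 shares; uniform if None
    init_age_range: tuple[int, int] = (10 * 12, 55 * 12)  # months, half-open

    def subgroup_p(self) -> np.ndarray:
        if self.subgroup_shares is None:
            return np.full(6, 1.0 / 6.0)
        p = np.asarray(self.subgroup_shares, dtype=float)
        if p.shape != (6,) or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-6:
            raise ValueError("subgroup_shares must be 6 non-negative values summing to 1")
        return p / p.sum()

    def entrant_counts(self) -> np.ndarray:
        n_years = self.years[1] - self.years[0] + 1
        e = np.asarray(self.entrants_per_year)
        if e.ndim == 0:
            e = np.full(n_years, int(e))
        if len(e) != n_years or np.any(e < 0):
            raise ValueError("entrant schedule must be non-negative, one per year")
        return e.astype(int)


def simulate_country(pset_or_cp, lifetable: LifeTable, settings: RunSettings,
                     country: str | None = None, return_population: bool = False):
    """Run the monthly loop for one country and return its event tally
    (and, optionally, the final population state)."""
    cp = (pset_or_cp if isinstance(pset_or_cp, CompiledParams)
          else CompiledParams(pset_or_cp, settings.years))
    start, end = settings.years
    n_years = end - start + 1
    rng = np.random.default_rng(settings.seed)
    tally = EventTally(country or lifetable.country, start, n_years)

    entrants = settings.entrant_counts()
    total = settings.n_initial + int(entrants.sum())
    pop = Population(total)
    sg_p = settings.subgroup_p()

    # initial cross-section, ages uniform over the configured range
    idx0 = np.arange(settings.n_initial)
    age0 = rng.integers(*settings.init_age_range,
                        size=settings.n_initial).astype(np.int32)
    sg0 = rng.choice(6, size=settings.n_initial, p=sg_p).astype(np.int8)
    pop.init_women(idx0, age0, sg0, cp, rng)
    next_slot = settings.n_initial

    # monthly entrant allocation (deterministic split of the annual count)
    for yi in range(n_years):
        year = start + yi
        per_month = np.diff(np.round(np.linspace(0, entrants[yi], 13)).astype(int))
        for month in range(12):
            _advance_month(pop, cp, lifetable, tally, yi, year, rng)
            k = per_month[month]
            if k:
                idx = np.arange(next_slot, next_slot + k)
                sg = rng.choice(6, size=k, p=sg_p).astype(np.int8)
                pop.init_women(idx, np.full(k, 120, np.int32), sg, cp, rng)
                next_slot += k
    tally.open_pregnancies_end = int((pop.alive & pop.pregnant).sum())
    if return_population:
        return tally, pop
    return tally


def _advance_month(pop: Population, cp: CompiledParams, lt: LifeTable,
                   tally: EventTally, yi: int, year: int,
                   rng: np.random.Generator) -> None:
    alive = pop.alive
    live_idx = np.flatnonzero(alive)
    if live_idx.size:
        age_y = pop.age_m[live_idx] // 12
        in_rep = (age_y >= 15) & (age_y < 50)
        ri = live_idx[in_rep]
        np.add.at(tally.person_months[yi], pop.age_m[ri] // 12 - 15, 1)
        np.add.at(tally.person_months_sg[yi], pop.subgroup[ri], 1)

    # (1) background mortality with injury/indirect classification
    if live_idx.size:
        q = lt.q_for(pop.age_m[live_idx] // 12, year)
        died = rng.random(live_idx.size) < annual_to_monthly(q)
        d_idx = live_idx[died]
        if d_idx.size:
            in_window = (pop.pregnant[d_idx]
                         | ((pop.postpartum_m[d_idx] >= 0)
                            & (pop.postpartum_m[d_idx] <= PP_WINDOW)))
            p_inj = lt.p_injury_for(pop.age_m[d_idx] // 12, year)
            cause = classify_nonobstetric_death(in_window, p_inj, cp.p_indirect, rng)
            _record_deaths(pop, tally, yi, d_idx, cause,
                           np.full(d_idx.size, SITE["home"], np.int8),
                           in_window, cp, rng)

    # (2) aging
    pop.age_m[pop.alive] += 1

    # (3) family planning
    _fp_update(pop, cp, yi, rng)

    # (4) conception
    _conception(pop, cp, yi, rng, tally)

    # (5) pregnancy-month update (incl. delivery care pathway)
    _pregnancy_update(pop, cp, yi, rng, tally)

    # (6) postpartum update
    _postpartum_update(pop, cp, yi, rng, tally)


def _eligible_fp(pop: Population) -> np.ndarray:
    return (pop.alive & ~pop.pregnant
            & (pop.age_m >= pop.debut_m) & (pop.age_m < pop.menopause_m))


def _fp_update(pop: Population, cp: CompiledParams, yi: int,
               rng: np.random.Generator) -> None:
    idx = np.flatnonzero(_eligible_fp(pop))
    if not idx.size:
        return
    intent = fp.intention_of(pop.living_children[idx], pop.desired[idx],
                             pop.months_since_birth[idx], cp.spacing_window)
    method = pop.method[idx]

    # wants-soon users discontinue everything but permanent methods
    stop = (intent == fp.WANTS_SOON) & (method > 0) & (method != 3)
    pop.method[idx[stop]] = 0
    pop.spell_end[idx[stop]] = -1
    method[stop] = 0

    # spell expiry: spacing users switch or discontinue, limiting users renew
    expiring = (method > 0) & (method != 3) & (pop.spell_end[idx] <= 0)
    exp_i = np.flatnonzero(expiring)
    if exp_i.size:
        sw = rng.random(exp_i.size) < cp.p_switch
        limiting = intent[exp_i] == fp.LIMITING
        renew = limiting | sw
        n_new = int(renew.sum())
        if n_new:
            mixes = np.where(limiting[renew], 1, 0)
            new_m = np.empty(n_new, np.int8)
            for mix_id, mix in ((0, cp.mix_spacing), (1, cp.mix_limiting)):
                sel = mixes == mix_id
                if sel.any():
                    new_m[sel] = fp.draw_method(mix, rng, int(sel.sum()))
            tgt = idx[exp_i[renew]]
            pop.method[tgt] = new_m
            pop.spell_end[tgt] = fp.draw_spell_months(cp, rng, n_new)
        drop = idx[exp_i[~renew]]
        pop.method[drop] = 0
        pop.spell_end[drop] = -1
        method = pop.method[idx]

    pop.spell_end[idx[(method > 0) & (method != 3)]] -= 1

    # adoption for women with need (spacing/limiting) and no method
    need = (method == 0) & (intent != fp.WANTS_SOON)
    need_i = np.flatnonzero(need)
    if need_i.size:
        p = fp.monthly_adoption_probability(cp.met_need[yi][pop.subgroup[idx[need_i]]])
        adopt = rng.random(need_i.size) < p
        a_i = need_i[adopt]
        if a_i.size:
            limiting = intent[a_i] == fp.LIMITING
            new_m = np.empty(a_i.size, np.int8)
            if limiting.any():
                new_m[limiting] = fp.draw_method(cp.mix_limiting, rng, int(limiting.sum()))
            if (~limiting).any():
                new_m[~limiting] = fp.draw_method(cp.mix_spacing, rng, int((~limiting).sum()))
            tgt = idx[a_i]
            pop.method[tgt] = new_m
            pop.spell_end[tgt] = fp.draw_spell_months(cp, rng, a_i.size)

    pop.months_since_birth[pop.alive & (pop.months_since_birth < fp.NO_BIRTH_YET)] += 1


def _conception(pop: Population, cp: CompiledParams, yi: int,
                rng: np.random.Generator, tally: EventTally) -> None:
    idx = np.flatnonzero(_eligible_fp(pop) & ~pop.infertile)
    if not idx.size:
        return
    lam = rep.lam_multiplier(pop.postpartum_m[idx], pop.bf_remaining[idx],
                             pop.bf_exclusive[idx], cp)
    p = rep.conception_probability(pop.age_m[idx], pop.method[idx], lam, cp)
    conceived = rng.random(idx.size) < p
    c_idx = idx[conceived]
    if not c_idx.size:
        return
    tally.conceptions[yi] += c_idx.size
    n = c_idx.size
    pop.pregnant[c_idx] = True
    pop.gest_m[c_idx] = 0
    pop.postpartum_m[c_idx] = -1
    pop.bf_remaining[c_idx] = 0
    pop.abortion_decided[c_idx] = False
    n_fetus, n_female = rep.draw_fetuses(pop.age_m[c_idx], cp, rng)
    ectopic = rng.random(n) < rep.ectopic_probability(
        pop.age_m[c_idx], pop.hist_ectopic[c_idx], cp)
    n_fetus[ectopic] = 1
    n_female[ectopic] = np.minimum(n_female[ectopic], 1)
    pop.n_fetus[c_idx] = n_fetus
    pop.n_female[c_idx] = n_female
    pop.ectopic[c_idx] = ectopic
    pop.sched_del[c_idx] = rep.schedule_delivery(cp.delivery_month_dist, rng, n)
    pop.sched_del[c_idx[ectopic]] = 127  # never reached; ectopics resolve early
    intent = fp.intention_of(pop.living_children[c_idx], pop.desired[c_idx],
                             pop.months_since_birth[c_idx], cp.spacing_window)
    pop.unintended[c_idx] = (pop.method[c_idx] > 0) | (intent == fp.LIMITING)
    # conception ends any contraceptive spell
    nonperm = pop.method[c_idx] != 3
    pop.method[c_idx[nonperm]] = 0
    pop.spell_end[c_idx[nonperm]] = -1
    pop.anc_visits[c_idx] = care.anc_visits(yi, cp, rng, n)


def _pregnancy_update(pop: Population, cp: CompiledParams, yi: int,
                      rng: np.random.Generator, tally: EventTally) -> None:
    preg = np.flatnonzero(pop.alive & pop.pregnant)
    if not preg.size:
        return
    pop.gest_m[preg] += 1
    gest = pop.gest_m[preg]

    # (a) ectopic resolution at gestational month 3
    eidx = preg[(gest == 3) & pop.ectopic[preg]]
    if eidx.size:
        _resolve_ectopic(pop, cp, yi, rng, tally, eidx)

    preg = np.flatnonzero(pop.alive & pop.pregnant)
    gest = pop.gest_m[preg]

    # (b) induced abortion decision, once, at gestational month 2
    aidx = preg[(gest == 2) & pop.unintended[preg] & ~pop.abortion_decided[preg]
                & ~pop.ectopic[preg]]
    if aidx.size:
        _resolve_abortion(pop, cp, yi, rng, tally, aidx)

    preg = np.flatnonzero(pop.alive & pop.pregnant)
    gest = pop.gest_m[preg]

    # (c) miscarriage, gestational months 1-5
    midx = preg[(gest >= 1) & (gest <= rep.MISCARRIAGE_MAX_GEST) & ~pop.ectopic[preg]]
    if midx.size:
        p = rep.miscarriage_probability(pop.age_m[midx], pop.hist_miscarriage[midx], cp)
        lost = midx[rng.random(midx.size) < p]
        if lost.size:
            tally.miscarriages[yi] += lost.size
            pop.hist_miscarriage[lost] = True
            _clear_pregnancy(pop, lost)

    preg = np.flatnonzero(pop.alive & pop.pregnant)
    gest = pop.gest_m[preg]

    # (d) antepartum stillbirth per fetus, months 6+
    sidx = preg[(gest >= rep.STILLBIRTH_MIN_GEST) & ~pop.ectopic[preg]]
    if sidx.size:
        p_f, p_m = rep.stillbirth_probabilities(pop.age_m[sidx], cp)
        n_m = (pop.n_fetus[sidx] - pop.n_female[sidx]).astype(np.int64)
        d_f = rng.binomial(pop.n_female[sidx].astype(np.int64), p_f)
        d_m = rng.binomial(n_m, p_m)
        dead_fetus = d_f + d_m
        if dead_fetus.sum():
            tally.stillbirths[yi] += int(dead_fetus.sum())
            pop.n_female[sidx] = (pop.n_female[sidx] - d_f).astype(np.int8)
            pop.n_fetus[sidx] = (pop.n_fetus[sidx] - dead_fetus).astype(np.int8)
            all_lost = sidx[pop.n_fetus[sidx] == 0]
            if all_lost.size:
                # pregnancy ends with a stillbirth delivery; the late-window
                # clock starts but no breastfeeding follows
                tally.stillbirth_only_endings[yi] += all_lost.size
                _clear_pregnancy(pop, all_lost)
                pop.postpartum_m[all_lost] = 0
                pop.months_since_birth[all_lost] = 0

    preg = np.flatnonzero(pop.alive & pop.pregnant)
    gest = pop.gest_m[preg]

    # (e) delivery at the scheduled month
    didx = preg[gest >= pop.sched_del[preg]]
    if didx.size:
        _process_delivery(pop, cp, yi, rng, tally, didx)


def _resolve_ectopic(pop, cp, yi, rng, tally, idx) -> None:
    n = idx.size
    tally.ectopics[yi] += n
    severe = np.ones(n, bool)
    treated_at, _rec = care.referral_cascade(
        care.PPH, severe, np.full(n, SITE["home"], np.int8),
        pop.anc_visits[idx], yi, cp, rng)
    rr = care.intervention_rr("ectopic_mgmt", treated_at, yi, cp)
    died = rng.random(n) < np.clip(cp.cfr_ectopic * rr, 0, 1)
    pop.hist_ectopic[idx] = True
    _clear_pregnancy(pop, idx)
    if died.any():
        d = idx[died]
        _record_deaths(pop, tally, yi, d,
                       np.full(d.size, CAUSE["abortive"], np.int8),
                       treated_at[died], np.ones(d.size, bool), cp, rng)


def _resolve_abortion(pop, cp, yi, rng, tally, idx) -> None:
    pop.abortion_decided[idx] = True
    all_female = pop.n_female[idx] == pop.n_fetus[idx]
    p_abort = fp.abortion_probability(all_female, yi, cp)
    abort = rng.random(idx.size) < p_abort
    a = idx[abort]
    if not a.size:
        return
    safe = rng.random(a.size) < cp.p_abortion_safe[yi]
    tally.abortions_safe[yi] += int(safe.sum())
    tally.abortions_unsafe[yi] += int((~safe).sum())
    _clear_pregnancy(pop, a)
    unsafe = a[~safe]
    if unsafe.size:
        anemic = rep.anemia_flags(pop.hb[unsafe], True)
        died = rng.random(unsafe.size) < fp.unsafe_abortion_death_probability(anemic, cp)
        surv = unsafe[~died]
        pop.infertile[surv] |= rng.random(surv.size) < cp.p_infertility_unsafe
        if died.any():
            d = unsafe[died]
            _record_deaths(pop, tally, yi, d,
                           np.full(d.size, CAUSE["abortive"], np.int8),
                           np.full(d.size, SITE["home"], np.int8),
                           np.ones(d.size, bool), cp, rng)


def _process_delivery(pop, cp, yi, rng, tally, idx) -> None:
    n = idx.size
    tally.deliveries[yi] += n
    tally.twin_deliveries[yi] += int((pop.n_fetus[idx] >= 2).sum())
    visits = pop.anc_visits[idx]
    hb_del = pop.hb[idx] + visits * cp.anc_hb_per_visit
    anemic = hb_del < rep.HB_THRESHOLD_PREGNANT

    site, elective_cs = care.choose_delivery_site(pop.subgroup[idx], yi, cp, rng)
    cs_risk = elective_cs | pop.had_csection[idx]
    probs = care.complication_probabilities(
        pop.age_m[idx], anemic, pop.n_fetus[idx], pop.hist_pe_e[idx],
        cs_risk, site, yi, cp)
    occurs = rng.random((n, N_COMP)) < probs
    severe = occurs & (rng.random((n, N_COMP)) < cp.severity[None, :])

    treated_at = np.repeat(site[:, None], N_COMP, axis=1)
    fatal = np.zeros((n, N_COMP), bool)
    unresolved_severe = np.zeros(n, bool)
    for c in range(N_COMP):
        sel = np.flatnonzero(occurs[:, c])
        if not sel.size:
            continue
        t_at, _rec = care.referral_cascade(c, severe[sel, c], site[sel],
                                           visits[sel], yi, cp, rng)
        treated_at[sel, c] = t_at
        p_die = care.death_probability(c, severe[sel, c], t_at, yi, cp)
        fatal[sel, c] = rng.random(sel.size) < p_die
        required = np.where(severe[sel, c], REQUIRED_SITE_SEVERE[c],
                            REQUIRED_SITE_NONSEVERE[c])
        unresolved_severe[sel] |= severe[sel, c] & (t_at < required)

    died = fatal.any(axis=1)
    death_comp = np.full(n, -1)
    for c in FATAL_PRIORITY:  # first fatal draw in fixed priority order
        death_comp[(death_comp == -1) & fatal[:, c]] = c

    # intrapartum stillbirth risk when a severe complication goes
    # unresolved or the mother dies
    at_risk = unresolved_severe | died
    p_ip = np.where(at_risk, cp.p_ip_stillbirth, 0.0)
    n_m = (pop.n_fetus[idx] - pop.n_female[idx]).astype(np.int64)
    sb_f = rng.binomial(pop.n_female[idx].astype(np.int64), p_ip)
    sb_m = rng.binomial(n_m, p_ip)
    live_f = pop.n_female[idx] - sb_f
    live_m = n_m - sb_m
    live = live_f + live_m
    tally.stillbirths[yi] += int((sb_f + sb_m).sum())
    tally.births[yi] += int(live.sum())
    tally.female_births[yi] += int(live_f.sum())

    pop.hist_pe_e[idx] |= occurs[:, PE_E]
    pop.had_csection[idx] |= elective_cs | (severe[:, OBSTRUCTED]
                                            & (treated_at[:, OBSTRUCTED] == SITE["cemoc"]))
    _clear_pregnancy(pop, idx)

    surv = idx[~died]
    if surv.size:
        pop.living_children[surv] += live[~died].astype(np.int16)
        pop.postpartum_m[surv] = 0
        pop.months_since_birth[surv] = 0
        bf_m, bf_x = rep.draw_breastfeeding(live[~died], cp, rng)
        pop.bf_remaining[surv] = bf_m
        pop.bf_exclusive[surv] = bf_x

    if died.any():
        d = idx[died]
        comp = death_comp[died]
        cause = COMP_CAUSE_IDX[comp].astype(np.int8)
        d_site = treated_at[died, comp]
        _record_deaths(pop, tally, yi, d, cause, d_site.astype(np.int8),
                       np.ones(d.size, bool), cp, rng)


def _postpartum_update(pop, cp, yi, rng, tally) -> None:
    pp = np.flatnonzero(pop.alive & (pop.postpartum_m >= 0) & ~pop.pregnant)
    if not pp.size:
        return
    pop.postpartum_m[pp] += 1
    m = pop.postpartum_m[pp]
    late = pp[(m >= LATE_LO) & (m <= LATE_HI)]
    if late.size:
        died = rng.random(late.size) < cp.late_monthly_hazard
        if died.any():
            d = late[died]
            _record_deaths(pop, tally, yi, d,
                           np.full(d.size, CAUSE["late"], np.int8),
                           np.full(d.size, SITE["home"], np.int8),
                           np.zeros(d.size, bool), cp, rng)
    closed = pp[pop.postpartum_m[pp] > LATE_HI]
    pop.postpartum_m[closed] = -1
    bf = pp[pop.bf_remaining[pp] > 0]
    pop.bf_remaining[bf] -= 1


def _clear_pregnancy(pop: Population, idx: np.ndarray) -> None:
    pop.pregnant[idx] = False
    pop.gest_m[idx] = 0
    pop.n_fetus[idx] = 0
    pop.n_female[idx] = 0
    pop.ectopic[idx] = False
    pop.unintended[idx] = False
    pop.sched_del[idx] = 0
    pop.anc_visits[idx] = 0


def _record_deaths(pop: Population, tally: EventTally, yi: int, idx: np.ndarray,
                   cause: np.ndarray, site: np.ndarray, in_window: np.ndarray,
                   cp: CompiledParams, rng: np.random.Generator) -> None:
    """Freeze state for dying women and accumulate all death tallies."""
    pop.alive[idx] = False
    pop.death_cause[idx] = cause
    tally.pregnancy_end_death[yi] += int(pop.pregnant[idx].sum())
    pop.pregnant[idx] = False
    pop.postpartum_m[idx] = -1
    np.add.at(tally.deaths_cause[yi], cause, 1)
    age_y = pop.age_m[idx] // 12
    in_rep = (age_y >= 15) & (age_y < 50)
    tally.allcause_15_49[yi] += int(in_rep.sum())
    tally.pregnancy_related[yi] += int(np.asarray(in_window, bool).sum())
    maternal = cause < CAUSE["late"]  # eight causes minus late
    mi = np.flatnonzero(maternal & in_rep)
    if mi.size:
        np.add.at(tally.maternal_deaths_age[yi], age_y[mi] - 15, 1)
    rep_i = np.flatnonzero(cause < N_MATERNAL_CAUSES)
    if rep_i.size:
        u = rng.random(rep_i.size)
        p_c = care.capture_probability("crvs", site[rep_i], yi, cp)
        p_s = care.capture_probability("survey", site[rep_i], yi, cp)
        crvs = u < p_c
        survey = u < p_s  # nested draw: survey capture ⊇ CRVS capture
        np.add.at(tally.reported_crvs[yi], cause[rep_i][crvs], 1)
        np.add.at(tally.reported_survey[yi], cause[rep_i][survey], 1)
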