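"""Maternal-mortality indicators and uncertainty summaries.

Definitions (denominators per 100,000 where noted):

* MMR — maternal deaths (direct + indirect, within pregnancy or 42 days
  of its end, late excluded) per 100,000 live births.
* Pregnancy mortality ratio — deaths from *any* cause during pregnancy or
  the 42-day window per 100,000 live births; a superset of the MMR
  numerator, so PMR ≥ MMR always.
* Proportional mortality ratio — maternal deaths as % of all deaths among
  women 15–49.
* Maternal mortality rate — maternal deaths per 100,000 woman-years 15–49.
* Total maternal deaths — maternal + late maternal deaths.
* Lifetime risk — Σ over ages 15–49 of age-specific maternal mortality
  rates: the probability a 15-year-old eventually dies of a maternal cause
  at current rates.

Uncertainty intervals are the empirical 2.5/97.5 percentiles across
simulation iterations (linear interpolation between order statistics).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .engine import EventTally
from .params import CAUSE, CAUSES


class UndefinedIndicatorError(ZeroDivisionError):
    """A required denominator is zero."""


MATERNAL_CAUSE_NAMES = CAUSES[:7]   # eight grouped causes minus late
ALL_MATERNAL_NAMES = CAUSES[:8]


def tally_frame(tally: EventTally) -> pd.DataFrame:
    """One row per calendar year with all counts needed by the indicators."""
    df = pd.DataFrame({
        "country": tally.country,
        "year": tally.years,
        "live_births": tally.births,
        "maternal_deaths": tally.deaths_cause[:, :7].sum(axis=1),
        "late_maternal_deaths": tally.deaths_cause[:, CAUSE["late"]],
        "pregnancy_related_deaths": tally.pregnancy_related,
        "deaths_all_cause_15_49": tally.allcause_15_49,
        "person_years_15_49": tally.person_months.sum(axis=1) / 12.0,
    })
    for name in CAUSES:
        df[f"deaths_{name}"] = tally.deaths_cause[:, CAUSE[name]]
    for name in ALL_MATERNAL_NAMES:
        df[f"reported_crvs_{name}"] = tally.reported_crvs[:, CAUSE[name]]
        df[f"reported_survey_{name}"] = tally.reported_survey[:, CAUSE[name]]
    df["reported_crvs_total"] = tally.reported_crvs.sum(axis=1)
    df["reported_survey_total"] = tally.reported_survey.sum(axis=1)
    return df


def aggregate_tallies(tallies: list[EventTally], name: str = "aggregate") -> EventTally:
    """Element-wise sum of tallies (regional additivity is exact on counts)."""
    first = tallies[0]
    out = EventTally(name, first.start_year, first.n_years)
    for t in tallies:
        if (t.start_year, t.n_years) != (first.start_year, first.n_years):
            raise ValueError("tallies cover different year ranges")
        for fname in ("births", "female_births", "deaths_cause", "maternal_deaths_age",
                      "pregnancy_related", "allcause_15_49", "person_months",
                      "person_months_sg", "reported_crvs", "reported_survey",
                      "conceptions", "miscarriages", "ectopics", "abortions_safe",
                      "abortions_unsafe", "stillbirths", "deliveries", "twin_deliveries",
                      "stillbirth_only_endings", "pregnancy_end_death"):
            getattr(out, fname).__iadd__(getattr(t, fname))
        out.open_pregnancies_end += t.open_pregnancies_end
    return out


def mmr(maternal_deaths, live_births):
    """Maternal deaths per 100,000 live births."""
    births = np.asarray(live_births, dtype=float)
    if np.any(births <= 0):
        raise UndefinedIndicatorError("MMR undefined with zero live births")
    return np.asarray(maternal_deaths, dtype=float) / births * 1e5


def indicator_suite(df: pd.DataFrame) -> pd.DataFrame:
    """All six indicators for each row of a tally frame."""
    out = df[["country", "year"]].copy()
    births = df["live_births"].to_numpy(float)
    md = df["maternal_deaths"].to_numpy(float)
    if np.any(births <= 0):
        raise UndefinedIndicatorError("zero live births in tally")
    py = df["person_years_15_49"].to_numpy(float)
    ac = df["deaths_all_cause_15_49"].to_numpy(float)
    if np.any(py <= 0):
        raise UndefinedIndicatorError("zero person-years 15-49 in tally")
    out["mmr"] = md / births * 1e5
    out["pregnancy_mortality_ratio"] = df["pregnancy_related_deaths"] / births * 1e5
    with np.errstate(divide="ignore", invalid="ignore"):
        pmr = np.where(ac > 0, md / ac * 100.0, np.nan)
    out["proportional_mortality_ratio"] = pmr
    out["maternal_mortality_rate"] = md / py * 1e5
    out["total_maternal_deaths"] = df["maternal_deaths"] + df["late_maternal_deaths"]
    return out


def lifetime_risk(maternal_deaths_by_age: np.ndarray,
                  person_years_by_age: np.ndarray) -> float:
    """Σ age-specific maternal mortality rates, ages 15–49 (probability)."""
    d = np.asarray(maternal_deaths_by_age, dtype=float)
    e = np.asarray(person_years_by_age, dtype=float)
    if d.shape != (35,) or e.shape != (35,):
        raise ValueError("need one cell per single age 15-49")
    if np.any(e <= 0):
        raise UndefinedIndicatorError("missing exposure at some age 15-49")
    return float((d / e).sum())


def uncertainty(values) -> tuple[float, float, float]:
    """(mean, 2.5th, 97.5th percentile) across iterations."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("uncertainty summary needs at least 2 iterations")
    lo, hi = np.percentile(v, [2.5, 97.5])  # linear interpolation convention
    return float(v.mean()), float(lo), float(hi)


def indicator_table(tally_sets: list[list[EventTally]], report_from: int) -> pd.DataFrame:
    """Long-form dashboard across iterations.

    ``tally_sets``: one list of per-country tallies per iteration.  Rows:
    (scope, scope_id, year, indicator, mean, ui_lo, ui_hi), including a
    pooled 'global' scope, reported from ``report_from`` onward.
    """
    if len(tally_sets) < 2:
        raise ValueError("need at least 2 iterations for uncertainty intervals")
    per_iter = []
    for tallies in tally_sets:
        frames = [indicator_suite(tally_frame(t)) for t in tallies]
        glob = indicator_suite(tally_frame(aggregate_tallies(tallies, "global")))
        glob["country"] = "global"
        per_iter.append(pd.concat(frames + [glob], ignore_index=True))
    stacked = pd.concat(per_iter, keys=range(len(per_iter)), names=["iteration"])
    long = stacked.melt(id_vars=["country", "year"], var_name="indicator",
                        value_name="value")
    rows = []
    for (cid, year, ind), grp in long.groupby(["country", "year", "indicator"]):
        if year < report_from:
            continue
        mean, lo, hi = uncertainty(grp["value"].to_numpy())
        scope = "global" if cid == "global" else "country"
        rows.append((scope, cid, int(year), ind, mean, lo, hi))
    return pd.DataFrame(rows, columns=["scope", "scope_id", "year", "indicator",
                                       "mean", "ui_lo", "ui_hi"])


# ------------------------------------------------- printed-arithmetic helpers

def decline(a: float, b: float) -> float:
    """Percent decline from a to b: 100·(1 − b/a)."""
    if a == 0:
        raise ZeroDivisionError("decline undefined from zero")
    return 100.0 * (1.0 - b / a)


def share(x: float, total: float) -> float:
    """Percentage share 100·x/total."""
    if total == 0:
        raise ZeroDivisionError("share undefined with zero total")
    return 100.0 * x / total


def ratio(x: float, y: float) -> float:
    if y == 0:
        raise ZeroDivisionError("ratio undefined with zero denominator")
    return x / y
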