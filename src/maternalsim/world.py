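"""Synthetic world and calibration-target generation.

The generator stands in for the national data systems a country-scale run
would ingest: female lifetables and cohort sizes (population-prospects
style), urban/rural × education composition and family-planning levels
(household-survey style), and reported maternal deaths (vital-registration
style).  It draws country-level truth from the hierarchical priors,
records that truth exactly, and produces targets by running the engine
under the truth with underreporting applied — so recovery studies have a
known answer key.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import RunSettings, simulate_country
from .hierarchy import LEVELS, Hierarchy, linear_hierarchy
from .indicators import tally_frame
from .lifetables import LifeTable, synthetic_lifetable
from .params import PARAM_DEFS, ParameterSet, build_prior_library
from .priors import PriorLibrary, resolve_parameter

CAUSE_TARGETS = ("abortive", "hypertensive", "obstructed_labor", "hemorrhage",
                 "sepsis", "other_direct", "indirect", "late")


@dataclass
class WorldConfig:
    hierarchy: Hierarchy
    countries: list[str]
    years: tuple[int, int]          # includes the burn-in period
    report_from: int = 1990
    persons_per_agent: float = 1.0
    n_agents: int = 800
    entrants_per_year: int = 18
    seed: int = 0
    subgroup_shares: dict[str, list[float]] | None = None  # per-country 6 shares

    def __post_init__(self):
        if not (self.years[0] < self.report_from <= self.years[1]):
            raise ValueError("need start < report_from <= end (burn-in precedes "
                             "the reporting window)")
        if self.persons_per_agent <= 0 or self.n_agents < 1:
            raise ValueError("agent scaling must be positive")

    def settings_for(self, country: str, seed: int) -> RunSettings:
        if country not in self.countries:
            raise KeyError(f"{country!r} not in world")
        shares = None
        if self.subgroup_shares is not None:
            shares = np.asarray(self.subgroup_shares[country], dtype=float)
        return RunSettings(self.years, self.n_agents, self.entrants_per_year, seed,
                           subgroup_shares=shares)

    def to_dict(self) -> dict:
        return {
            "hierarchy": self.hierarchy.to_dict(),
            "countries": list(self.countries),
            "years": list(self.years),
            "report_from": self.report_from,
            "persons_per_agent": self.persons_per_agent,
            "n_agents": self.n_agents,
            "entrants_per_year": self.entrants_per_year,
            "seed": self.seed,
            "subgroup_shares": self.subgroup_shares,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "WorldConfig":
        return cls(Hierarchy.from_dict(d["hierarchy"]), list(d["countries"]),
                   tuple(d["years"]), d["report_from"], d["persons_per_agent"],
                   d["n_agents"], d["entrants_per_year"], d["seed"],
                   d.get("subgroup_shares"))


def generate_synthetic_world(
    n_countries: int,
    seed: int,
    years: tuple[int, int] = (1986, 2020),
    report_from: int = 1990,
    n_agents: int = 800,
    free_params: list[str] | None = None,
    priors: PriorLibrary | None = None,
) -> tuple[WorldConfig, dict[str, ParameterSet], dict[str, LifeTable]]:
    """Self-consistent small world with recorded ground truth.

    Country truth is drawn from the hierarchical priors: one shared offset
    per upper level (all synthetic countries share income group, continent
    and region) plus an independent country-level offset.  When
    ``free_params`` is given, only those parameters receive offsets —
    everything else sits exactly at the prior mean, which keeps recovery
    studies identified.  Bit-identical under a fixed seed.
    """
    if n_countries < 1:
        raise ValueError("need at least one country")
    rng = np.random.default_rng(seed)
    countries = [f"C{i + 1:02d}" for i in range(n_countries)]
    hierarchy = linear_hierarchy(countries)
    world = WorldConfig(hierarchy, countries, years, report_from,
                        n_agents=n_agents,
                        entrants_per_year=max(1, round(n_agents / 45)), seed=seed)
    if priors is None:
        priors = build_prior_library()
    free = set(free_params) if free_params is not None else set(PARAM_DEFS)

    truth: dict[str, ParameterSet] = {c: {} for c in countries}
    for name in sorted(PARAM_DEFS):
        prior = priors[name]
        if name in free:
            shared = [rng.normal(0.0, s) if s > 0 else 0.0 for s in prior.level_sds[:-1]]
            for c in countries:
                c_off = rng.normal(0.0, prior.level_sds[-1]) if prior.level_sds[-1] > 0 else 0.0
                offsets = dict(zip(LEVELS, [*shared, c_off]))
                truth[c][name] = resolve_parameter(prior, c, offsets, hierarchy)
        else:
            zero = dict.fromkeys(LEVELS, 0.0)
            for c in countries:
                truth[c][name] = resolve_parameter(prior, c, zero, hierarchy)

    # urban/rural × education composition: Dirichlet around a rural-low-heavy
    # profile typical of high-burden settings
    base = np.array([6.0, 4.0, 2.0, 3.0, 3.0, 2.0])  # rural l/m/h, urban l/m/h
    world.subgroup_shares = {
        c: list(np.round(rng.dirichlet(base * 10), 9)) for c in countries}
    for c in countries:
        s = np.asarray(world.subgroup_shares[c])
        world.subgroup_shares[c] = list(s / s.sum())

    lifetables = {}
    for c in countries:
        level = float(np.exp(rng.normal(0.0, 0.2)))
        lifetables[c] = synthetic_lifetable(c, years, level=level)
    return world, truth, lifetables


def generate_synthetic_targets(
    world: WorldConfig,
    truth: dict[str, ParameterSet],
    lifetables: dict[str, LifeTable],
    seed: int,
    noise_sd: float = 0.0,
    cut_year: int = 2015,
    reps: int = 1,
    survey_every: int = 5,
) -> pd.DataFrame:
    """Calibration targets from the engine run under the recorded truth.

    Vital-registration (CRVS) targets are *reported* maternal-death counts
    — true deaths thinned by the underreporting model — total and by the
    eight grouped causes, one per country-year in the reporting window.
    Survey-source targets (total reported deaths, active case finding)
    appear every ``survey_every`` years.  Gaussian observation noise of sd
    ``noise_sd`` is added on top; targets are tagged train/test at
    ``cut_year``.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    scale = world.persons_per_agent
    rows = []
    for ci, country in enumerate(world.countries):
        frames = []
        for r in range(reps):
            settings = world.settings_for(country, seed + 7919 * r + 104729 * ci)
            frames.append(tally_frame(
                simulate_country(truth[country], lifetables[country], settings)))
        mean = sum(f.drop(columns=["country"]).set_index("year") for f in frames) / reps
        for year, row in mean.iterrows():
            if year < world.report_from:
                continue
            rows.append((country, int(year), "reported_maternal_deaths", "total",
                         scale * row["reported_crvs_total"], "CRVS", 1.0))
            for cause in CAUSE_TARGETS:
                rows.append((country, int(year), "reported_maternal_deaths", cause,
                             scale * row[f"reported_crvs_{cause}"], "CRVS", 1.0))
            if (year - world.report_from) % survey_every == 0:
                rows.append((country, int(year), "reported_maternal_deaths", "total",
                             scale * row["reported_survey_total"], "survey", 1.0))
    df = pd.DataFrame(rows, columns=["country", "year", "indicator", "cause",
                                     "value", "source", "weight"])
    if noise_sd > 0:
        df["value"] = np.maximum(0.0, df["value"] + rng.normal(0, noise_sd, len(df)))
    df["split"] = np.where(df["year"] <= cut_year, "train", "test")
    return df
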