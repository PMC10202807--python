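"""Shared fixtures: stripped-down parameter sets and constant lifetables.

"Stripped" means every stochastic channel (losses, contraception, care
seeking, complications, background mortality trends) is switched off so a
test can turn exactly one channel back on and compare against a closed
form.
"""

from __future__ import annotations

import numpy as np
import pytest

from maternalsim.lifetables import AGE_HI, AGE_LO, LifeTable
from maternalsim.params import BAND_SUFFIX, INTERVENTIONS, SITES, default_parameter_set

OFF = -40.0  # logit-scale minus infinity for practical purposes


def stripped_pset(**overrides):
    """Defaults with all hazards/processes off; overrides re-enable."""
    p = default_parameter_set()
    for suf in BAND_SUFFIX:
        p[f"bio.miscarriage.{suf}"] = 0.0
        p[f"bio.ectopic.naive.{suf}"] = 0.0
        p[f"bio.stillbirth.antepartum.{suf}"] = 0.0
        p[f"bio.twin.di.{suf}"] = 0.0
    p["bio.twin.mono"] = 0.0
    p["bio.breastfeed.p_any"] = 0.0
    p["fp.abortion.logit0"] = OFF
    p["fp.met_need.logit0"] = OFF
    p["fp.met_need.slope"] = 0.0
    p["hs.anc.logit0"] = OFF
    p["hs.anc.slope"] = 0.0
    p["hs.elective_cs.logit0"] = OFF
    p["hs.elective_cs.slope"] = 0.0
    p["hs.site.facility_slope"] = 0.0
    p["hs.site.urban_shift"] = 0.0
    p["hs.site.edu_shift"] = 0.0
    for s in SITES[1:]:
        p[f"hs.site.logit.{s}"] = OFF        # point mass on home delivery
    for s in SITES:
        p[f"hs.recog.logit.{s}"] = OFF       # no recognition → no referral
    p["hs.quality.slope"] = 0.0
    p["hs.report.slope"] = 0.0
    for name in INTERVENTIONS:
        p[f"int.{name}.avail0"] = 0.0
        p[f"int.{name}.slope"] = 0.0
    for c in ("pe_e", "obstructed", "pph", "sepsis", "other"):
        p[f"comp.inc.{c}"] = 0.0
    p["comp.cfr.ectopic"] = 0.0
    p["comp.late.monthly_hazard"] = 0.0
    p["comp.p_ip_stillbirth"] = 0.0
    p["fp.abortion.slope"] = 0.0
    p["fp.abortion.safe.slope"] = 0.0
    p.update(overrides)
    return p


def flat_fecundity(p, f):
    for suf in BAND_SUFFIX:
        p[f"bio.fecundity.{suf}"] = f
    return p


def constant_lifetable(country: str, years: tuple[int, int], q: float,
                       p_injury: float = 0.0) -> LifeTable:
    yr = np.arange(years[0], years[1] + 1)
    shape = (AGE_HI - AGE_LO, len(yr))
    return LifeTable(country, yr, np.full(shape, q), np.full(shape, p_injury))


@pytest.fixture
def rng():
    return np.random.default_rng(42)
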