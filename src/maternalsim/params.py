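"""Parameter registry: names, scales, defaults, bounds and prior dispersions.

Every tunable quantity in the simulator is a named scalar on a declared
transformed scale (logit for probabilities, log for positive rates and
relative risks, identity for coefficients such as trend slopes or
hemoglobin shifts).  Age-structured quantities are stored as one scalar
per 5-year band (ages 10–50, eight bands).  A country-resolved
``ParameterSet`` is a flat ``{name: natural-scale value}`` mapping;
:func:`compile_params` turns one into the dense arrays the monthly engine
reads.

Fixed structural constants that are not calibrated (age relative-risk
shapes for complications, site gradients for case fatality and
intervention availability) live at the bottom of this module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, logit

from .priors import ParameterPrior, PriorLibrary, transform

# ---------------------------------------------------------------- structure

AGE_BANDS = np.array([10, 15, 20, 25, 30, 35, 40, 45])  # band starts, width 5
N_BANDS = len(AGE_BANDS)
BAND_SUFFIX = [f"a{a}" for a in AGE_BANDS]

SITES = ("home", "home_sba", "nonemoc", "bemoc", "cemoc")
N_SITES = len(SITES)
SITE = {s: i for i, s in enumerate(SITES)}

METHODS = ("none", "short_acting", "long_acting", "permanent", "traditional")

# maternal-death causes; first eight are the grouped maternal causes
CAUSES = (
    "abortive", "hypertensive", "obstructed_labor", "hemorrhage",
    "sepsis", "other_direct", "indirect", "late",
    "injury", "other_nonmaternal",
)
CAUSE = {c: i for i, c in enumerate(CAUSES)}
N_MATERNAL_CAUSES = 8

COMPLICATIONS = ("pe_eclampsia", "obstructed_labor", "pph", "sepsis", "other_direct")

TREND_REF_YEAR = 2000  # trends are linear (damped) in years since this


@dataclass(frozen=True)
class ParamDef:
    scale: str                      # logit | log | identity
    default: float                  # natural scale
    prior_sd: float = 0.2           # overall dispersion budget (transformed scale)
    bounds: tuple[float, float] | None = None


def _band(name: str, scale: str, values, prior_sd=0.15, bounds=None) -> dict[str, ParamDef]:
    return {
        f"{name}.{suf}": ParamDef(scale, float(v), prior_sd, bounds)
        for suf, v in zip(BAND_SUFFIX, values)
    }


PARAM_DEFS: dict[str, ParamDef] = {}

# demography
PARAM_DEFS.update({
    "demog.p_injury": ParamDef("logit", 0.08, 0.2),
    "demog.p_indirect": ParamDef("logit", 0.25, 0.3),
})

# biology
PARAM_DEFS.update(_band("bio.fecundity", "logit",
                        [0.02, 0.18, 0.23, 0.21, 0.17, 0.12, 0.06, 0.02], 0.1))
PARAM_DEFS.update({
    "bio.twin.mono": ParamDef("logit", 0.004, 0.1),
})
PARAM_DEFS.update(_band("bio.twin.di", "logit",
                        [0.002, 0.004, 0.006, 0.008, 0.010, 0.013, 0.015, 0.015], 0.1))
PARAM_DEFS.update({
    "bio.sex_ratio.primary": ParamDef("log", 1.05, 0.01, (0.8, 1.4)),
})
PARAM_DEFS.update(_band("bio.miscarriage", "logit",
                        [0.050, 0.035, 0.030, 0.030, 0.035, 0.050, 0.080, 0.120], 0.1))
PARAM_DEFS.update({
    "bio.miscarriage.rr_history": ParamDef("log", 1.5, 0.1),
})
PARAM_DEFS.update(_band("bio.ectopic.naive", "logit",
                        [0.008, 0.010, 0.012, 0.015, 0.018, 0.022, 0.026, 0.030], 0.1))
PARAM_DEFS.update({
    "bio.ectopic.rr_recurrence": ParamDef("log", 3.0, 0.1),
})
PARAM_DEFS.update(_band("bio.stillbirth.antepartum", "logit",
                        [0.004, 0.003, 0.0025, 0.0025, 0.003, 0.004, 0.006, 0.008], 0.1))
PARAM_DEFS.update({
    "bio.stillbirth.rr_male": ParamDef("log", 1.10, 0.05),
    "bio.delivery.p7": ParamDef("identity", 0.02, 0.0, (0.0, 1.0)),
    "bio.delivery.p8": ParamDef("identity", 0.08, 0.0, (0.0, 1.0)),
    "bio.delivery.p9": ParamDef("identity", 0.55, 0.0, (0.0, 1.0)),
    "bio.delivery.p10": ParamDef("identity", 0.35, 0.0, (0.0, 1.0)),
    "bio.lam.exclusive_multiplier": ParamDef("logit", 0.10, 0.15),
    "bio.lam.nonexclusive_multiplier": ParamDef("logit", 0.60, 0.15),
    "bio.breastfeed.p_any": ParamDef("logit", 0.90, 0.15),
    "bio.breastfeed.p_exclusive": ParamDef("logit", 0.50, 0.15),
    "bio.breastfeed.mean_months": ParamDef("log", 12.0, 0.1, (1.0, 36.0)),
    "bio.menopause.mean_years": ParamDef("identity", 49.0, 0.3, (42.0, 56.0)),
    "bio.menopause.sd_years": ParamDef("log", 3.0, 0.1, (0.5, 8.0)),
    "bio.hb.mean": ParamDef("identity", 11.9, 0.15, (8.0, 15.0)),
    "bio.hb.sd": ParamDef("log", 1.5, 0.1, (0.5, 3.0)),
    "bio.hb.urban_shift": ParamDef("identity", 0.2, 0.05),
    "bio.hb.edu_shift": ParamDef("identity", 0.2, 0.05),
})

# family planning
PARAM_DEFS.update({
    "fp.debut.median_years": ParamDef("identity", 17.5, 0.3, (12.0, 30.0)),
    "fp.debut.urban_shift": ParamDef("identity", 0.5, 0.1),
    "fp.debut.edu_shift": ParamDef("identity", 0.5, 0.1),
    "fp.debut.log_sd": ParamDef("log", 0.08, 0.1, (0.005, 0.5)),
    "fp.desired.lambda": ParamDef("log", 3.5, 0.15, (0.3, 10.0)),
    "fp.desired.urban_shift": ParamDef("identity", -0.5, 0.1),
    "fp.desired.edu_shift": ParamDef("identity", -0.4, 0.1),
    "fp.desired.inflate_w": ParamDef("logit", 0.15, 0.15),
    "fp.desired.inflate_k": ParamDef("identity", 2.0, 0.0, (0.0, 10.0)),
    "fp.met_need.logit0": ParamDef("identity", -0.4, 0.25),
    "fp.met_need.slope": ParamDef("identity", 0.03, 0.01),
    "fp.met_need.damping": ParamDef("identity", 1.0, 0.0, (0.05, 1.0)),
    "fp.met_need.urban_shift": ParamDef("identity", 0.3, 0.1),
    "fp.met_need.edu_shift": ParamDef("identity", 0.25, 0.1),
    "fp.mix.spacing.short_acting": ParamDef("identity", 0.50, 0.0, (0.0, 1.0)),
    "fp.mix.spacing.long_acting": ParamDef("identity", 0.20, 0.0, (0.0, 1.0)),
    "fp.mix.spacing.permanent": ParamDef("identity", 0.0, 0.0, (0.0, 1.0)),
    "fp.mix.spacing.traditional": ParamDef("identity", 0.30, 0.0, (0.0, 1.0)),
    "fp.mix.limiting.short_acting": ParamDef("identity", 0.30, 0.0, (0.0, 1.0)),
    "fp.mix.limiting.long_acting": ParamDef("identity", 0.40, 0.0, (0.0, 1.0)),
    "fp.mix.limiting.permanent": ParamDef("identity", 0.20, 0.0, (0.0, 1.0)),
    "fp.mix.limiting.traditional": ParamDef("identity", 0.10, 0.0, (0.0, 1.0)),
    "fp.fail.annual.short_acting": ParamDef("logit", 0.09, 0.15),
    "fp.fail.annual.long_acting": ParamDef("logit", 0.01, 0.15),
    "fp.fail.annual.permanent": ParamDef("logit", 0.001, 0.15),
    "fp.fail.annual.traditional": ParamDef("logit", 0.20, 0.15),
    "fp.duration.mean_months": ParamDef("log", 24.0, 0.15, (3.0, 120.0)),
    "fp.p_switch": ParamDef("logit", 0.5, 0.15),
    "fp.spacing_window_months": ParamDef("identity", 24.0, 0.0, (6.0, 60.0)),
    "fp.abortion.logit0": ParamDef("identity", -0.85, 0.3),
    "fp.abortion.slope": ParamDef("identity", 0.0, 0.01),
    "fp.abortion.damping": ParamDef("identity", 1.0, 0.0, (0.05, 1.0)),
    "fp.abortion.safe.logit0": ParamDef("identity", 0.0, 0.3),
    "fp.abortion.safe.slope": ParamDef("identity", 0.02, 0.01),
    "fp.abortion.cfr_unsafe": ParamDef("logit", 0.003, 0.3),
    "fp.abortion.rr_cfr_anemia": ParamDef("log", 1.5, 0.1),
    "fp.abortion.p_infertility_unsafe": ParamDef("logit", 0.05, 0.2),
    "fp.sex_ratio.secondary": ParamDef("log", 1.05, 0.01, (0.8, 1.6)),
})

# health system
PARAM_DEFS.update({
    "hs.anc.logit0": ParamDef("identity", 0.85, 0.25),
    "hs.anc.slope": ParamDef("identity", 0.03, 0.01),
    "hs.anc.lambda": ParamDef("log", 3.5, 0.1, (0.2, 12.0)),
    "hs.anc.hb_per_visit": ParamDef("identity", 0.08, 0.03, (0.0, 1.0)),
    "hs.anc.recog_logit_per_visit": ParamDef("identity", 0.12, 0.03, (0.0, 1.0)),
    "hs.site.logit.home_sba": ParamDef("identity", -0.5, 0.2),
    "hs.site.logit.nonemoc": ParamDef("identity", -0.7, 0.2),
    "hs.site.logit.bemoc": ParamDef("identity", -0.9, 0.2),
    "hs.site.logit.cemoc": ParamDef("identity", -1.2, 0.2),
    "hs.site.facility_slope": ParamDef("identity", 0.04, 0.01),
    "hs.site.urban_shift": ParamDef("identity", 0.4, 0.1),
    "hs.site.edu_shift": ParamDef("identity", 0.3, 0.1),
    "hs.elective_cs.logit0": ParamDef("identity", -3.0, 0.3),
    "hs.elective_cs.slope": ParamDef("identity", 0.05, 0.01),
    "hs.recog.logit.home": ParamDef("identity", -0.85, 0.2),
    "hs.recog.logit.home_sba": ParamDef("identity", -0.40, 0.2),
    "hs.recog.logit.nonemoc": ParamDef("identity", 0.0, 0.2),
    "hs.recog.logit.bemoc": ParamDef("identity", 0.85, 0.2),
    "hs.recog.logit.cemoc": ParamDef("identity", 1.40, 0.2),
    "hs.recog.severe_boost": ParamDef("identity", 1.0, 0.1, (0.0, 4.0)),
    "hs.transport.home": ParamDef("logit", 0.50, 0.2),
    "hs.transport.home_sba": ParamDef("logit", 0.55, 0.2),
    "hs.transport.nonemoc": ParamDef("logit", 0.65, 0.2),
    "hs.transport.bemoc": ParamDef("logit", 0.75, 0.2),
    "hs.refer.p_bypass": ParamDef("logit", 0.5, 0.2),
    "hs.refer.p_horizontal": ParamDef("logit", 0.1, 0.2),
    "hs.quality.logit.home": ParamDef("identity", -1.40, 0.25),
    "hs.quality.logit.home_sba": ParamDef("identity", -0.85, 0.25),
    "hs.quality.logit.nonemoc": ParamDef("identity", -0.40, 0.25),
    "hs.quality.logit.bemoc": ParamDef("identity", 0.40, 0.25),
    "hs.quality.logit.cemoc": ParamDef("identity", 1.40, 0.25),
    "hs.quality.slope": ParamDef("identity", 0.02, 0.01),
    "hs.report.crvs.logit.home": ParamDef("identity", -0.85, 0.3),
    "hs.report.crvs.logit.home_sba": ParamDef("identity", -0.40, 0.3),
    "hs.report.crvs.logit.nonemoc": ParamDef("identity", 0.0, 0.3),
    "hs.report.crvs.logit.bemoc": ParamDef("identity", 0.85, 0.3),
    "hs.report.crvs.logit.cemoc": ParamDef("identity", 1.40, 0.3),
    # country-level reporting-completeness offset added to every site logit
    "hs.report.crvs.shift": ParamDef("identity", 0.0, 0.3),
    "hs.report.slope": ParamDef("identity", 0.03, 0.01),
    "hs.report.survey_boost": ParamDef("log", 0.7, 0.2, (0.0, 5.0)),
})

# obstetric complications
PARAM_DEFS.update({
    "comp.inc.pe_e": ParamDef("logit", 0.04, 0.25),
    "comp.inc.obstructed": ParamDef("logit", 0.04, 0.25),
    "comp.inc.pph": ParamDef("logit", 0.06, 0.25),
    "comp.inc.sepsis": ParamDef("logit", 0.03, 0.25),
    "comp.inc.other": ParamDef("logit", 0.02, 0.25),
    "comp.rr.pe_e.anemia": ParamDef("log", 1.2, 0.1),
    "comp.rr.pe_e.twin": ParamDef("log", 2.0, 0.1),
    "comp.rr.pe_e.history": ParamDef("log", 3.0, 0.1),
    "comp.rr.pph.anemia": ParamDef("log", 1.5, 0.1),
    "comp.rr.sepsis.anemia": ParamDef("log", 1.3, 0.1),
    "comp.rr.sepsis.csection": ParamDef("log", 2.0, 0.1),
    "comp.sev.pe_e": ParamDef("logit", 0.25, 0.15),
    "comp.sev.obstructed": ParamDef("logit", 0.30, 0.15),
    "comp.sev.pph": ParamDef("logit", 0.25, 0.15),
    "comp.sev.sepsis": ParamDef("logit", 0.30, 0.15),
    "comp.cfr.pe_e": ParamDef("logit", 0.10, 0.3),
    "comp.cfr.obstructed": ParamDef("logit", 0.08, 0.3),
    "comp.cfr.pph": ParamDef("logit", 0.12, 0.3),
    "comp.cfr.sepsis": ParamDef("logit", 0.10, 0.3),
    "comp.cfr.other": ParamDef("logit", 0.05, 0.3),
    "comp.cfr.ectopic": ParamDef("logit", 0.08, 0.3),
    "comp.cfr.nonsevere_frac": ParamDef("logit", 0.10, 0.2),
    "comp.p_ip_stillbirth": ParamDef("logit", 0.30, 0.2),
    "comp.late.monthly_hazard": ParamDef("logit", 2e-5, 0.3),
})

# clinical interventions: (kind, minimum site, efficacy RR or recognition boost)
INTERVENTIONS = {
    "amtsl": ("preventive", SITE["home_sba"], 0.40),        # RR on PPH incidence
    "clean_delivery": ("preventive", SITE["home_sba"], 0.40),  # RR on sepsis incidence
    "partograph": ("preventive", SITE["home_sba"], 0.80),   # recognition logit boost
    "hypertension_mgmt": ("curative", SITE["bemoc"], 0.40),
    "assisted_delivery": ("curative", SITE["bemoc"], 0.50),
    "hemorrhage_mgmt": ("curative", SITE["bemoc"], 0.35),
    "antibiotics": ("curative", SITE["nonemoc"], 0.30),
    "ectopic_mgmt": ("curative", SITE["cemoc"], 0.10),
}
for _name, (_kind, _minsite, _eff) in INTERVENTIONS.items():
    PARAM_DEFS[f"int.{_name}.avail0"] = ParamDef("identity", 0.5, 0.2)
    PARAM_DEFS[f"int.{_name}.slope"] = ParamDef("identity", 0.03, 0.01)
    if _name == "partograph":
        PARAM_DEFS[f"int.{_name}.recog_boost"] = ParamDef("identity", _eff, 0.1, (0.0, 3.0))
    else:
        PARAM_DEFS[f"int.{_name}.rr_eff"] = ParamDef("logit", _eff, 0.1)

# ----------------------------------------------------- structural constants

# age relative-risk shapes for complication incidence (per band, ages 10-50)
AGE_RR_PE_E = np.array([1.8, 1.4, 1.0, 1.0, 1.1, 1.3, 1.6, 1.8])
AGE_RR_OBSTRUCTED = np.array([2.0, 1.5, 1.0, 1.0, 1.0, 1.1, 1.2, 1.3])
# case-fatality gradient by treatment site (multiplies the severe home CFR)
CFR_SITE_RR = np.array([1.0, 0.9, 0.8, 0.6, 0.4])
# site gradient added to every intervention availability logit
AVAIL_SITE_SHIFT = np.array([-3.0, -1.5, -0.5, 0.5, 1.5])
# required care level: (complication index, severe?) -> minimum adequate site
REQUIRED_SITE_NONSEVERE = np.array([SITE["bemoc"]] * len(COMPLICATIONS))
REQUIRED_SITE_SEVERE = np.array([
    SITE["bemoc"],   # pe_eclampsia
    SITE["cemoc"],   # obstructed labor (surgical delivery)
    SITE["cemoc"],   # pph
    SITE["bemoc"],   # sepsis
    SITE["bemoc"],   # other direct
])

ParameterSet = dict  # {name: natural-scale float}


def default_parameter_set() -> ParameterSet:
    return {name: d.default for name, d in PARAM_DEFS.items()}


def validate_parameter_set(pset: ParameterSet) -> None:
    for name, value in pset.items():
        d = PARAM_DEFS.get(name)
        if d is None:
            raise KeyError(f"unknown parameter {name!r}")
        if d.scale == "logit" and not (0.0 <= value <= 1.0):
            raise ValueError(f"{name}: probability {value} outside [0, 1]")
        if d.scale == "log" and value < 0:
            raise ValueError(f"{name}: rate {value} negative")
        if d.bounds is not None and not (d.bounds[0] <= value <= d.bounds[1]):
            raise ValueError(f"{name}: {value} outside bounds {d.bounds}")


def build_prior_library(pset: ParameterSet | None = None) -> PriorLibrary:
    """Five-level priors centred on ``pset`` (default registry values).

    The per-parameter dispersion budget is split across levels with most
    spread at the global level and progressively tighter offsets at finer
    levels (hierarchical shrinkage).
    """
    if pset is None:
        pset = default_parameter_set()
    split = np.array([0.5, 0.4, 0.3, 0.25, 0.25])
    lib = PriorLibrary()
    for name, d in PARAM_DEFS.items():
        centre = float(transform(pset[name], d.scale)) if d.scale != "logit" else float(
            logit(min(max(pset[name], 1e-9), 1 - 1e-9)))
        sds = tuple(float(s) for s in d.prior_sd * split)
        means = (centre, 0.0, 0.0, 0.0, 0.0)
        lib.add(ParameterPrior(name, d.scale, means, sds, d.bounds))
    return lib


def band_index(age_years) -> np.ndarray:
    """Half-open 5-year band index for ages; clipped to the 10-50 range."""
    return np.clip(((np.asarray(age_years) - 10) // 5).astype(int), 0, N_BANDS - 1)


def _arr(pset, name) -> np.ndarray:
    return np.array([pset[f"{name}.{suf}"] for suf in BAND_SUFFIX])


class CompiledParams:
    """Dense, year-indexed view of one country's ParameterSet.

    All trend-bearing quantities are pre-evaluated for every simulated
    year; the monthly loop then only does array lookups.  ``years`` is the
    inclusive [start, end] range of calendar years simulated.
    """

    def __init__(self, pset: ParameterSet, years: tuple[int, int]):
        validate_parameter_set(pset)
        self.pset = dict(pset)
        self.start_year, self.end_year = years
        n_years = self.end_year - self.start_year + 1
        t = np.arange(self.start_year, self.end_year + 1) - TREND_REF_YEAR
        t = np.maximum(t, 0.0)  # trends flat before the reference year
        p = pset

        # demography / biology
        self.p_injury = p["demog.p_injury"]
        self.p_indirect = p["demog.p_indirect"]
        self.fecundity = _arr(p, "bio.fecundity")
        self.twin_mono = p["bio.twin.mono"]
        self.twin_di = _arr(p, "bio.twin.di")
        self.p_female = 1.0 / (1.0 + p["bio.sex_ratio.primary"])
        self.miscarriage = _arr(p, "bio.miscarriage")
        self.rr_miscarriage_history = p["bio.miscarriage.rr_history"]
        self.ectopic_naive = _arr(p, "bio.ectopic.naive")
        self.rr_ectopic_recurrence = p["bio.ectopic.rr_recurrence"]
        self.stillbirth = _arr(p, "bio.stillbirth.antepartum")
        self.rr_stillbirth_male = p["bio.stillbirth.rr_male"]
        dm = np.array([p["bio.delivery.p7"], p["bio.delivery.p8"],
                       p["bio.delivery.p9"], p["bio.delivery.p10"]])
        if abs(dm.sum() - 1.0) > 1e-6:
            raise ValueError(f"delivery-month distribution sums to {dm.sum()}, not 1")
        self.delivery_month_dist = dm / dm.sum()
        self.lam_exclusive = p["bio.lam.exclusive_multiplier"]
        self.lam_nonexclusive = p["bio.lam.nonexclusive_multiplier"]
        self.bf_p_any = p["bio.breastfeed.p_any"]
        self.bf_p_exclusive = p["bio.breastfeed.p_exclusive"]
        self.bf_mean_months = p["bio.breastfeed.mean_months"]
        self.menopause_mean_m = p["bio.menopause.mean_years"] * 12.0
        self.menopause_sd_m = p["bio.menopause.sd_years"] * 12.0
        # hemoglobin mean per subgroup (residence*3 + education)
        sg_res = np.repeat([0, 1], 3)
        sg_edu = np.tile([0, 1, 2], 2)
        self.hb_mean_sg = (p["bio.hb.mean"] + p["bio.hb.urban_shift"] * sg_res
                           + p["bio.hb.edu_shift"] * (sg_edu - 1))
        self.hb_sd = p["bio.hb.sd"]

        # family planning
        self.debut_median_m = np.clip(
            (p["fp.debut.median_years"] + p["fp.debut.urban_shift"] * sg_res
             + p["fp.debut.edu_shift"] * (sg_edu - 1)), 10.0, 40.0) * 12.0
        self.debut_log_sd = p["fp.debut.log_sd"]
        self.desired_lambda_sg = np.clip(
            p["fp.desired.lambda"] + p["fp.desired.urban_shift"] * sg_res
            + p["fp.desired.edu_shift"] * (sg_edu - 1), 0.2, None)
        self.desired_w = p["fp.desired.inflate_w"]
        self.desired_k = int(round(p["fp.desired.inflate_k"]))
        # met need: [year, subgroup]
        shift = (p["fp.met_need.urban_shift"] * sg_res
                 + p["fp.met_need.edu_shift"] * (sg_edu - 1))
        te = _eff_time(t, p["fp.met_need.damping"])
        self.met_need = expit(p["fp.met_need.logit0"]
                              + p["fp.met_need.slope"] * te[:, None] + shift[None, :])
        mix_sp = np.array([p[f"fp.mix.spacing.{m}"] for m in METHODS[1:]])
        mix_li = np.array([p[f"fp.mix.limiting.{m}"] for m in METHODS[1:]])
        for nm, mx in (("spacing", mix_sp), ("limiting", mix_li)):
            if abs(mx.sum() - 1.0) > 1e-6:
                raise ValueError(f"{nm} method mix sums to {mx.sum()}, not 1")
        self.mix_spacing = mix_sp / mix_sp.sum()
        self.mix_limiting = mix_li / mix_li.sum()
        self.fail_monthly = np.array(
            [0.0] + [annual_to_monthly(p[f"fp.fail.annual.{m}"]) for m in METHODS[1:]])
        self.duration_mean = p["fp.duration.mean_months"]
        self.p_switch = p["fp.p_switch"]
        self.spacing_window = int(round(p["fp.spacing_window_months"]))
        te_ab = _eff_time(t, p["fp.abortion.damping"])
        self.p_abortion = expit(p["fp.abortion.logit0"] + p["fp.abortion.slope"] * te_ab)
        self.p_abortion_safe = expit(p["fp.abortion.safe.logit0"]
                                     + p["fp.abortion.safe.slope"] * t)
        self.cfr_unsafe_abortion = p["fp.abortion.cfr_unsafe"]
        self.rr_abortion_cfr_anemia = p["fp.abortion.rr_cfr_anemia"]
        self.p_infertility_unsafe = p["fp.abortion.p_infertility_unsafe"]
        # all-female pregnancies face an elevated abortion probability chosen
        # so the birth sex ratio moves from the primary to the secondary ratio
        self.sr_primary = p["bio.sex_ratio.primary"]
        self.sr_secondary = p["fp.sex_ratio.secondary"]
        self.p_abortion_female = female_abortion_probability(
            self.p_abortion, self.sr_primary, self.sr_secondary)

        # health system
        self.anc_p_any = expit(p["hs.anc.logit0"] + p["hs.anc.slope"] * t)
        self.anc_lambda = p["hs.anc.lambda"]
        self.anc_hb_per_visit = p["hs.anc.hb_per_visit"]
        self.anc_recog_per_visit = p["hs.anc.recog_logit_per_visit"]
        # delivery-site multinomial: [year, subgroup, site]
        fac_logits = np.array([p["hs.site.logit.home_sba"], p["hs.site.logit.nonemoc"],
                               p["hs.site.logit.bemoc"], p["hs.site.logit.cemoc"]])
        sgsh = (p["hs.site.urban_shift"] * sg_res + p["hs.site.edu_shift"] * (sg_edu - 1))
        z = np.zeros((n_years, 6, N_SITES))
        z[:, :, 1:] = (fac_logits[None, None, :]
                       + p["hs.site.facility_slope"] * t[:, None, None]
                       + sgsh[None, :, None])
        ez = np.exp(z - z.max(axis=2, keepdims=True))
        self.site_shares = ez / ez.sum(axis=2, keepdims=True)
        self.p_elective_cs = expit(p["hs.elective_cs.logit0"] + p["hs.elective_cs.slope"] * t)
        self.recog_logit_site = np.array([p[f"hs.recog.logit.{s}"] for s in SITES])
        self.recog_severe_boost = p["hs.recog.severe_boost"]
        self.transport = np.array([p[f"hs.transport.{s}"] for s in SITES[:4]] + [1.0])
        self.p_bypass = p["hs.refer.p_bypass"]
        self.p_horizontal = p["hs.refer.p_horizontal"]
        # quality kappa: [year, site]
        qlog = np.array([p[f"hs.quality.logit.{s}"] for s in SITES])
        self.quality = expit(qlog[None, :] + p["hs.quality.slope"] * t[:, None])
        # death-capture probabilities: [year, site], survey >= CRVS by construction
        rlog = np.array([p[f"hs.report.crvs.logit.{s}"] for s in SITES])
        base = (rlog[None, :] + p["hs.report.crvs.shift"]
                + p["hs.report.slope"] * t[:, None])
        self.capture_crvs = expit(base)
        self.capture_survey = expit(base + p["hs.report.survey_boost"])

        # complications
        self.inc = np.array([p["comp.inc.pe_e"], p["comp.inc.obstructed"],
                             p["comp.inc.pph"], p["comp.inc.sepsis"], p["comp.inc.other"]])
        self.rr_pe_e_anemia = p["comp.rr.pe_e.anemia"]
        self.rr_pe_e_twin = p["comp.rr.pe_e.twin"]
        self.rr_pe_e_history = p["comp.rr.pe_e.history"]
        self.rr_pph_anemia = p["comp.rr.pph.anemia"]
        self.rr_sepsis_anemia = p["comp.rr.sepsis.anemia"]
        self.rr_sepsis_cs = p["comp.rr.sepsis.csection"]
        self.severity = np.array([p["comp.sev.pe_e"], p["comp.sev.obstructed"],
                                  p["comp.sev.pph"], p["comp.sev.sepsis"], 1.0])
        self.cfr_severe = np.array([p["comp.cfr.pe_e"], p["comp.cfr.obstructed"],
                                    p["comp.cfr.pph"], p["comp.cfr.sepsis"],
                                    p["comp.cfr.other"]])
        self.cfr_ectopic = p["comp.cfr.ectopic"]
        self.cfr_nonsevere_frac = p["comp.cfr.nonsevere_frac"]
        self.p_ip_stillbirth = p["comp.p_ip_stillbirth"]
        self.late_monthly_hazard = p["comp.late.monthly_hazard"]

        # interventions: availability [name][year, site]
        self.avail = {}
        for name in INTERVENTIONS:
            a0 = p[f"int.{name}.avail0"]
            z0 = np.log(a0 / (1 - a0)) if 0 < a0 < 1 else (10.0 if a0 >= 1 else -10.0)
            self.avail[name] = expit(z0 + AVAIL_SITE_SHIFT[None, :]
                                     + p[f"int.{name}.slope"] * t[:, None])
        self.int_rr = {name: p[f"int.{name}.rr_eff"]
                       for name in INTERVENTIONS if name != "partograph"}
        self.partograph_boost = p["int.partograph.recog_boost"]

    def year_index(self, year: int) -> int:
        if not (self.start_year <= year <= self.end_year):
            raise KeyError(f"year {year} outside compiled range "
                           f"[{self.start_year}, {self.end_year}]")
        return year - self.start_year


def _eff_time(t, alpha: float):
    t = np.asarray(t, dtype=float)
    if alpha == 1.0:
        return t
    return (1.0 - alpha**t) / (1.0 - alpha)


def annual_to_monthly(q: float):
    """Monthly probability whose 12-fold compounding reproduces annual q."""
    q = np.asarray(q, dtype=float)
    if np.any((q < 0) | (q > 1)):
        raise ValueError("annual probability outside [0, 1]")
    return 1.0 - (1.0 - q) ** (1.0 / 12.0)


def female_abortion_probability(p, sr_primary: float, sr_secondary: float):
    """Abortion probability for all-female pregnancies.

    Solves, in expectation, for the probability p_f that maps the sex ratio
    at conception (primary, male/female) to the sex ratio at birth
    (secondary) when male-bearing pregnancies abort with probability ``p``:
    carrying ratio SR1·(1-p)/(1-p_f) = SR2, hence
    p_f = 1 - (1-p)·SR1/SR2, clipped to [0, 1].  Equal ratios give p_f = p.
    """
    if sr_primary <= 0 or sr_secondary <= 0:
        raise ValueError("sex ratios must be positive")
    p = np.asarray(p, dtype=float)
    return np.clip(1.0 - (1.0 - p) * sr_primary / sr_secondary, 0.0, 1.0)
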