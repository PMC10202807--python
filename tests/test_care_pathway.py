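"""ANC, delivery sites, complications, referral, effectiveness, reporting."""

import numpy as np
import pytest

from maternalsim import care_pathway as care
from maternalsim.params import SITE, SITES, CompiledParams, default_parameter_set
from tests.conftest import OFF, stripped_pset

YEARS = (2000, 2000)


def cp_with(**over):
    return CompiledParams(stripped_pset(**over), YEARS)


class TestAntenatalCare:
    def test_no_any_visit_probability_means_zero_visits(self, rng):
        visits = care.anc_visits(0, cp_with(), rng, 1000)  # p_any ≈ 0
        assert np.all(visits == 0)

    def test_truncated_poisson_mean(self, rng):
        # zero-truncated Poisson(4): mean 4/(1-e^-4) = 4.0746
        draws = care.zero_truncated_poisson(4.0, rng, 10**5)
        assert np.all(draws >= 1)
        expected = 4.0 / (1 - np.exp(-4.0))
        assert abs(draws.mean() - expected) < 3 * 2.0 / np.sqrt(10**5)

    def test_hemoglobin_gain_is_linear_in_visits(self):
        cp = cp_with(**{"hs.anc.hb_per_visit": 0.1})
        assert 4 * cp.anc_hb_per_visit == pytest.approx(0.4)


class TestEffectiveness:
    def test_full_availability_and_quality_yields_efficacy(self):
        assert care.effectiveness(1.0, 1.0, 0.3) == pytest.approx(0.3)

    def test_unavailable_intervention_has_no_effect(self):
        assert care.effectiveness(0.0, 0.7, 0.3) == 1.0

    def test_interpolation_formula(self):
        # 1 - 0.8·0.5·(1-0.3) = 0.72
        assert care.effectiveness(0.8, 0.5, 0.3) == pytest.approx(0.72, abs=1e-9)

    def test_below_minimum_site_returns_unit_rr(self):
        cp = cp_with(**{"int.hemorrhage_mgmt.avail0": 0.9})
        rr = care.intervention_rr("hemorrhage_mgmt", SITE["home"], 0, cp)
        assert rr == 1.0

    def test_applied_rr_bounded_by_efficacy_and_one(self):
        cp = CompiledParams(default_parameter_set(), YEARS)
        for name in cp.int_rr:
            for s in range(5):
                rr = float(care.intervention_rr(name, s, 0, cp))
                assert cp.int_rr[name] - 1e-12 <= rr <= 1.0 + 1e-12


class TestDeliverySite:
    def test_point_mass_home(self, rng):
        site, cs = care.choose_delivery_site(np.zeros(500, int), 0, cp_with(), rng)
        assert np.all(site == SITE["home"])
        assert not cs.any()

    def test_multinomial_shares_match_softmax(self, rng):
        over = {f"hs.site.logit.{s}": z for s, z in
                zip(SITES[1:], [-0.4, -0.1, 0.3, 0.6])}
        over.update({"hs.site.urban_shift": 0.0, "hs.site.edu_shift": 0.0,
                     "hs.site.facility_slope": 0.0})
        cp = cp_with(**over)
        expected = cp.site_shares[0, 0]
        site, _ = care.choose_delivery_site(np.zeros(10**5, int), 0, cp, rng)
        for s in range(5):
            freq = (site == s).mean()
            se = np.sqrt(expected[s] * (1 - expected[s]) / 10**5)
            assert abs(freq - expected[s]) < 3 * se + 1e-9

    def test_elective_csection_gated_to_emoc_sites(self, rng):
        cp = cp_with(**{"hs.elective_cs.logit0": 40.0})  # probability ≈ 1
        site, cs = care.choose_delivery_site(np.zeros(500, int), 0, cp, rng)
        assert not cs.any()  # all deliveries at home → gate blocks the flag


class TestComplications:
    def test_zero_base_rates_no_complications(self):
        p = care.complication_probabilities(
            np.full(10, 300), np.zeros(10, bool), np.ones(10, int),
            np.zeros(10, bool), np.zeros(10, bool), np.zeros(10, int), 0, cp_with())
        assert np.all(p == 0)

    def test_anemia_relative_risk_on_pph(self):
        cp = cp_with(**{"comp.inc.pph": 0.05, "comp.rr.pph.anemia": 2.0})
        p = care.complication_probabilities(
            np.array([300]), np.array([True]), np.array([1]),
            np.array([False]), np.array([False]), np.array([SITE["home"]]), 0, cp)
        assert p[0, care.PPH] == pytest.approx(0.10)

    def test_amtsl_scales_pph_incidence_by_applied_rr(self):
        over = {"comp.inc.pph": 0.10, "int.amtsl.avail0": 1.0 - 1e-9,
                "hs.quality.logit.bemoc": 40.0}
        cp = cp_with(**over)
        args = (np.array([300]), np.array([False]), np.array([1]),
                np.array([False]), np.array([False]))
        p_home = care.complication_probabilities(*args, np.array([SITE["home"]]), 0, cp)
        p_bemoc = care.complication_probabilities(*args, np.array([SITE["bemoc"]]), 0, cp)
        rr = float(care.intervention_rr("amtsl", SITE["bemoc"], 0, cp))
        assert p_home[0, care.PPH] == pytest.approx(0.10)
        assert p_bemoc[0, care.PPH] == pytest.approx(0.10 * rr)
        assert rr < 1.0


class TestReferralCascade:
    def test_no_recognition_treated_at_start(self, rng):
        site = np.full(1000, SITE["home"], np.int8)
        treated, recognized = care.referral_cascade(
            care.PPH, np.ones(1000, bool), site, np.zeros(1000), 0, cp_with(), rng)
        assert not recognized.any()
        assert np.all(treated == SITE["home"])

    def test_certain_cascade_reaches_cemoc(self, rng):
        over = {f"hs.recog.logit.{s}": 40.0 for s in SITES}
        over.update({f"hs.transport.{s}": 1.0 for s in SITES[:4]})
        over.update({"hs.refer.p_bypass": 1.0, "hs.refer.p_horizontal": 0.0})
        cp = cp_with(**over)
        site = np.full(500, SITE["home"], np.int8)
        treated, _ = care.referral_cascade(care.PPH, np.ones(500, bool), site,
                                           np.zeros(500), 0, cp, rng)
        assert np.all(treated == SITE["cemoc"])

    def test_arrival_fraction_is_recognition_times_transport(self, rng):
        over = {f"hs.recog.logit.{s}": OFF for s in SITES}
        over["hs.recog.logit.home"] = np.log(0.8 / 0.2)
        over["hs.recog.severe_boost"] = 0.0
        over.update({"hs.transport.home": 0.5, "hs.refer.p_bypass": 1.0,
                     "hs.refer.p_horizontal": 0.0})
        cp = cp_with(**over)
        n = 10**5
        site = np.full(n, SITE["home"], np.int8)
        treated, _ = care.referral_cascade(care.PPH, np.ones(n, bool), site,
                                           np.zeros(n), 0, cp, rng)
        moved = (treated > SITE["home"]).mean()
        se = np.sqrt(0.4 * 0.6 / n)
        assert abs(moved - 0.4) < 3 * se


class TestDeathResolution:
    def test_zero_cfr_no_deaths(self):
        p = care.death_probability(care.PPH, np.ones(5, bool),
                                   np.full(5, SITE["home"]), 0, cp_with(
                                       **{"comp.cfr.pph": 0.0}))
        assert np.all(p == 0)

    def test_cfr_times_intervention_rr(self):
        over = {"comp.cfr.pph": 0.1, "int.hemorrhage_mgmt.avail0": 1.0 - 1e-9,
                "int.hemorrhage_mgmt.rr_eff": 0.2, "hs.quality.logit.cemoc": 40.0}
        cp = cp_with(**over)
        p = care.death_probability(care.PPH, np.array([True]),
                                   np.array([SITE["cemoc"]]), 0, cp)
        from maternalsim.params import CFR_SITE_RR
        assert p[0] == pytest.approx(0.1 * CFR_SITE_RR[SITE["cemoc"]] * 0.2, rel=1e-6)

    def test_nonsevere_fatality_is_fraction_of_severe(self):
        cp = cp_with(**{"comp.cfr.sepsis": 0.2, "comp.cfr.nonsevere_frac": 0.1})
        p_sev = care.death_probability(care.SEPSIS, np.array([True]),
                                       np.array([SITE["home"]]), 0, cp)
        p_non = care.death_probability(care.SEPSIS, np.array([False]),
                                       np.array([SITE["home"]]), 0, cp)
        assert p_non[0] == pytest.approx(0.1 * p_sev[0])


class TestReporting:
    def test_certain_capture_reports_everything(self):
        over = {f"hs.report.crvs.logit.{s}": 40.0 for s in SITES}
        cp = cp_with(**over)
        p = care.capture_probability("crvs", np.arange(5), 0, cp)
        np.testing.assert_allclose(p, 1.0)

    def test_reported_fraction_binomial(self, rng):
        over = {f"hs.report.crvs.logit.{s}": float(np.log(0.6 / 0.4)) for s in SITES}
        cp = cp_with(**over)
        p = care.capture_probability("crvs", np.zeros(10**4, int), 0, cp)
        reported = (rng.random(10**4) < p).sum()
        se = np.sqrt(10**4 * 0.6 * 0.4)
        assert abs(reported - 6000) < 3 * se

    def test_survey_capture_at_least_crvs_over_random_parameters(self, rng):
        for trial in range(20):
            pset = default_parameter_set()
            for s in SITES:
                pset[f"hs.report.crvs.logit.{s}"] = rng.normal(0, 2)
            pset["hs.report.survey_boost"] = float(rng.uniform(0, 3))
            pset["hs.report.slope"] = float(rng.normal(0, 0.05))
            cp = CompiledParams(pset, (1995, 2010))
            assert np.all(cp.capture_survey >= cp.capture_crvs - 1e-12)

    def test_unknown_source_rejected(self):
        with pytest.raises(ValueError):
            care.capture_probability("census2", np.zeros(1, int), 0, cp_with())
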