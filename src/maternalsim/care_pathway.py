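"""Delivery care: ANC, site choice, complications, referral, interventions,
death resolution and underreporting.

The cascade follows the three-delays framing: a complication must be
*recognized* (first delay), *transport* must be available (second delay),
and the receiving facility must offer adequate care with sufficient
quality (third delay).  Referral allows bypassing to a comprehensive
facility, horizontal transfer, and at most two hops.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

from .params import (
    CFR_SITE_RR, AGE_RR_OBSTRUCTED, AGE_RR_PE_E, COMPLICATIONS, INTERVENTIONS,
    REQUIRED_SITE_NONSEVERE, REQUIRED_SITE_SEVERE, SITE, CompiledParams, band_index,
)

N_COMP = len(COMPLICATIONS)
PE_E, OBSTRUCTED, PPH, SEPSIS, OTHER = range(N_COMP)

# deterministic priority when several complications draw fatal in one cycle:
# cause bookkeeping allows at most one maternal death per woman
FATAL_PRIORITY = (PPH, SEPSIS, PE_E, OBSTRUCTED, OTHER)

# complication index -> DeathRecord cause name
COMP_CAUSE = ("hypertensive", "obstructed_labor", "hemorrhage", "sepsis", "other_direct")
# complication index -> curative intervention (None for other_direct)
CURATIVE = ("hypertension_mgmt", "assisted_delivery", "hemorrhage_mgmt", "antibiotics", None)


def zero_truncated_poisson(lam: float, rng: np.random.Generator, n: int) -> np.ndarray:
    """Positive-Poisson draws via inverse CDF conditioned on k >= 1."""
    if lam <= 0:
        raise ValueError("lambda must be positive")
    u = rng.random(n)
    # P(K <= k | K >= 1) = (CDF(k) - CDF(0)) / (1 - CDF(0))
    p0 = np.exp(-lam)
    target = p0 + u * (1.0 - p0)
    k = np.ones(n, dtype=np.int64)
    cdf = np.full(n, p0 + lam * p0)  # CDF at 1
    pmf = np.full(n, lam * p0)
    while True:
        below = cdf < target
        if not below.any():
            break
        k[below] += 1
        pmf[below] *= lam / k[below]
        cdf[below] += pmf[below]
    return k


def anc_visits(year_idx: int, cp: CompiledParams, rng: np.random.Generator, n: int):
    """Two-part antenatal-care model: any-visit Bernoulli, then positive Poisson."""
    any_visit = rng.random(n) < cp.anc_p_any[year_idx]
    visits = np.zeros(n, dtype=np.int16)
    m = int(any_visit.sum())
    if m:
        visits[any_visit] = zero_truncated_poisson(cp.anc_lambda, rng, m)
    return visits


def effectiveness(availability, quality, rr_efficacy):
    """Applied relative risk: 1 - a·κ·(1 - RR_efficacy).

    Interpolates between no effect (unavailable or zero quality) and full
    efficacy (available, perfect quality); always within [RR_efficacy, 1].
    """
    a = np.asarray(availability, dtype=float)
    k = np.asarray(quality, dtype=float)
    return 1.0 - a * k * (1.0 - np.asarray(rr_efficacy, dtype=float))


def intervention_rr(name: str, site, year_idx: int, cp: CompiledParams):
    """Applied RR of a named intervention at each woman's site (1 if below
    the intervention's minimum site)."""
    _kind, min_site, _eff = INTERVENTIONS[name]
    site = np.asarray(site)
    a = cp.avail[name][year_idx][site]
    k = cp.quality[year_idx][site]
    rr = effectiveness(a, k, cp.int_rr[name])
    return np.where(site >= min_site, rr, 1.0)


def choose_delivery_site(subgroup, year_idx: int, cp: CompiledParams,
                         rng: np.random.Generator):
    """Starting delivery site (multinomial by year × subgroup) and elective
    C-section flag (facility deliveries only)."""
    sg = np.asarray(subgroup)
    n = len(sg)
    shares = cp.site_shares[year_idx]  # [6, 5]
    u = rng.random(n)
    cum = np.cumsum(shares, axis=1)
    site = (u[:, None] > cum[sg][:, :-1]).sum(axis=1).astype(np.int8)
    at_emoc = site >= SITE["bemoc"]
    elective_cs = at_emoc & (rng.random(n) < cp.p_elective_cs[year_idx])
    return site, elective_cs


def complication_probabilities(age_m, anemic, n_fetus, hist_pe_e, csection,
                               site, year_idx: int, cp: CompiledParams):
    """[n, 5] incidence matrix with risk multipliers and preventive
    interventions (AMTSL on PPH, clean delivery on sepsis) applied."""
    band = band_index(np.asarray(age_m) // 12)
    n = len(band)
    anemic = np.asarray(anemic, bool)
    p = np.empty((n, N_COMP))
    p[:, PE_E] = (cp.inc[PE_E] * AGE_RR_PE_E[band]
                  * np.where(anemic, cp.rr_pe_e_anemia, 1.0)
                  * np.where(np.asarray(n_fetus) >= 2, cp.rr_pe_e_twin, 1.0)
                  * np.where(np.asarray(hist_pe_e, bool), cp.rr_pe_e_history, 1.0))
    p[:, OBSTRUCTED] = cp.inc[OBSTRUCTED] * AGE_RR_OBSTRUCTED[band]
    p[:, PPH] = cp.inc[PPH] * np.where(anemic, cp.rr_pph_anemia, 1.0)
    p[:, SEPSIS] = (cp.inc[SEPSIS] * np.where(anemic, cp.rr_sepsis_anemia, 1.0)
                    * np.where(np.asarray(csection, bool), cp.rr_sepsis_cs, 1.0))
    p[:, OTHER] = cp.inc[OTHER]
    p[:, PPH] *= intervention_rr("amtsl", site, year_idx, cp)
    p[:, SEPSIS] *= intervention_rr("clean_delivery", site, year_idx, cp)
    return np.clip(p, 0.0, 1.0)


def recognition_probability(comp_idx: int, severe, site, visits,
                            year_idx: int, cp: CompiledParams):
    """First delay: probability the complication is recognized/referral is
    initiated.  Rises with site capability, severity and ANC exposure; the
    partograph boosts detection of obstructed labor where available."""
    site = np.asarray(site)
    z = (cp.recog_logit_site[site]
         + cp.recog_severe_boost * np.asarray(severe, float)
         + cp.anc_recog_per_visit * np.asarray(visits, float))
    if comp_idx == OBSTRUCTED:
        _kind, min_site, _eff = INTERVENTIONS["partograph"]
        a = cp.avail["partograph"][year_idx][site]
        k = cp.quality[year_idx][site]
        z = z + np.where(site >= min_site, cp.partograph_boost * a * k, 0.0)
    return expit(z)


def referral_cascade(comp_idx: int, severe, site, visits, year_idx: int,
                     cp: CompiledParams, rng: np.random.Generator):
    """Final treatment site for one complication type across women.

    recognized → transport → target (bypass to CEmOC, else BEmOC; possible
    horizontal transfer); a second hop is allowed when the first target
    still lacks the required care level.  Unrecognized or untransported
    women are treated where they are.
    """
    site = np.asarray(site)
    n = len(site)
    severe = np.asarray(severe, bool)
    required = np.where(severe, REQUIRED_SITE_SEVERE[comp_idx],
                        REQUIRED_SITE_NONSEVERE[comp_idx])
    treated_at = site.copy()

    recognized = rng.random(n) < recognition_probability(
        comp_idx, severe, site, visits, year_idx, cp)
    needs = recognized & (treated_at < required)
    for _hop in range(2):
        if not needs.any():
            break
        moving = needs & (rng.random(n) < cp.transport[treated_at])
        horizontal = moving & (rng.random(n) < cp.p_horizontal)
        vertical = moving & ~horizontal
        bypass = vertical & (rng.random(n) < cp.p_bypass)
        target = np.where(bypass | (treated_at >= SITE["bemoc"]),
                          SITE["cemoc"], SITE["bemoc"])
        treated_at = np.where(vertical, np.maximum(treated_at, target), treated_at)
        needs = recognized & moving & (treated_at < required)
    return treated_at, recognized


def death_probability(comp_idx: int, severe, treated_at, year_idx: int,
                      cp: CompiledParams):
    """CFR(type, severity, site) times the applied RR of the curative
    intervention (if any) at the treatment site."""
    treated_at = np.asarray(treated_at)
    cfr = cp.cfr_severe[comp_idx] * CFR_SITE_RR[treated_at]
    cfr = np.where(np.asarray(severe, bool), cfr, cfr * cp.cfr_nonsevere_frac)
    name = CURATIVE[comp_idx]
    if name is not None:
        cfr = cfr * intervention_rr(name, treated_at, year_idx, cp)
    return np.clip(cfr, 0.0, 1.0)


def capture_probability(source: str, site, year_idx: int, cp: CompiledParams):
    """Probability a maternal death is captured by the reporting system.

    Survey capture (active case finding) is at least CRVS capture (passive
    registration) at the same site and year, by construction.
    """
    site = np.asarray(site)
    if source == "crvs":
        return cp.capture_crvs[year_idx][site]
    if source == "survey":
        return cp.capture_survey[year_idx][site]
    raise ValueError(f"unknown reporting source {source!r}")
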