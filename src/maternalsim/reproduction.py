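"""Conception, pregnancy loss, delivery timing, lactation, menopause, anemia.

All functions are vectorized over women (scalars broadcast), draw nothing
unless handed an ``rng``, and read rates from a
:class:`~maternalsim.params.CompiledParams`.
"""

from __future__ import annotations

import numpy as np
from scipy.special import ndtr, ndtri

from .params import CompiledParams, band_index

MENOPAUSE_TRUNC_YEARS = (40.0, 60.0)
HB_THRESHOLD_PREGNANT = 11.0   # g/dL, anemia cut-off in pregnancy
HB_THRESHOLD_NONPREGNANT = 12.0
MISCARRIAGE_MAX_GEST = 5       # miscarriage hazard applies gestational months 1-5
STILLBIRTH_MIN_GEST = 6        # antepartum stillbirth hazard from month 6
LAM_MAX_POSTPARTUM = 9         # lactational amenorrhea ceases after month 9


def lam_multiplier(postpartum_m, bf_remaining, bf_exclusive, cp: CompiledParams):
    """Fecundity multiplier from lactational amenorrhea.

    Applies only while breastfeeding and within nine months of delivery;
    exclusive breastfeeding suppresses fecundity more strongly.
    """
    postpartum_m = np.asarray(postpartum_m)
    active = (postpartum_m >= 0) & (postpartum_m <= LAM_MAX_POSTPARTUM) & (bf_remaining > 0)
    mult = np.ones(np.broadcast(postpartum_m, bf_remaining, bf_exclusive).shape)
    mult = np.where(active & bf_exclusive, cp.lam_exclusive, mult)
    mult = np.where(active & ~np.asarray(bf_exclusive, bool), cp.lam_nonexclusive, mult)
    return mult


def conception_probability(age_m, method, lam_mult, cp: CompiledParams):
    """Monthly conception probability.

    Unprotected women face age-specific fecundability times the lactational
    multiplier; contraceptive users face only their method's monthly
    failure probability.
    """
    band = band_index(np.asarray(age_m) // 12)
    natural = cp.fecundity[band] * np.asarray(lam_mult)
    return np.where(np.asarray(method) == 0, natural, cp.fail_monthly[np.asarray(method)])


def twin_probability(age_m, cp: CompiledParams):
    band = band_index(np.asarray(age_m) // 12)
    return np.clip(cp.twin_mono + cp.twin_di[band], 0.0, 1.0)


def ectopic_probability(age_m, hist_ectopic, cp: CompiledParams):
    band = band_index(np.asarray(age_m) // 12)
    p = cp.ectopic_naive[band] * np.where(hist_ectopic, cp.rr_ectopic_recurrence, 1.0)
    return np.clip(p, 0.0, 1.0)


def miscarriage_probability(age_m, hist_miscarriage, cp: CompiledParams):
    band = band_index(np.asarray(age_m) // 12)
    p = cp.miscarriage[band] * np.where(hist_miscarriage, cp.rr_miscarriage_history, 1.0)
    return np.clip(p, 0.0, 1.0)


def stillbirth_probabilities(age_m, cp: CompiledParams):
    """(female, male) monthly antepartum stillbirth hazards per fetus."""
    band = band_index(np.asarray(age_m) // 12)
    p_f = cp.stillbirth[band]
    p_m = np.clip(p_f * cp.rr_stillbirth_male, 0.0, 1.0)
    return p_f, p_m


def schedule_delivery(dist: np.ndarray, rng: np.random.Generator, n: int) -> np.ndarray:
    """Draw gestational month of delivery (7-10) from the fetal lifetable."""
    dist = np.asarray(dist, dtype=float)
    if dist.shape != (4,) or abs(dist.sum() - 1.0) > 1e-6 or np.any(dist < 0):
        raise ValueError("delivery-month distribution must be 4 non-negative "
                         "probabilities summing to 1")
    return 7 + rng.choice(4, size=n, p=dist / dist.sum())


def draw_fetuses(age_m, cp: CompiledParams, rng: np.random.Generator):
    """(n_fetus, n_female): twinning by age, sex by the primary sex ratio."""
    n = len(np.atleast_1d(age_m))
    twins = rng.random(n) < twin_probability(age_m, cp)
    n_fetus = np.where(twins, 2, 1).astype(np.int8)
    n_female = rng.binomial(n_fetus, cp.p_female).astype(np.int8)
    return n_fetus, n_female


def draw_menopause_age_months(cp: CompiledParams, rng: np.random.Generator, n: int):
    """Per-woman menopause age (months), truncated normal within [40, 60] y.

    Inverse-CDF sampling: u ~ U(Φ(a), Φ(b)), x = μ + σ·Φ⁻¹(u).
    """
    lo, hi = (np.array(MENOPAUSE_TRUNC_YEARS) * 12.0)
    mu, sd = cp.menopause_mean_m, cp.menopause_sd_m
    if sd <= 0:
        raise ValueError("menopause sd must be positive")
    fa, fb = ndtr((lo - mu) / sd), ndtr((hi - mu) / sd)
    u = fa + (fb - fa) * rng.random(n)
    return (mu + sd * ndtri(u)).astype(np.int32)


def draw_hemoglobin(subgroup, cp: CompiledParams, rng: np.random.Generator):
    if cp.hb_sd <= 0:
        raise ValueError("hemoglobin sd must be positive")
    sg = np.asarray(subgroup)
    return rng.normal(cp.hb_mean_sg[sg], cp.hb_sd)


def anemia_flags(hb, pregnant):
    """WHO cut-offs: < 11 g/dL pregnant, < 12 g/dL otherwise."""
    thr = np.where(pregnant, HB_THRESHOLD_PREGNANT, HB_THRESHOLD_NONPREGNANT)
    return np.asarray(hb) < thr


def draw_breastfeeding(n_live, cp: CompiledParams, rng: np.random.Generator):
    """(months_remaining, exclusive) at delivery; zero months if no live birth."""
    n = len(np.atleast_1d(n_live))
    any_bf = (rng.random(n) < cp.bf_p_any) & (np.asarray(n_live) > 0)
    months = np.where(any_bf, np.ceil(rng.exponential(cp.bf_mean_months, n)), 0)
    exclusive = any_bf & (rng.random(n) < cp.bf_p_exclusive)
    return months.astype(np.int16), exclusive
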