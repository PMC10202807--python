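"""Sexual debut, fertility preferences, contraception and induced abortion."""

from __future__ import annotations

import numpy as np

from .params import CompiledParams, annual_to_monthly

# intention codes
SPACING, LIMITING, WANTS_SOON = 0, 1, 2

NO_BIRTH_YET = 9999  # sentinel for months_since_birth before any delivery


def draw_debut_age_months(subgroup, cp: CompiledParams, rng: np.random.Generator):
    """Log-normal age at sexual debut, subgroup-specific median."""
    if cp.debut_log_sd <= 0:
        raise ValueError("debut log-sd must be positive")
    sg = np.asarray(subgroup)
    median = cp.debut_median_m[sg]
    draws = np.exp(np.log(median) + cp.debut_log_sd * rng.standard_normal(sg.shape))
    return np.clip(draws, 10 * 12, 45 * 12).astype(np.int32)


def draw_desired_children(subgroup, cp: CompiledParams, rng: np.random.Generator):
    """Inflated Poisson: a point mass at k* mixed with Poisson(lambda)."""
    sg = np.asarray(subgroup)
    lam = cp.desired_lambda_sg[sg]
    draws = rng.poisson(lam)
    inflate = rng.random(sg.shape) < cp.desired_w
    return np.where(inflate, cp.desired_k, draws).astype(np.int16)


def intention_of(living_children, desired_children, months_since_birth, spacing_window):
    """Fertility intention this cycle.

    Women at or above their desired family size are limiting; below it they
    are spacing while a recent birth is within the spacing window, and want
    a birth soon otherwise.
    """
    living = np.asarray(living_children)
    limiting = living >= np.asarray(desired_children)
    spacing = ~limiting & (np.asarray(months_since_birth) < spacing_window)
    out = np.full(living.shape, WANTS_SOON, dtype=np.int8)
    out[spacing] = SPACING
    out[limiting] = LIMITING
    return out


def monthly_adoption_probability(met_need):
    """Convert the met-need level to a monthly adoption hazard."""
    return annual_to_monthly(np.asarray(met_need))


def draw_method(mix: np.ndarray, rng: np.random.Generator, n: int) -> np.ndarray:
    """Method codes 1..4 (short/long/permanent/traditional) from a mix."""
    mix = np.asarray(mix, dtype=float)
    if abs(mix.sum() - 1.0) > 1e-6:
        raise ValueError("method mix must sum to 1")
    return (1 + rng.choice(len(mix), size=n, p=mix / mix.sum())).astype(np.int8)


def draw_spell_months(cp: CompiledParams, rng: np.random.Generator, n: int) -> np.ndarray:
    """Exponential duration of a contraceptive spell, in whole months ≥ 1."""
    return np.maximum(1, np.ceil(rng.exponential(cp.duration_mean, n))).astype(np.int32)


def abortion_probability(all_female, year_idx: int, cp: CompiledParams):
    """Per-unintended-pregnancy abortion probability.

    All-female pregnancies face the elevated probability that maps the
    primary sex ratio to the secondary (sex-selective abortion); mixed or
    male-bearing pregnancies face the base probability.
    """
    base = cp.p_abortion[year_idx]
    return np.where(np.asarray(all_female), cp.p_abortion_female[year_idx], base)


def unsafe_abortion_death_probability(anemic, cp: CompiledParams):
    p = cp.cfr_unsafe_abortion * np.where(np.asarray(anemic), cp.rr_abortion_cfr_anemia, 1.0)
    return np.clip(p, 0.0, 1.0)
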