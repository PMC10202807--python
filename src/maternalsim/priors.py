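"""Hierarchical parameter priors and damped time trends.

Each model parameter lives on a transformed scale (logit for probabilities,
log for rates, identity for unbounded quantities).  Its country-specific
value is the inverse transform of a sum of contributions along the
geographic ancestor path: a mean plus a normal offset at each of the five
levels (global, income group, continent, region, country).  Dispersions
shrink toward zero at finer levels, giving standard hierarchical pooling.

Secular trends are linear on the transformed scale in an *effective* time

    t_eff(t) = t                      if alpha == 1
             = (1 - alpha**t) / (1 - alpha)   if 0 < alpha < 1

the partial geometric sum, which equals ``t`` in the undamped limit, is
weakly monotone, and saturates at ``1/(1-alpha)`` as t grows — so damped
trends cannot extrapolate to unreasonable levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logit

from .hierarchy import LEVELS, Hierarchy

SCALES = ("logit", "log", "identity")


class PriorError(ValueError):
    pass


def transform(x, scale: str):
    if scale == "logit":
        return logit(x)
    if scale == "log":
        return np.log(x)
    if scale == "identity":
        return np.asarray(x, dtype=float)
    raise PriorError(f"unknown scale {scale!r}")


def inverse_transform(z, scale: str):
    if scale == "logit":
        return expit(z)
    if scale == "log":
        return np.exp(z)
    if scale == "identity":
        return np.asarray(z, dtype=float)
    raise PriorError(f"unknown scale {scale!r}")


@dataclass(frozen=True)
class ParameterPrior:
    """Five-level hierarchical prior for one scalar parameter."""

    name: str
    scale: str
    level_means: tuple[float, ...]  # transformed scale, one per hierarchy level
    level_sds: tuple[float, ...]    # non-negative dispersions, one per level
    bounds: tuple[float, float] | None = None  # natural scale

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise PriorError(f"{self.name}: unknown scale {self.scale!r}")
        if len(self.level_means) != len(LEVELS) or len(self.level_sds) != len(LEVELS):
            raise PriorError(f"{self.name}: need one mean and sd per hierarchy level")
        if any(s < 0 for s in self.level_sds):
            raise PriorError(f"{self.name}: level_sds must be non-negative")

    def sample_offsets(self, rng: np.random.Generator) -> tuple[float, ...]:
        """One normal offset per level; independent across levels."""
        return tuple(rng.normal(0.0, s) if s > 0 else 0.0 for s in self.level_sds)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "scale": self.scale,
            "level_means": list(self.level_means),
            "level_sds": list(self.level_sds),
            "bounds": list(self.bounds) if self.bounds is not None else None,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ParameterPrior":
        b = d.get("bounds")
        return cls(
            d["name"], d["scale"], tuple(d["level_means"]), tuple(d["level_sds"]),
            tuple(b) if b is not None else None,
        )


def resolve_parameter(
    prior: ParameterPrior,
    country: str,
    offsets: dict[str, float] | tuple[float, ...],
    hierarchy: Hierarchy | None = None,
) -> float:
    """Natural-scale value for ``country``: inverse-transform of the summed
    level means and offsets along the ancestor path, clipped to bounds.

    ``offsets`` may be keyed by level name or given positionally
    (global → country).  Addition is commutative, so the result does not
    depend on level order.
    """
    if hierarchy is not None:
        hierarchy.ancestor_path(country)  # validates membership
    if isinstance(offsets, dict):
        missing = [lv for lv in LEVELS if lv not in offsets]
        if missing:
            raise PriorError(f"{prior.name}: missing offsets for levels {missing}")
        off = [offsets[lv] for lv in LEVELS]
    else:
        if len(offsets) != len(LEVELS):
            raise PriorError(f"{prior.name}: need {len(LEVELS)} offsets")
        off = list(offsets)
    z = float(np.sum(prior.level_means) + np.sum(off))
    value = float(inverse_transform(z, prior.scale))
    if prior.bounds is not None:
        value = float(np.clip(value, *prior.bounds))
    return value


@dataclass(frozen=True)
class TrendSpec:
    """Damped linear trend on a transformed scale.

    baseline: intercept at the reference year (transformed scale)
    slope: per-year coefficient (transformed scale)
    damping: alpha in (0, 1]; 1 means undamped linear trend
    scale: transform under which the trend is linear
    """

    baseline: float
    slope: float = 0.0
    damping: float = 1.0
    scale: str = "logit"

    def __post_init__(self) -> None:
        if not (0.0 < self.damping <= 1.0):
            raise PriorError(f"damping must be in (0, 1], got {self.damping}")
        if self.scale not in SCALES:
            raise PriorError(f"unknown scale {self.scale!r}")


def effective_time(t, alpha: float):
    """Partial geometric sum (1 - alpha^t)/(1 - alpha); equals t at alpha=1."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise PriorError("t must be non-negative")
    if alpha == 1.0:
        return t
    return (1.0 - alpha**t) / (1.0 - alpha)


def trend_value(trend: TrendSpec, t):
    """Natural-scale value of the trend at ``t`` years past the reference."""
    z = trend.baseline + trend.slope * effective_time(t, trend.damping)
    return inverse_transform(z, trend.scale)


@dataclass
class PriorLibrary:
    """Named collection of priors, JSON-round-trippable."""

    priors: dict[str, ParameterPrior] = field(default_factory=dict)

    def add(self, prior: ParameterPrior) -> None:
        self.priors[prior.name] = prior

    def __getitem__(self, name: str) -> ParameterPrior:
        return self.priors[name]

    def __contains__(self, name: str) -> bool:
        return name in self.priors

    def names(self) -> list[str]:
        return sorted(self.priors)

    def to_records(self) -> list[dict]:
        return [self.priors[n].to_dict() for n in self.names()]

    @classmethod
    def from_records(cls, records: list[dict]) -> "PriorLibrary":
        lib = cls()
        for rec in records:
            lib.add(ParameterPrior.from_dict(rec))
        return lib
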