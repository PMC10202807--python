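"""Simulated-annealing calibration and posterior predictive checks.

The calibration treats the empirical targets as fixed and the simulator
parameters as random: a goodness-of-fit (GoF) score — the weighted sum of
squared scaled distances between model predictions and observations — is
minimized by simulated annealing with Metropolis acceptance
exp(−ΔGoF/T) under geometric cooling.  Every evaluated parameter set is
archived with its score; the best-k sets are resampled to propagate
second-order (parameter) uncertainty on top of first-order (stochastic)
simulation noise, and posterior predictive checks summarize how often the
resulting 95% intervals cover held-out observations.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd


def train_test_split(targets: pd.DataFrame, cut_year: int) -> pd.DataFrame:
    """Tag targets as train (year ≤ cut) or test (year > cut). Idempotent."""
    out = targets.copy()
    out["split"] = np.where(out["year"] <= cut_year, "train", "test")
    return out


def goodness_of_fit(predictions, observations, weights=None, scales=None) -> float:
    """Σ w_i·((pred_i − obs_i)/s_i)².

    The default per-target scale s_i = max(obs_i, 10) normalizes
    heterogeneous magnitudes; pass ``scales=1`` for the unnormalized sum of
    squared distances.
    """
    pred = np.asarray(predictions, dtype=float)
    obs = np.asarray(observations, dtype=float)
    if pred.shape != obs.shape:
        raise ValueError("predictions and observations are misaligned")
    w = np.ones_like(obs) if weights is None else np.broadcast_to(
        np.asarray(weights, dtype=float), obs.shape)
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    s = np.maximum(np.abs(obs), 10.0) if scales is None else np.broadcast_to(
        np.asarray(scales, dtype=float), obs.shape)
    return float((w * ((pred - obs) / s) ** 2).sum())


@dataclass
class AnnealConfig:
    steps: int = 2000
    t0: float | None = None         # None: auto-set for ~0.8 initial acceptance
    cooling: float | None = None    # None: reach t0/1000 by the final step
    t_min: float = 0.0              # temperature floor; > 0 keeps late-stage
                                    # exploration alive on noisy surfaces
    proposal_scale: float = 0.25    # × per-coordinate sd
    fresh_prior_prob: float = 0.10  # fraction of fresh draws from the prior
    subset_mean: float = 2.0        # mean no. of coordinates perturbed
    seed: int = 0

    def __post_init__(self):
        if self.steps < 1:
            raise ValueError("steps must be positive")
        if self.t0 is not None and self.t0 < 0:
            raise ValueError("t0 must be non-negative")
        if self.cooling is not None and not (0 < self.cooling < 1):
            raise ValueError("cooling factor must be in (0, 1)")


@dataclass
class PosteriorArchive:
    """Every evaluated (parameter vector, GoF score), kept sorted ascending."""

    thetas: list = field(default_factory=list)
    scores: list = field(default_factory=list)

    def append(self, theta: np.ndarray, score: float) -> None:
        self.thetas.append(np.asarray(theta, dtype=float).copy())
        self.scores.append(float(score))

    def __len__(self) -> int:
        return len(self.scores)

    def best(self, k: int) -> tuple[np.ndarray, np.ndarray]:
        """k best-scoring sets; ties at the cut broken by parameter hash."""
        if len(self) < k:
            raise ValueError(f"archive holds {len(self)} < k={k} sets")
        keys = [(s, _theta_hash(t)) for s, t in zip(self.scores, self.thetas)]
        order = sorted(range(len(keys)), key=lambda i: keys[i])[:k]
        return (np.array([self.thetas[i] for i in order]),
                np.array([self.scores[i] for i in order]))

    @property
    def best_score_trace(self) -> np.ndarray:
        return np.minimum.accumulate(np.array(self.scores))


def _theta_hash(theta: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(theta, dtype=float).tobytes()).hexdigest()


def anneal(
    gof: Callable[[np.ndarray], float],
    theta0: np.ndarray,
    step_sds: np.ndarray,
    config: AnnealConfig,
    prior_draw: Callable[[np.random.Generator], np.ndarray] | None = None,
) -> PosteriorArchive:
    """Minimize ``gof`` over a transformed-scale parameter vector.

    Proposals perturb a random subset of coordinates with normal steps of
    sd ``proposal_scale × step_sds``; a fraction of proposals are fresh
    draws from the prior (if ``prior_draw`` is given) to escape local
    modes.  A failing evaluation (non-finite score or exception) is
    recorded as rejected.  Deterministic given the config seed.
    """
    rng = np.random.default_rng(config.seed)
    theta = np.asarray(theta0, dtype=float).copy()
    sds = np.broadcast_to(np.asarray(step_sds, dtype=float), theta.shape)
    archive = PosteriorArchive()
    current = gof(theta)
    archive.append(theta, current)

    t0 = config.t0
    if t0 is None:
        # probe local score variation to target ~0.8 initial acceptance
        deltas = []
        for _ in range(10):
            cand = _propose(theta, sds, config, rng, prior_draw)
            try:
                s = gof(cand)
            except Exception:
                continue
            if np.isfinite(s):
                archive.append(cand, s)
                deltas.append(abs(s - current))
                if s < current:
                    theta, current = cand, s
        med = float(np.median(deltas)) if deltas else 1.0
        t0 = max(med, 1e-12) / np.log(1 / 0.8)
    cooling = config.cooling
    if cooling is None:
        cooling = (1e-3) ** (1.0 / max(config.steps - 1, 1))

    temp = t0
    for _step in range(config.steps):
        cand = _propose(theta, sds, config, rng, prior_draw)
        try:
            score = gof(cand)
        except Exception:
            temp = max(temp * cooling, config.t_min)
            continue
        if not np.isfinite(score):
            temp = max(temp * cooling, config.t_min)
            continue
        archive.append(cand, score)
        delta = score - current
        if delta <= 0 or (temp > 0 and rng.random() < np.exp(-delta / temp)):
            theta, current = cand, score
        temp = max(temp * cooling, config.t_min)
    return archive


def _propose(theta, sds, config, rng, prior_draw):
    if prior_draw is not None and rng.random() < config.fresh_prior_prob:
        return np.asarray(prior_draw(rng), dtype=float)
    cand = theta.copy()
    k = max(1, min(len(theta), rng.poisson(config.subset_mean)))
    coords = rng.choice(len(theta), size=k, replace=False)
    cand[coords] += rng.normal(0.0, config.proposal_scale * sds[coords])
    return cand


def posterior_sample(archive: PosteriorArchive, k: int, n: int,
                     rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Uniform resample (with replacement) of the k best sets for n
    iterations; each iteration also gets a fresh first-order seed."""
    best_thetas, _scores = archive.best(k)
    picks = rng.integers(0, k, size=n)
    seeds = rng.integers(0, 2**31 - 1, size=n)
    return best_thetas[picks], seeds


@dataclass
class PpcReport:
    coverage_probability: float  # percent
    mean_absolute_error: float
    mean_error: float
    n_targets: int


def ppc(matched: pd.DataFrame, by: list[str] | None = None):
    """Posterior predictive check on matched targets.

    ``matched`` needs columns obs, pred_mean, ui_lo, ui_hi (one row per
    target).  Coverage = % of observations inside [ui_lo, ui_hi]; MAE and
    ME compare pred_mean with obs.  With ``by``, returns a DataFrame of
    per-group reports.
    """
    req = {"obs", "pred_mean", "ui_lo", "ui_hi"}
    if not req.issubset(matched.columns):
        raise ValueError(f"matched frame must have columns {sorted(req)}")
    if matched[list(req)].isna().any().any():
        raise ValueError("unmatched target: NaN in matched frame")

    def _one(g: pd.DataFrame) -> PpcReport:
        inside = (g["ui_lo"] <= g["obs"]) & (g["obs"] <= g["ui_hi"])
        err = g["pred_mean"] - g["obs"]
        return PpcReport(100.0 * inside.mean(), float(err.abs().mean()),
                         float(err.mean()), len(g))

    if by is None:
        return _one(matched)
    rows = []
    for key, grp in matched.groupby(by):
        rep = _one(grp)
        key = key if isinstance(key, tuple) else (key,)
        rows.append((*key, rep.coverage_probability, rep.mean_absolute_error,
                     rep.mean_error, rep.n_targets))
    return pd.DataFrame(rows, columns=[*by, "coverage_probability",
                                       "mean_absolute_error", "mean_error", "n_targets"])
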