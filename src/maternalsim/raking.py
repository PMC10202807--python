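"""Iterative proportional fitting (raking) of poststratification weights.

Used to re-weight simulated subgroup × age composition toward external
marginal targets, absorbing population change the simulator does not model
explicitly (migration, differential background mortality).
"""

from __future__ import annotations

import numpy as np


class RakingInfeasibleError(ValueError):
    """A positive marginal target has no positive simulated cell to carry it."""


class RakingConvergenceError(RuntimeError):
    def __init__(self, residual: float, max_iter: int):
        self.residual = residual
        super().__init__(f"IPF did not converge in {max_iter} iterations (residual {residual:.3g})")


def raking_weights(
    sim_counts: np.ndarray,
    row_targets: np.ndarray,
    col_targets: np.ndarray,
    tol: float = 1e-9,
    max_iter: int = 1000,
) -> np.ndarray:
    """Cell weights w such that (w * sim_counts) reproduces both margins.

    Classic IPF: alternate proportional scaling of rows and columns until
    both margins match within ``tol`` (absolute).  Margins must be
    consistent (equal totals) and feasible (no positive target on an
    all-zero slice).
    """
    counts = np.asarray(sim_counts, dtype=float)
    rt = np.asarray(row_targets, dtype=float)
    ct = np.asarray(col_targets, dtype=float)
    if counts.ndim != 2 or counts.shape != (rt.size, ct.size):
        raise ValueError("sim_counts must be 2-D matching the target margins")
    if np.any(counts < 0) or np.any(rt < 0) or np.any(ct < 0):
        raise ValueError("counts and targets must be non-negative")
    if abs(rt.sum() - ct.sum()) > 0.5:
        raise ValueError(f"margin totals disagree: {rt.sum()} vs {ct.sum()}")
    if np.any((rt > 0) & (counts.sum(axis=1) == 0)):
        raise RakingInfeasibleError("positive row target on an all-zero simulated row")
    if np.any((ct > 0) & (counts.sum(axis=0) == 0)):
        raise RakingInfeasibleError("positive column target on an all-zero simulated column")

    fitted = counts.copy()
    residual = np.inf
    for _ in range(max_iter):
        rsum = fitted.sum(axis=1)
        rfac = np.divide(rt, rsum, out=np.zeros_like(rt), where=rsum > 0)
        fitted *= rfac[:, None]
        csum = fitted.sum(axis=0)
        cfac = np.divide(ct, csum, out=np.zeros_like(ct), where=csum > 0)
        fitted *= cfac[None, :]
        residual = max(
            np.abs(fitted.sum(axis=1) - rt).max(),
            np.abs(fitted.sum(axis=0) - ct).max(),
        )
        if residual <= tol:
            break
    else:
        raise RakingConvergenceError(residual, max_iter)

    weights = np.ones_like(counts)
    positive = counts > 0
    weights[positive] = fitted[positive] / counts[positive]
    return weights
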