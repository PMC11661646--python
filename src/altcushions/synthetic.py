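"""Synthetic generators with known ground truth.

These produce data in the exact formats consumed by
:mod:`altcushions.phase_analysis`, with generator parameters that the
estimators are supposed to recover: overdamped-Langevin displacement
pairs for the drift/diffusion estimators, exponential first-exit
lineages for the survival machinery, and mixture densities for the
pseudopotential.  They emulate the *statistical structure* of sampler
output (weighted branch-local displacements, weighted exit events), not
the underlying lattice dynamics.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "langevin_pairs",
    "langevin_trajectory_samples",
    "exponential_exit_events",
    "noisy_exponential_survival",
]

LAM_COLS = ("lambda_AC", "lambda_BD")


def langevin_pairs(
    drift: Callable[[np.ndarray], np.ndarray],
    D: float,
    dt: float,
    n_pairs: int,
    rng: np.random.Generator,
    origin_low: float = 0.0,
    origin_high: float = 1.0,
    coord_cols: Sequence[str] = LAM_COLS,
) -> pd.DataFrame:
    """One-step displacement pairs of the 2D overdamped Langevin equation

        dx = v(x) dt + sqrt(2 D dt) eta,   eta ~ N(0, I).

    Starting points are uniform on the given square; ``drift`` maps an
    (n, 2) array of positions to an (n, 2) array of velocities
    [PSU/s].  Returns the displacement-pair frame (weight 1 per pair).
    """
    x0 = rng.uniform(origin_low, origin_high, size=(n_pairs, 2))
    v = np.asarray(drift(x0), dtype=float)
    dx = v * dt + np.sqrt(2.0 * D * dt) * rng.standard_normal((n_pairs, 2))
    out = pd.DataFrame({
        "time": np.zeros(n_pairs),
        coord_cols[0]: x0[:, 0],
        coord_cols[1]: x0[:, 1],
        f"d_{coord_cols[0]}": dx[:, 0],
        f"d_{coord_cols[1]}": dx[:, 1],
        "weight": np.ones(n_pairs),
    })
    return out


def langevin_trajectory_samples(
    drift: Callable[[np.ndarray], np.ndarray],
    D: float,
    dt: float,
    n_steps: int,
    n_traj: int,
    rng: np.random.Generator,
    x0: tuple[float, float] = (0.3, 0.3),
    coord_cols: Sequence[str] = LAM_COLS,
) -> pd.DataFrame:
    """Full Euler-Maruyama trajectories in the weighted-sample format
    (columns tree_id, branch_id, time, coordinates, weight)."""
    rows = []
    for k in range(n_traj):
        x = np.array(x0, dtype=float)
        for i in range(n_steps + 1):
            rows.append((k, 0, i * dt, x[0], x[1], 1.0 / n_traj))
            v = np.asarray(drift(x[np.newaxis, :]))[0]
            x = x + v * dt + np.sqrt(2.0 * D * dt) * rng.standard_normal(2)
    return pd.DataFrame(rows, columns=["tree_id", "branch_id", "time",
                                       *coord_cols, "weight"])


def exponential_exit_events(
    k: float,
    t_lag: float,
    n_lineages: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """First-exit events of lineages with exponential exit times:
    t_exit = t_lag + Exp(k); weight 1/n each (total weight 1)."""
    te = t_lag + rng.exponential(1.0 / k, size=n_lineages)
    return pd.DataFrame({
        "tree_id": np.arange(n_lineages),
        "branch_id": np.zeros(n_lineages, dtype=int),
        "time": te,
        "weight": np.full(n_lineages, 1.0 / n_lineages),
    })


def noisy_exponential_survival(
    k: float,
    t_lag: float,
    t_grid: np.ndarray,
    noise: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """S(t) = exp(-k (t - t_lag)_+) with multiplicative Gaussian noise,
    clipped to [0, 1] (the t <= t_lag plateau is kept exact)."""
    t_grid = np.asarray(t_grid, dtype=float)
    S = np.exp(-k * np.clip(t_grid - t_lag, 0.0, None))
    tail = t_grid > t_lag
    S[tail] *= 1.0 + noise * rng.standard_normal(tail.sum())
    return np.clip(S, 0.0, 1.0)
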