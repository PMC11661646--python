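"""Statistics of weighted phase-space samples.

Turns the reweighted (lambda_AC, lambda_BD) sample streams produced by
the sampler into densities, survival curves and destruction rates,
inter-region probability fluxes, drift-velocity and diffusion fields of
the overdamped phase-space Langevin picture

    d/dt lambda_vec = <v>(lambda_vec) + sqrt(2 D_lambda) dW,

and median-filtered pseudopotential landscapes -log p~.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, optimize

from .observables import DEFAULT_BOUNDS, Region, RegionBounds, classify_region

__all__ = [
    "EmptyWindowError",
    "SurvivalCurve",
    "DestructionFit",
    "FieldGrid",
    "weighted_histogram",
    "pattern_exit_events",
    "survival_probability",
    "fit_destruction_rate",
    "region_occupation",
    "average_flux",
    "velocity_field",
    "phase_diffusion",
    "pseudopotential",
]

LAM_COLS = ("lambda_AC", "lambda_BD")


class EmptyWindowError(ValueError):
    """No samples fall into the requested time window / region."""


# ---------------------------------------------------------------------------
# Densities
# ---------------------------------------------------------------------------


def weighted_histogram(
    samples: pd.DataFrame,
    t_center: float,
    half_window: float = 300.0,
    bins: int = 50,
    coord_cols: Sequence[str] = LAM_COLS,
    range_: tuple = ((0.0, 1.0), (0.0, 1.0)),
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Normalized 2D density of weighted samples within ``t_center +/- half_window``.

    Returns (H, x_edges, y_edges) with H summing to 1.
    """
    sel = samples[(samples["time"] >= t_center - half_window)
                  & (samples["time"] <= t_center + half_window)]
    if len(sel) == 0:
        raise EmptyWindowError(f"no samples within {t_center} +/- {half_window} s")
    H, xe, ye = np.histogram2d(sel[coord_cols[0]], sel[coord_cols[1]],
                               bins=bins, range=range_, weights=sel["weight"])
    tot = H.sum()
    if tot <= 0:
        raise EmptyWindowError("samples in window carry zero total weight")
    return H / tot, xe, ye


# ---------------------------------------------------------------------------
# Survival and destruction rate
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class SurvivalCurve:
    """Probability of never having left the stable region up to time t."""

    times: np.ndarray
    S: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.S = np.asarray(self.S, dtype=float)


def pattern_exit_events(trees, bounds: RegionBounds = DEFAULT_BOUNDS) -> pd.DataFrame:
    """First exits of tree lineages from the stable region R_S.

    Thin wrapper over the tree walker: a lineage exits when its recorded
    (lambda_AC, lambda_BD) point first classifies outside R_S; re-entry is
    never counted.
    """
    from .nsffs import first_passage_events

    def exited(coords: tuple) -> bool:
        return classify_region(coords[0], coords[1], bounds) is not Region.R_S

    return first_passage_events(trees, exited)


def survival_probability(
    exit_events: pd.DataFrame,
    t_grid: np.ndarray,
    total_weight: float = 1.0,
) -> SurvivalCurve:
    """Survival curve from per-lineage first-exit events.

    Each event removes its weight from the surviving probability at its
    exit time; the curve is therefore non-increasing by construction.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if len(exit_events) == 0:
        return SurvivalCurve(t_grid, np.full_like(t_grid, 1.0))
    order = np.argsort(exit_events["time"].to_numpy())
    te = exit_events["time"].to_numpy()[order]
    we = exit_events["weight"].to_numpy()[order]
    lost = np.concatenate([[0.0], np.cumsum(we)])
    idx = np.searchsorted(te, t_grid, side="right")
    S = (total_weight - lost[idx]) / total_weight
    return SurvivalCurve(t_grid, np.clip(S, 0.0, 1.0))


@dataclasses.dataclass
class DestructionFit:
    """Exponential-decay fit S(t) = exp(-k_D (t - t_lag)) for t > t_lag."""

    k_D: float          #: destruction rate [1/s]
    t_lag: float        #: lag time [s]
    tau_D: float        #: mean stability time 1/k_D [s] (inf when k_D = 0)
    t_start: float      #: accepted fit-window start
    k_D_err: float      #: 1-sigma fit error on k_D
    k_lin: float        #: slope of the linear control fit to 1 - S(t)


class FitError(RuntimeError):
    pass


def _exp_model(t, k, tlag):
    return np.exp(-k * np.clip(t - tlag, 0.0, None))


def fit_destruction_rate(
    curve: SurvivalCurve,
    t_start_grid: Optional[np.ndarray] = None,
    min_points: int = 10,
    s_floor: float = 0.1,
) -> DestructionFit:
    """Lag-scan protocol for the destruction rate.

    For every candidate ``t_start`` the model exp(-k_D (t - t_lag)) is
    fitted on [t_start, t_end]; the accepted fit minimizes
    |t_lag - t_start|.  A linear control fit g(t) = k (t - t_lag) to
    1 - S(t) on the accepted window is reported alongside.

    Candidate windows starting after the curve has already decayed below
    ``s_floor`` are skipped: on the flat S ~ 0 tail the lag-selection
    criterion would otherwise lock onto a meaningless floor fit.
    A survival curve that never decays returns k_D = 0 with tau_D = inf.
    """
    t, S = curve.times, curve.S
    t_end = t[-1]
    if np.all(S >= 1.0 - 1e-12):
        return DestructionFit(0.0, 0.0, math.inf, 0.0, 0.0, 0.0)
    if t_start_grid is None:
        t_start_grid = np.arange(0.0, t_end / 2.0 + 1.0, 900.0)
    best = None
    diagnostics = []
    for t_start in t_start_grid:
        m = t >= t_start
        if m.sum() < min_points:
            continue
        if S[m][0] < s_floor:
            continue
        tt, SS = t[m], S[m]
        decayed = SS < 1.0
        if decayed.sum() < 2:
            continue
        # log-linear seed for the nonlinear fit
        pos = SS > 0
        if pos.sum() >= 2:
            slope, icpt = np.polyfit(tt[pos], np.log(SS[pos]), 1)
            k0 = max(-slope, 1e-12)
            tl0 = min(max(icpt / k0, 0.0), t_end) if k0 > 0 else t_start
        else:
            k0, tl0 = 1e-5, t_start
        try:
            popt, pcov = optimize.curve_fit(
                _exp_model, tt, SS, p0=(k0, tl0),
                bounds=([0.0, -t_end], [np.inf, t_end]), maxfev=10000)
        except (RuntimeError, ValueError) as exc:
            diagnostics.append((t_start, str(exc)))
            continue
        k, tlag = popt
        kerr = float(np.sqrt(pcov[0, 0])) if np.isfinite(pcov[0, 0]) else math.inf
        cand = (abs(tlag - t_start), t_start, k, tlag, kerr)
        if best is None or cand[0] < best[0]:
            best = cand
    if best is None:
        raise FitError(f"no convergent fit on any start window; tried {diagnostics}")
    _, t_start, k, tlag, kerr = best
    m = t >= t_start
    k_lin = _linear_control_fit(t[m], S[m], tlag)
    tau = math.inf if k <= 0 else 1.0 / k
    return DestructionFit(float(k), float(tlag), tau, float(t_start), kerr, k_lin)


def _linear_control_fit(t: np.ndarray, S: np.ndarray, t_lag: float) -> float:
    """Slope of g(t) = k (t - t_lag) fitted to 1 - S(t) (fixed lag)."""
    x = t - t_lag
    denom = float((x * x).sum())
    if denom == 0.0:
        return 0.0
    return float((x * (1.0 - S)).sum() / denom)


# ---------------------------------------------------------------------------
# Region occupation and fluxes
# ---------------------------------------------------------------------------


def region_occupation(
    samples: pd.DataFrame,
    bounds: RegionBounds = DEFAULT_BOUNDS,
) -> pd.DataFrame:
    """Fractional probability per phase-space region at each sample time.

    Weights are renormalized within each time slice, so each row sums
    to 1 (the sampler records all live branches at every measuring time).
    """
    df = samples.copy()
    lam_ac = df["lambda_AC"].to_numpy()
    lam_bd = df["lambda_BD"].to_numpy()
    in_ac = lam_ac <= bounds.lambda_AC_max
    in_bd = lam_bd <= bounds.lambda_BD_max
    region = np.where(in_ac & in_bd, Region.R_S.value,
                      np.where(~in_ac & in_bd, Region.R_AC.value,
                               np.where(in_ac, Region.R_BD.value,
                                        Region.R_DOUBLE.value)))
    df["region"] = region
    occ = df.pivot_table(index="time", columns="region", values="weight",
                         aggfunc="sum", fill_value=0.0)
    for r in Region:
        if r.value not in occ.columns:
            occ[r.value] = 0.0
    occ = occ[[r.value for r in Region]]
    return occ.div(occ.sum(axis=1), axis=0)


def average_flux(times: np.ndarray, P_R: np.ndarray, t_start: float = 0.0) -> float:
    """Average probability flux into a region: slope of the linear fit
    J_avg*t + P_0 to the region occupation P_R(t) on [t_start, t_end]
    (the intercept is discarded)."""
    times = np.asarray(times, dtype=float)
    P_R = np.asarray(P_R, dtype=float)
    m = times >= t_start
    if m.sum() < 2:
        raise ValueError("need at least two occupation points past t_start")
    return float(np.polyfit(times[m], P_R[m], 1)[0])


# ---------------------------------------------------------------------------
# Drift, diffusion, pseudopotential
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class FieldGrid:
    """Binned phase-space fields.

    Bins never visited by an outgoing displacement are masked (``counts``
    = 0), not reported as zero.  Velocities are in phase-space units per
    hour (PSU/h), D_lambda in PSU^2/h.
    """

    x_edges: np.ndarray
    y_edges: np.ndarray
    counts: np.ndarray
    weight: np.ndarray
    vx: Optional[np.ndarray] = None
    vy: Optional[np.ndarray] = None
    D_lambda: Optional[np.ndarray] = None
    density: Optional[np.ndarray] = None
    potential: Optional[np.ndarray] = None

    @property
    def mask(self) -> np.ndarray:
        """True where the bin is empty."""
        return self.counts == 0


def _bin_pairs(pairs, coord_cols, bins, range_):
    x = pairs[coord_cols[0]].to_numpy()
    y = pairs[coord_cols[1]].to_numpy()
    (x0, x1), (y0, y1) = range_
    xe = np.linspace(x0, x1, bins + 1)
    ye = np.linspace(y0, y1, bins + 1)
    ix = np.clip(np.digitize(x, xe) - 1, 0, bins - 1)
    iy = np.clip(np.digitize(y, ye) - 1, 0, bins - 1)
    inside = (x >= x0) & (x <= x1) & (y >= y0) & (y <= y1)
    return xe, ye, ix[inside], iy[inside], inside


def _accumulate(ix, iy, bins, values):
    out = np.zeros((bins, bins))
    np.add.at(out, (ix, iy), values)
    return out


def velocity_field(
    pairs: pd.DataFrame,
    dt: float,
    bins: int = 50,
    coord_cols: Sequence[str] = LAM_COLS,
    range_: tuple = ((0.0, 1.0), (0.0, 1.0)),
) -> FieldGrid:
    """Mean outgoing drift velocity per bin [PSU/h].

    ``pairs`` must hold branch-local displacements over interval ``dt``
    (columns ``d_<coord>`` and ``weight``); each displacement is assigned
    to the bin it *leaves*.
    """
    xe, ye, ix, iy, inside = _bin_pairs(pairs, coord_cols, bins, range_)
    w = pairs["weight"].to_numpy()[inside]
    dx = pairs[f"d_{coord_cols[0]}"].to_numpy()[inside]
    dy = pairs[f"d_{coord_cols[1]}"].to_numpy()[inside]
    wsum = _accumulate(ix, iy, bins, w)
    cnt = _accumulate(ix, iy, bins, np.ones_like(w)).astype(np.int64)
    with np.errstate(invalid="ignore", divide="ignore"):
        vx = _accumulate(ix, iy, bins, w * dx) / wsum / dt * 3600.0
        vy = _accumulate(ix, iy, bins, w * dy) / wsum / dt * 3600.0
    return FieldGrid(xe, ye, cnt, wsum, vx=vx, vy=vy)


def phase_diffusion(
    pairs: pd.DataFrame,
    dt: float,
    bins: int = 50,
    coord_cols: Sequence[str] = LAM_COLS,
    range_: tuple = ((0.0, 1.0), (0.0, 1.0)),
) -> FieldGrid:
    """Local phase-space diffusion coefficient [PSU^2/h]:

        D_lambda = (1/(4 dt)) * (<|dlam|^2> - |<dlam>|^2),

    i.e. the variance of the outgoing 2D displacement per bin over 4 dt.
    """
    xe, ye, ix, iy, inside = _bin_pairs(pairs, coord_cols, bins, range_)
    w = pairs["weight"].to_numpy()[inside]
    dx = pairs[f"d_{coord_cols[0]}"].to_numpy()[inside]
    dy = pairs[f"d_{coord_cols[1]}"].to_numpy()[inside]
    wsum = _accumulate(ix, iy, bins, w)
    cnt = _accumulate(ix, iy, bins, np.ones_like(w)).astype(np.int64)
    with np.errstate(invalid="ignore", divide="ignore"):
        mx = _accumulate(ix, iy, bins, w * dx) / wsum
        my = _accumulate(ix, iy, bins, w * dy) / wsum
        m2 = _accumulate(ix, iy, bins, w * (dx * dx + dy * dy)) / wsum
        D = (m2 - (mx * mx + my * my)) / (4.0 * dt) * 3600.0
    return FieldGrid(xe, ye, cnt, wsum, D_lambda=D)


def pseudopotential(
    pairs: pd.DataFrame,
    bins: int = 50,
    n_filt: int = 4,
    coord_cols: Sequence[str] = LAM_COLS,
    range_: tuple = ((0.0, 1.0), (0.0, 1.0)),
) -> FieldGrid:
    """Median-filtered pseudopotential -log p~ of the outgoing-sample density.

    The raw per-bin weighted density is smoothed by a 2D median filter over
    an ``n_filt`` x ``n_filt`` window with edge replication; empty bins are
    masked (NaN in ``potential``), not treated as zero.
    """
    xe, ye, ix, iy, inside = _bin_pairs(pairs, coord_cols, bins, range_)
    w = pairs["weight"].to_numpy()[inside]
    wsum = _accumulate(ix, iy, bins, w)
    cnt = _accumulate(ix, iy, bins, np.ones_like(w)).astype(np.int64)
    tot = wsum.sum()
    if tot <= 0:
        raise EmptyWindowError("no weighted samples to build a density from")
    dens = wsum / tot
    smooth = ndimage.median_filter(dens, size=n_filt, mode="nearest")
    pot = np.full_like(smooth, np.nan)
    occupied = smooth > 0
    pot[occupied] = -np.log(smooth[occupied])
    pot[cnt == 0] = np.nan
    return FieldGrid(xe, ye, cnt, wsum, density=smooth, potential=pot)
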