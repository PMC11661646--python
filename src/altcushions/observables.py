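"""Order parameters and phase-space regions of the stripe pattern.

The pattern's integrity is tracked by two *asymmetry factors*

    lambda_AC = max([A]_tot, [C]_tot) / N,
    lambda_BD = max([B]_tot, [D]_tot) / N,

where [P]_tot counts dimers twice and N is the total protein number
across all four species.  A well-ordered five-stripe pattern sits near
(0.25, 0.25); loss of one domain of a strongly repressing pair drives
the corresponding factor towards ~0.5.  The scalar progress coordinate
is their sum, lambda = lambda_AC + lambda_BD (about 0.5 for intact
patterns, above 0.75 after breakdown).

The alternative *shifted difference* coordinates retain the sign of the
imbalance:  delta_AC = (1/2)([A]-[C])/N + 1/2  (and likewise BD), with
the intact symmetric pattern at (1/2, 1/2).

Phase space is partitioned into four rectangular regions: the stable
basin R_S (lambda_AC <= 0.45 and lambda_BD <= 0.43), the two
one-domain-lost regions R_AC and R_BD (dagger regions), and the
two-domains-lost remainder.
"""

from __future__ import annotations

import dataclasses
import enum
from typing import Optional, Union

import numpy as np

from .model import Gene
from .ssa import LatticeState

__all__ = [
    "Region",
    "RegionBounds",
    "DEFAULT_BOUNDS",
    "PhasePoint",
    "asymmetry_factors",
    "progress_coordinate",
    "shifted_differences",
    "classify_region",
    "center_of_mass",
    "domain_centers",
]


class UndefinedStateError(ValueError):
    """Raised when an observable is requested for a state with no proteins."""


class Region(enum.Enum):
    """Phase-space region labels."""

    R_S = "R_S"          # intact five-stripe basin
    R_AC = "R_AC+"       # A or C domain lost
    R_BD = "R_BD+"       # B or D domain lost
    R_DOUBLE = "R++"     # one of each strong pair lost


@dataclasses.dataclass(frozen=True)
class RegionBounds:
    """Rectangular region thresholds (defaults fixed for all kappa)."""

    lambda_AC_max: float = 0.45
    lambda_BD_max: float = 0.43


DEFAULT_BOUNDS = RegionBounds()


@dataclasses.dataclass(frozen=True)
class PhasePoint:
    """A weighted point in the reduced phase space."""

    time: float
    lambda_AC: float
    lambda_BD: float
    delta_AC: float
    delta_BD: float
    weight: float = 1.0

    @property
    def progress(self) -> float:
        return self.lambda_AC + self.lambda_BD


def _totals(state: Union[LatticeState, np.ndarray]) -> np.ndarray:
    if isinstance(state, LatticeState):
        return state.totals().astype(float)
    tot = np.asarray(state, dtype=float)
    if tot.shape != (4,):
        raise ValueError("expected a LatticeState or a length-4 total-count vector")
    return tot


def asymmetry_factors(state: Union[LatticeState, np.ndarray]) -> tuple[float, float]:
    """(lambda_AC, lambda_BD) of a state or a per-gene total-count vector.

    Degenerate pairs with both members at zero contribute lambda = 0 (the
    pair expresses nothing, so no asymmetry is attributed to it).
    Raises :class:`UndefinedStateError` when no proteins are present at all.
    """
    tot = _totals(state)
    N = tot.sum()
    if N <= 0:
        raise UndefinedStateError("no proteins present; asymmetry undefined")
    lam_ac = max(tot[Gene.A], tot[Gene.C]) / N
    lam_bd = max(tot[Gene.B], tot[Gene.D]) / N
    return float(lam_ac), float(lam_bd)


def progress_coordinate(state: Union[LatticeState, np.ndarray]) -> float:
    """Scalar progress coordinate lambda = lambda_AC + lambda_BD."""
    lam_ac, lam_bd = asymmetry_factors(state)
    return lam_ac + lam_bd


def shifted_differences(state: Union[LatticeState, np.ndarray]) -> tuple[float, float]:
    """(delta_AC, delta_BD): signed, shifted pair differences in [0, 1]."""
    tot = _totals(state)
    N = tot.sum()
    if N <= 0:
        raise UndefinedStateError("no proteins present; differences undefined")
    d_ac = 0.5 * (tot[Gene.A] - tot[Gene.C]) / N + 0.5
    d_bd = 0.5 * (tot[Gene.B] - tot[Gene.D]) / N + 0.5
    return float(d_ac), float(d_bd)


def phase_point(state: LatticeState, weight: float = 1.0) -> PhasePoint:
    """Bundle all reduced coordinates of a lattice state."""
    lam_ac, lam_bd = asymmetry_factors(state)
    d_ac, d_bd = shifted_differences(state)
    return PhasePoint(state.time, lam_ac, lam_bd, d_ac, d_bd, weight)


def classify_region(
    lambda_AC: float,
    lambda_BD: float,
    bounds: RegionBounds = DEFAULT_BOUNDS,
) -> Region:
    """Assign a phase-space point to its region (boundaries belong to the
    <= side, so the partition is exhaustive and exclusive)."""
    in_ac = lambda_AC <= bounds.lambda_AC_max
    in_bd = lambda_BD <= bounds.lambda_BD_max
    if in_ac and in_bd:
        return Region.R_S
    if not in_ac and in_bd:
        return Region.R_AC
    if in_ac and not in_bd:
        return Region.R_BD
    return Region.R_DOUBLE


def center_of_mass(
    state: LatticeState,
    gene: Gene,
    z_window: Optional[tuple[int, int]] = None,
) -> float:
    """Count-weighted mean axial row of ``gene``'s total expression.

    ``z_window = (z_lo, z_hi)`` restricts to rows z_lo <= z < z_hi (used to
    separate the anterior and posterior A domains).  Raises
    :class:`UndefinedStateError` when the gene has no copies in the window.
    """
    per_row = state.totals_per_row()[:, int(gene)].astype(float)
    z = np.arange(state.N_z, dtype=float)
    if z_window is not None:
        lo, hi = z_window
        per_row = per_row[lo:hi]
        z = z[lo:hi]
    mass = per_row.sum()
    if mass <= 0:
        raise UndefinedStateError(f"gene {gene.name} has no copies in the window")
    return float((z * per_row).sum() / mass)


def domain_centers(state: LatticeState) -> dict[str, float]:
    """Centers of mass of the five domains: A split at mid-system into
    anterior/posterior halves, B, C and D over the full axis.

    Domains with zero copies are reported as NaN.
    """
    half = state.N_z // 2
    out: dict[str, float] = {}
    for label, gene, window in [
        ("A_ant", Gene.A, (0, half)),
        ("B", Gene.B, None),
        ("C", Gene.C, None),
        ("D", Gene.D, None),
        ("A_post", Gene.A, (half, state.N_z)),
    ]:
        try:
            out[label] = center_of_mass(state, gene, window)
        except UndefinedStateError:
            out[label] = float("nan")
    return out
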