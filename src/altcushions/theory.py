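"""Deterministic contact-zone stability theory.

The microscopic lattice model coarse-grains onto an effective
reaction-diffusion system for the dimer concentration of each gene X:

    dX2/dt = D d2X2/dx2 - gamma*X2 + H * theta(1 - sum_Y eps_XY * Y2),

with Heaviside production kinetics.  D, gamma and H follow from the
microscopic rates through the stationary monomer/dimer ratio
r = X1~/X2~ (D = D_P/(1+r), gamma = (mu_D + mu_M r)/(1+r),
H = beta_c/(1+r)); the interaction constants are the dissociation
concentrations K_w = kappa*koff_s/kon_R and K_s = koff_s/kon_R.

Two types of contact zone occur in the five-stripe pattern:
type (i) between two strong antagonists with the weak "cushion" gene
expressed in the background at its equilibrium level H/gamma, and
type (ii) between two weak antagonists.  Each zone is characterized by

    R = 1 - 2*gamma*C~ / (eps * H),

and is stationary (a zero-velocity traveling front) iff -1 < R < 1,
with the signed stationary boundary separation

    delta_r = sgn(R) * lambda * (-ln(1 - |R|)),    lambda = sqrt(D/gamma).

delta_r > 0 is a no-expression gap between the domains; delta_r < 0 an
overlap of the active-production regions.  Simultaneous stability of
both zone types requires K_w = H/gamma, i.e. the optimal repression
ratio kappa_theor = (H/gamma)/K_s; the type-(ii) width changes sign at
kappa_0 = kappa_theor/2.

Sign convention: R and delta_r are defined so that gap widths come out
positive; the closed form was derived from the Green's-function
free-boundary integrals and verified against numerical quadrature.  It
yields the reference landmarks kappa_0 ~ 38, kappa_theor ~ 76 and a
saturated type-(i) gap width of +31.3 um for kappa -> inf.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Literal, Optional

import numpy as np
from scipy import optimize

from .model import ModelParams

__all__ = [
    "EffectiveParams",
    "ContactZone",
    "FrontSolution",
    "StabilityReport",
    "stationary_monomer_dimer",
    "map_effective",
    "zone_constants",
    "contact_zone",
    "stability_conditions",
    "kappa_theor",
    "kappa_zero",
    "solve_traveling",
    "pde_front_tracker",
    "simulate_four_gene",
]

ZoneType = Literal["i", "ii"]


@dataclasses.dataclass(frozen=True)
class EffectiveParams:
    """Coarse-grained reaction-diffusion constants."""

    D: float        #: effective dimer diffusivity [um^2/s]
    gamma: float    #: effective degradation rate [1/s]
    H: float        #: effective production rate [um^-3/s]
    K_w: float      #: weak dissociation concentration [um^-3] (inf if uncoupled)
    K_s: float      #: strong dissociation concentration [um^-3]

    @property
    def lambda_char(self) -> float:
        """Characteristic interaction length sqrt(D/gamma) [um]."""
        return math.sqrt(self.D / self.gamma)

    @property
    def H_over_gamma(self) -> float:
        """Equilibrium expression level of an unrepressed gene [um^-3]."""
        return self.H / self.gamma

    @property
    def kappa(self) -> float:
        return self.K_w / self.K_s

    def with_kappa(self, kappa: float) -> "EffectiveParams":
        return dataclasses.replace(self, K_w=kappa * self.K_s)


class InvalidRegimeError(ValueError):
    """Parameters outside the regime where the mapping is defined."""


def stationary_monomer_dimer(p: ModelParams) -> tuple[float, float]:
    """Stationary monomer and dimer concentrations (X1~, X2~) [um^-3] of a
    single unrepressed gene in a well-stirred volume.

    Closed form of the homogeneous steady state of

        0 = -mu_M X1 - kon_D X1^2 + koff_D X2 + beta_c
        0 = -(koff_D + mu_D) X2 + kon_D X1^2

    with beta_c = beta / V_N the production rate density.
    """
    p.validate()
    beta_c = p.beta / p.V_N
    if beta_c == 0.0:
        return 0.0, 0.0
    a = (p.koff_D + p.mu_D) / p.mu_D
    disc = a**2 * p.mu_M**2 + 4.0 * p.kon_D * beta_c * a
    X1 = (-a * p.mu_M + math.sqrt(disc)) / (2.0 * p.kon_D)
    X2 = beta_c / p.mu_D - (p.mu_M / p.mu_D) * X1
    if X2 <= 0.0:
        raise InvalidRegimeError("stationary dimer concentration is non-positive")
    return X1, X2


def stationary_counts_mass_conserving(p: ModelParams) -> tuple[float, float]:
    """Stationary mean (monomers, dimers) per nucleus of the simulated
    reaction system, in copy numbers.

    Unlike :func:`stationary_monomer_dimer` -- which solves the
    effective-mapping equations in which dimerization converts monomer
    concentration 1:1 into dimer concentration -- this mean field keeps
    the physical stoichiometry of the simulator (two monomers consumed
    per dimer formed and released):

        0 = beta - mu_M n1 - 2 kon_D n1^2 / V_N + 2 koff_D n2
        0 = kon_D n1^2 / V_N - (koff_D + mu_D) n2

    It is the appropriate deterministic oracle for the SSA's long-run
    mean copy numbers (up to small-copy-number fluctuation corrections).
    """
    a = p.kon_D / (p.V_N * (p.koff_D + p.mu_D))      # n2 = a * n1^2
    # beta = mu_M n1 + 2 mu_D n2  (protein conservation)
    c2 = 2.0 * p.mu_D * a
    disc = p.mu_M**2 + 4.0 * c2 * p.beta
    n1 = (-p.mu_M + math.sqrt(disc)) / (2.0 * c2)
    return n1, a * n1 * n1


def map_effective(p: ModelParams) -> EffectiveParams:
    """Map microscopic parameters onto the effective dimer-only model."""
    X1, X2 = stationary_monomer_dimer(p)
    r = X1 / X2
    beta_c = p.beta / p.V_N
    D = p.D_P / (1.0 + r)
    gamma = (p.mu_D + p.mu_M * r) / (1.0 + r)
    H = beta_c / (1.0 + r)
    K_s = p.koff_s / p.kon_R
    K_w = math.inf if math.isinf(p.kappa) else p.kappa * K_s
    return EffectiveParams(D=D, gamma=gamma, H=H, K_w=K_w, K_s=K_s)


@dataclasses.dataclass(frozen=True)
class ContactZone:
    """Stationary properties of one contact zone."""

    zone_type: ZoneType
    R: float              #: stability variable; stationary iff -1 < R < 1
    stable: bool
    delta_r: float        #: signed width [um]; +inf/-inf when unstable

    @property
    def is_gap(self) -> Optional[bool]:
        if not self.stable:
            return None
        return self.delta_r > 0


def zone_constants(zone_type: ZoneType, eff: EffectiveParams) -> tuple[float, float]:
    """(C~, eps) of the symmetric two-gene reduction of a contact zone.

    Type (i): strong antagonists with the cushion gene at level H/gamma in
    the background, C~ = 1 - (H/gamma)/K_w, eps = 1/K_s.  Type (ii): weak
    antagonists, C~ = 1, eps = 1/K_w.
    """
    if zone_type == "i":
        bg = 0.0 if math.isinf(eff.K_w) else eff.H_over_gamma / eff.K_w
        return 1.0 - bg, 1.0 / eff.K_s
    if zone_type == "ii":
        if math.isinf(eff.K_w):
            return 1.0, 0.0
        return 1.0, 1.0 / eff.K_w
    raise ValueError(f"unknown zone type {zone_type!r}")


def _R_value(Ct: float, eps: float, eff: EffectiveParams) -> float:
    return 1.0 - 2.0 * eff.gamma * Ct / (eps * eff.H)


def delta_r_from_R(R: float, lambda_char: float) -> float:
    """Signed stationary width from the stability variable."""
    if abs(R) >= 1.0:
        return math.copysign(math.inf, R)
    if R == 0.0:
        return 0.0
    return math.copysign(lambda_char * (-math.log1p(-abs(R))), R)


def contact_zone(zone_type: ZoneType, eff: EffectiveParams) -> ContactZone:
    """Evaluate R and the stationary signed width of a contact zone."""
    Ct, eps = zone_constants(zone_type, eff)
    if eps == 0.0:
        # uncoupled weak pair: no interaction at all, no contact zone forms
        return ContactZone(zone_type, -math.inf, False, -math.inf)
    R = _R_value(Ct, eps, eff)
    stable = -1.0 < R < 1.0
    return ContactZone(zone_type, R, stable, delta_r_from_R(R, eff.lambda_char))


@dataclasses.dataclass(frozen=True)
class StabilityReport:
    """Admissibility of each zone type and the simultaneous-stability point."""

    type_i_stable: bool
    type_ii_stable: bool
    K_w_min_type_i: float      #: type (i) requires K_w >= H/gamma
    K_s_max_type_i: float      #: type (i) requires K_s <= 1/((H/gamma)^-1 - K_w^-1)
    K_w_max_type_ii: float     #: type (ii) requires K_w <= H/gamma
    simultaneous: bool         #: both types stable (only at K_w = H/gamma)


def stability_conditions(eff: EffectiveParams, rel_tol: float = 1e-9) -> StabilityReport:
    """Evaluate the closed-form stability ranges of both zone types."""
    hg = eff.H_over_gamma
    kw_inv = 0.0 if math.isinf(eff.K_w) else 1.0 / eff.K_w
    denom = 1.0 / hg - kw_inv
    ks_max = math.inf if denom <= 0.0 else 1.0 / denom
    type_i = (eff.K_w >= hg * (1.0 - rel_tol)) and (eff.K_s <= ks_max * (1.0 + rel_tol))
    type_ii = eff.K_w <= hg * (1.0 + rel_tol)
    return StabilityReport(
        type_i_stable=type_i,
        type_ii_stable=type_ii,
        K_w_min_type_i=hg,
        K_s_max_type_i=ks_max,
        K_w_max_type_ii=hg,
        simultaneous=type_i and type_ii,
    )


def kappa_theor(eff: EffectiveParams) -> float:
    """Repression ratio ensuring simultaneous stability of both zone types,
    (H/gamma)/K_s (from the marginal condition K_w = H/gamma)."""
    return eff.H_over_gamma / eff.K_s


def kappa_zero(eff: EffectiveParams) -> float:
    """Repression ratio at which the type-(ii) width changes sign,
    (H/gamma)/(2 K_s) = kappa_theor/2."""
    return eff.H_over_gamma / (2.0 * eff.K_s)


# ---------------------------------------------------------------------------
# Traveling-front system for a single contact zone
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class FrontSolution:
    """Common asymptotic front velocity and boundary separation.

    Geometry: gene X occupies the left half (boundary q_X), gene Y the
    right half (boundary q_Y); ``delta_r = q_Y - q_X`` (positive = gap),
    ``v`` > 0 when both boundaries drift to the right (X advancing).
    """

    v: float          #: [um/s]
    delta_r: float    #: [um]


class NoBoundFrontError(RuntimeError):
    """The two boundaries do not travel at a common velocity (no bound
    contact zone exists for these interactions)."""


def _front_residual(vu, RX, RY, D, gamma, s):
    v, g = vu
    w = math.sqrt(4.0 * D * gamma + v * v)
    ag = abs(g)
    f1 = RX - (s - math.exp((v * g - ag * w) / (2.0 * D)) * (s + v / w))
    f2 = RY - (s - math.exp((-v * g - ag * w) / (2.0 * D)) * (s - v / w))
    return [f1, f2]


def solve_traveling(
    eff: EffectiveParams,
    Ct_X: float,
    Ct_Y: float,
    eps_XY: float,
    eps_YX: float,
) -> FrontSolution:
    """Solve the free-boundary system for the asymptotic (v, delta_r).

    The activation conditions at both boundaries, evaluated with the
    constant-velocity ansatz, give two algebraic equations

        R_X = s - exp((+v dr - |dr| w)/(2D)) (s + v/w)
        R_Y = s - exp((-v dr - |dr| w)/(2D)) (s - v/w)

    with w = sqrt(4 D gamma + v^2), s = sgn(dr), R as defined above.
    Both sign branches are attempted with multi-start damped root finding;
    the symmetric case R_X = R_Y returns v = 0 and the closed-form width.
    """
    D, gamma = eff.D, eff.gamma
    RX = _R_value(Ct_X, eps_XY, eff)
    RY = _R_value(Ct_Y, eps_YX, eff)
    lam = eff.lambda_char
    if abs(RX - RY) < 1e-12 and -1.0 < RX < 1.0:
        return FrontSolution(0.0, delta_r_from_R(RX, lam))
    Rm = 0.5 * (RX + RY)
    g_seed = delta_r_from_R(min(max(Rm, -0.999), 0.999), lam)
    v_scale = 2.0 * math.sqrt(D * gamma)
    best = None
    for s in (1.0, -1.0):
        seeds = []
        for g0 in (g_seed, s * lam, s * 0.3 * lam, s * 3.0 * lam):
            if g0 * s <= 0:
                continue
            for v0 in (0.0, 0.2 * v_scale, -0.2 * v_scale, v_scale, -v_scale):
                seeds.append((v0, g0))
        for x0 in seeds:
            sol = optimize.root(_front_residual, x0, args=(RX, RY, D, gamma, s),
                                method="hybr", tol=1e-12)
            if not sol.success:
                continue
            v, g = sol.x
            if g * s < 0 or abs(g) < 1e-12:
                continue
            res = np.abs(_front_residual((v, g), RX, RY, D, gamma, s)).max()
            if res > 1e-8:
                continue
            if best is None or res < best[2]:
                best = (v, g, res)
        if best is not None:
            break
    if best is None:
        raise NoBoundFrontError("no common-velocity bound front in either sign branch")
    return FrontSolution(float(best[0]), float(best[1]))


# ---------------------------------------------------------------------------
# Direct finite-difference integration (independent oracle)
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class FrontTrack:
    """Boundary trajectories from direct PDE integration."""

    times: np.ndarray
    q_X: np.ndarray
    q_Y: np.ndarray

    def late_velocity(self, fraction: float = 0.5) -> float:
        """Common front velocity from a linear fit over the late-time window."""
        i0 = int(len(self.times) * (1.0 - fraction))
        vx = np.polyfit(self.times[i0:], self.q_X[i0:], 1)[0]
        vy = np.polyfit(self.times[i0:], self.q_Y[i0:], 1)[0]
        return float(0.5 * (vx + vy))

    def late_separation(self, fraction: float = 0.25) -> float:
        """Mean boundary separation q_Y - q_X over the late-time window."""
        i0 = int(len(self.times) * (1.0 - fraction))
        return float(np.mean(self.q_Y[i0:] - self.q_X[i0:]))


def _threshold_crossing(x: np.ndarray, f: np.ndarray, level: float, rising: bool) -> float:
    """First linear-interpolated crossing of ``level`` (rising -> scan from the
    left for f increasing through level; else from the right)."""
    above = f > level
    if rising:
        idx = np.nonzero(above[1:] & ~above[:-1])[0]
        if len(idx) == 0:
            return x[-1] if above[0] else x[0]
        i = idx[0]
    else:
        idx = np.nonzero(above[:-1] & ~above[1:])[0]
        if len(idx) == 0:
            return x[0] if above[-1] else x[-1]
        i = idx[-1]
    f0, f1 = f[i], f[i + 1]
    if f1 == f0:
        return float(x[i])
    return float(x[i] + (level - f0) / (f1 - f0) * (x[i + 1] - x[i]))


def pde_front_tracker(
    eff: EffectiveParams,
    Ct_X: float,
    Ct_Y: float,
    eps_XY: float,
    eps_YX: float,
    L: float = 400.0,
    dx: float = 0.8,
    dt: float = 0.25,
    t_end: float = 8000.0,
    record_dt: float = 50.0,
    gap0: float = 0.0,
) -> FrontTrack:
    """Integrate the two-gene effective system with Heaviside kinetics and
    track the free boundaries.

    X initially occupies the left half up to L/2 - gap0/2 at level H/gamma;
    Y the right half from L/2 + gap0/2.  No-flux ends.  The boundary q_X is
    where eps_XY*Y2 rises through Ct_X (edge of X's active-production
    region), q_Y where eps_YX*X2 falls through Ct_Y.

    Refuses to run when dt violates the explicit-scheme stability limit or
    dx fails to resolve the interaction length (dx <= lambda/10 required).
    """
    D, gamma, H = eff.D, eff.gamma, eff.H
    lam = eff.lambda_char
    if dx > lam / 10.0 + 1e-12:
        raise ValueError(f"dx={dx} does not resolve lambda={lam:.3f} (need dx <= lambda/10)")
    if dt > dx * dx / (2.0 * D):
        raise ValueError("CFL violation: need dt <= dx^2/(2D)")
    n = int(round(L / dx)) + 1
    x = np.linspace(0.0, L, n)
    amp = H / gamma
    X = np.where(x <= L / 2.0 - gap0 / 2.0, amp, 0.0)
    Y = np.where(x >= L / 2.0 + gap0 / 2.0, amp, 0.0)
    c = D * dt / dx**2
    n_steps = int(round(t_end / dt))
    rec_every = max(1, int(round(record_dt / dt)))
    times, qxs, qys = [], [], []

    def lap(F):
        out = np.empty_like(F)
        out[1:-1] = F[2:] - 2.0 * F[1:-1] + F[:-2]
        out[0] = 2.0 * (F[1] - F[0])
        out[-1] = 2.0 * (F[-2] - F[-1])
        return out

    for k in range(n_steps + 1):
        if k % rec_every == 0:
            times.append(k * dt)
            qxs.append(_threshold_crossing(x, eps_XY * Y, Ct_X, rising=True))
            qys.append(_threshold_crossing(x, eps_YX * X, Ct_Y, rising=False))
        if k == n_steps:
            break
        prod_X = (eps_XY * Y < Ct_X).astype(float)
        prod_Y = (eps_YX * X < Ct_Y).astype(float)
        X = X + c * lap(X) + dt * (-gamma * X + H * prod_X)
        Y = Y + c * lap(Y) + dt * (-gamma * Y + H * prod_Y)
    return FrontTrack(np.asarray(times), np.asarray(qxs), np.asarray(qys))


@dataclasses.dataclass
class FourGeneResult:
    """Final state of the deterministic four-gene integration."""

    x: np.ndarray
    profiles: np.ndarray          # (4, n) dimer concentrations A, B, C, D
    segment_counts: np.ndarray    # (4,) contiguous super-threshold domains per gene

    def five_domains_present(self) -> bool:
        """A expressed in two separate domains, B, C, D in one each."""
        return (self.segment_counts[0] >= 2
                and (self.segment_counts[1:] >= 1).all())


def simulate_four_gene(
    eff: EffectiveParams,
    L: float = 340.0,
    dx: float = 0.85,
    dt: float = 0.25,
    t_end: float = 20000.0,
    threshold_frac: float = 0.2,
) -> FourGeneResult:
    """Deterministic integration of the full four-gene effective system from
    the rectangular five-stripe initial condition (order A-B-C-D-A).

    Production of gene X is on wherever sum_{Y != X} Y2/K_XY < 1 with
    K = K_s for the strong partner and K_w for the two weak partners.
    A gene's domains are counted as contiguous runs where its dimer level
    exceeds ``threshold_frac * H/gamma``.
    """
    D, gamma, H = eff.D, eff.gamma, eff.H
    lam = eff.lambda_char
    if dx > lam / 10.0 + 1e-12:
        raise ValueError("dx does not resolve lambda (need dx <= lambda/10)")
    if dt > dx * dx / (2.0 * D):
        raise ValueError("CFL violation: need dt <= dx^2/(2D)")
    n = int(round(L / dx)) + 1
    x = np.linspace(0.0, L, n)
    amp = H / gamma
    C5 = np.zeros((4, n))
    edges = np.linspace(0.0, L, 6)
    owners = [0, 1, 2, 3, 0]
    for g, (lo, hi) in zip(owners, zip(edges[:-1], edges[1:])):
        C5[g, (x >= lo) & (x <= hi)] = amp
    inv_K = np.zeros((4, 4))
    for t in range(4):
        for r in range(4):
            if t == r:
                continue
            if (t - r) % 4 == 2:
                inv_K[t, r] = 1.0 / eff.K_s
            elif not math.isinf(eff.K_w):
                inv_K[t, r] = 1.0 / eff.K_w
    c = D * dt / dx**2
    n_steps = int(round(t_end / dt))
    for _ in range(n_steps):
        load = inv_K @ C5                     # repressor load at each cell
        prod = (load < 1.0).astype(float)
        lap = np.empty_like(C5)
        lap[:, 1:-1] = C5[:, 2:] - 2.0 * C5[:, 1:-1] + C5[:, :-2]
        lap[:, 0] = 2.0 * (C5[:, 1] - C5[:, 0])
        lap[:, -1] = 2.0 * (C5[:, -2] - C5[:, -1])
        C5 = C5 + c * lap + dt * (-gamma * C5 + H * prod)
    thr = threshold_frac * amp
    seg = np.zeros(4, dtype=int)
    for g in range(4):
        above = C5[g] > thr
        seg[g] = int(np.count_nonzero(above[1:] & ~above[:-1]) + (1 if above[0] else 0))
    return FourGeneResult(x, C5, seg)
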