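"""Reaction network of the alternating-cushions four-gene system.

Four genes A, B, C, D are arranged in an axial five-stripe pattern
A-B-C-D-A.  Genes whose expression domains are next-nearest neighbors
(the pairs (A,C) and (B,D)) repress each other strongly; nearest-neighbor
pairs ((A,B), (B,C), (C,D), (D,A)) repress each other weakly.  In each
nucleus a gene's proteins are produced from a constitutive promoter,
degrade, homo-dimerize, and -- only as dimers -- bind the promoters of
the other genes.  A promoter is inactive whenever at least one repressor
dimer is bound (OR logic, non-competitive sites: one site per foreign
gene).  The single control parameter of interest is the repression
strength ratio

    kappa = koff_weak / koff_strong  >= 1,

tuned entirely through the weak-repressor unbinding rate.  kappa = inf
means nearest-neighbor repressor sites are absent altogether.

With the "pinning" option enabled, the A promoter carries no repressor
sites in the first and last axial rings of nuclei, so A is expressed
there unconditionally (mimicking residual maternal inputs anchoring the
peripheral A stripes).
"""

from __future__ import annotations

import dataclasses
import enum
import math
from typing import Callable, Optional

import numpy as np

__all__ = [
    "Gene",
    "GENES",
    "NO_SITE",
    "ModelParams",
    "default_params",
    "is_strong_pair",
    "is_weak_pair",
    "repressor_offrate",
    "offrate_matrix",
    "site_exists_matrix",
    "Reaction",
    "build_reactions",
    "load_params",
    "save_params",
]


class Gene(enum.IntEnum):
    """The four patterning genes, in axial stripe order A-B-C-D(-A)."""

    A = 0
    B = 1
    C = 2
    D = 3


GENES = tuple(Gene)

#: Sentinel returned by :func:`repressor_offrate` when the repressor site
#: does not exist (nearest-neighbor site in the uncoupled limit kappa=inf).
NO_SITE = None


def is_strong_pair(x: Gene, y: Gene) -> bool:
    """True for the strongly repressing next-nearest-neighbor pairs (A,C), (B,D)."""
    return (int(x) - int(y)) % 4 == 2


def is_weak_pair(x: Gene, y: Gene) -> bool:
    """True for the weakly repressing nearest-neighbor pairs (A,B),(B,C),(C,D),(D,A)."""
    return (int(x) - int(y)) % 2 == 1


@dataclasses.dataclass(frozen=True)
class ModelParams:
    """All microscopic rates plus lattice geometry.

    Rates are per second; lengths in micrometres; volumes in cubic
    micrometres.  ``kon_R`` is not stored but derived from the
    diffusion-limited expression 4*pi*sigma_R*D_N.
    """

    beta: float        #: production rate per active promoter [1/s]
    mu_M: float        #: monomer degradation rate [1/s]
    mu_D: float        #: (free) dimer degradation rate [1/s]
    kon_D: float       #: macroscopic dimerization rate constant [um^3/s]
    koff_D: float      #: dedimerization rate [1/s]; invariant kon_D / V_N
    koff_s: float      #: strong-repressor unbinding rate [1/s]
    kappa: float       #: repression strength ratio koff_w / koff_s (>=1, inf allowed)
    D_P: float         #: internuclear protein diffusion coefficient [um^2/s]
    l: float           #: lattice spacing [um]
    N_z: int           #: axial lattice size [nuclei]
    N_phi: int         #: circumferential lattice size [nuclei]
    V_N: float         #: nuclear reaction volume [um^3]
    pinned: bool       #: A promoter irrepressible in the boundary rings
    sigma_R: float     #: repressor target radius [um] (only sets kon_R)
    D_N: float         #: intranuclear diffusion coefficient [um^2/s] (only sets kon_R)

    @property
    def kon_R(self) -> float:
        """Diffusion-limited repressor-promoter binding rate 4*pi*sigma_R*D_N [um^3/s]."""
        return 4.0 * math.pi * self.sigma_R * self.D_N

    @property
    def koff_w(self) -> Optional[float]:
        """Weak-repressor unbinding rate kappa*koff_s; None in the uncoupled limit."""
        if math.isinf(self.kappa):
            return NO_SITE
        return self.kappa * self.koff_s

    @property
    def L(self) -> float:
        """Axial system length N_z * l [um]."""
        return self.N_z * self.l

    def validate(self) -> None:
        pos = {
            "beta": self.beta, "mu_M": self.mu_M, "mu_D": self.mu_D,
            "kon_D": self.kon_D, "koff_D": self.koff_D, "koff_s": self.koff_s,
            "l": self.l, "V_N": self.V_N, "sigma_R": self.sigma_R,
            "D_N": self.D_N,
        }
        for name, val in pos.items():
            if not val > 0.0:
                raise ValueError(f"{name} must be strictly positive, got {val}")
        if self.D_P < 0.0:
            raise ValueError("D_P must be non-negative")
        if self.kappa < 1.0:
            raise ValueError("kappa must be >= 1 (or inf)")
        if self.N_z < 2 or self.N_phi < 1:
            raise ValueError("lattice must have N_z >= 2 and N_phi >= 1")
        if not math.isclose(self.koff_D, self.kon_D / self.V_N, rel_tol=1e-9):
            raise ValueError("invariant violated: koff_D must equal kon_D / V_N")

    def replace(self, **kw) -> "ModelParams":
        """Return a copy with fields replaced (koff_D tracks kon_D/V_N if either moves)."""
        p = dataclasses.replace(self, **kw)
        if ("kon_D" in kw or "V_N" in kw) and "koff_D" not in kw:
            p = dataclasses.replace(p, koff_D=p.kon_D / p.V_N)
        return p


# ---------------------------------------------------------------------------
# Default parameter set.
#
# The defaults are a constrained reconstruction anchored on the quantities the
# study fixes explicitly:
#
#   * lattice 40 x 8 nuclei at spacing l = 8.5 um, internuclear D_P = 1 um^2/s;
#   * effective protein lifetime ~ 100 s  ->  mu_M = mu_D = 0.01 /s;
#   * effective-model landmarks  H/gamma = 0.2295 um^-3,  K_s = 0.0030357 um^-3
#     (i.e. kappa_theor = (H/gamma)/K_s = 75.6), characteristic interaction
#     length lambda = sqrt(D/gamma) = 8.62 um;
#   * dimerization rate twice the diffusion-limited binding rate
#     (kon_D = 2*kon_R) with dedimerization koff_D = kon_D / V_N;
#   * mean copy number per expressing nucleus ~ 15 molecules.
#
# Given these anchors every microscopic rate follows algebraically; see
# docs/methods.md for the derivation.
# ---------------------------------------------------------------------------

_GAMMA_EFF = 0.01          # effective degradation rate [1/s] (lifetime 100 s)
_LAMBDA_CHAR = 8.62        # characteristic interaction length [um]
_H_OVER_GAMMA = 0.2295     # effective production/degradation ratio [um^-3]
_KAPPA_THEOR = 75.6        # (H/gamma)/K_s fixing the strong dissociation constant
_COPIES = 15.0             # molecules (monomers + dimer particles) per nucleus
_D_NUC = 4.0               # intranuclear diffusion coefficient [um^2/s]


def default_params(
    kappa: float = 31.6,
    pinned: bool = True,
    N_z: int = 40,
    N_phi: int = 8,
) -> ModelParams:
    """Default parameter set of the study.

    ``kappa`` defaults to the optimum of the pinned system (31.6); geometry
    defaults to the full 40 x 8 cylindrical lattice.
    """
    D_P = 1.0
    l = 8.5
    D_eff = _GAMMA_EFF * _LAMBDA_CHAR**2          # effective dimer diffusivity
    r = D_P / D_eff - 1.0                          # stationary monomer/dimer ratio
    X2 = _H_OVER_GAMMA                             # stationary dimer concentration
    X1 = r * X2
    V_N = _COPIES / (X1 + X2)
    mu = _GAMMA_EFF                                # mu_M = mu_D = gamma
    kon_D = mu * X2 / (X1**2 - X2 / V_N)
    koff_D = kon_D / V_N
    kon_R = kon_D / 2.0
    sigma_R = kon_R / (4.0 * math.pi * _D_NUC)
    K_s = _H_OVER_GAMMA / _KAPPA_THEOR
    koff_s = K_s * kon_R
    beta = _H_OVER_GAMMA * _GAMMA_EFF * (1.0 + r) * V_N
    p = ModelParams(
        beta=beta, mu_M=mu, mu_D=mu, kon_D=kon_D, koff_D=koff_D,
        koff_s=koff_s, kappa=float(kappa), D_P=D_P, l=l,
        N_z=N_z, N_phi=N_phi, V_N=V_N, pinned=pinned,
        sigma_R=sigma_R, D_N=_D_NUC,
    )
    p.validate()
    return p


def repressor_offrate(repressor: Gene, target: Gene, p: ModelParams) -> Optional[float]:
    """Unbinding rate of ``repressor`` dimers from ``target``'s promoter site.

    Strong (next-nearest-neighbor) pairs unbind at ``koff_s``; weak
    (nearest-neighbor) pairs at ``kappa * koff_s``.  Returns :data:`NO_SITE`
    (None) for weak pairs in the uncoupled limit kappa = inf, where the site
    is absent.  Raises ``ValueError`` for repressor == target.
    """
    if repressor == target:
        raise ValueError("a gene has no repressor site for its own product")
    if is_strong_pair(repressor, target):
        return p.koff_s
    return p.koff_w  # kappa * koff_s, or NO_SITE when kappa = inf


def offrate_matrix(p: ModelParams) -> np.ndarray:
    """4x4 array off[target, repressor]; 0.0 where no site exists (incl. diagonal)."""
    off = np.zeros((4, 4))
    for t in GENES:
        for r in GENES:
            if t == r:
                continue
            rate = repressor_offrate(r, t, p)
            off[t, r] = 0.0 if rate is NO_SITE else rate
    return off


def site_exists_matrix(p: ModelParams, boundary: bool = False) -> np.ndarray:
    """4x4 uint8 mask site[target, repressor].

    ``boundary=True`` applies the pinning rule: the A promoter has no sites
    at all in boundary-ring nuclei of a pinned system.
    """
    site = np.zeros((4, 4), dtype=np.uint8)
    for t in GENES:
        for r in GENES:
            if t == r:
                continue
            if is_weak_pair(t, r) and math.isinf(p.kappa):
                continue
            site[t, r] = 1
    if boundary and p.pinned:
        site[Gene.A, :] = 0
    return site


@dataclasses.dataclass(frozen=True)
class Reaction:
    """One reaction channel of a single nucleus.

    ``propensity(mono, dimr, bound)`` maps the nucleus state (two length-4
    integer arrays and the 4x4 bound-site matrix) to the channel propensity.
    """

    kind: str                     # production|mono_decay|dimer_decay|dimerize|dedimerize|bind|unbind
    gene: Gene                    # the gene whose species/promoter is affected
    repressor: Optional[Gene]     # for bind/unbind channels
    rate: float
    propensity: Callable[[np.ndarray, np.ndarray, np.ndarray], float]


def build_reactions(p: ModelParams, nucleus_is_boundary: bool = False) -> list[Reaction]:
    """The full channel list of one well-stirred nucleus (hops excluded).

    The numerical engine implements exactly these channels; this explicit
    list exists for inspection and testing.  Dimerization uses the exact
    stochastic counterpart of the macroscopic rate, kon_D*n1*(n1-1)/V_N;
    repressor binding kon_R*n2(repressor)/V_N per free site.  Bound dimers
    neither degrade nor hop; they return to the free pool only by unbinding.
    """
    p.validate()
    site = site_exists_matrix(p, boundary=nucleus_is_boundary)
    off = offrate_matrix(p)
    rxns: list[Reaction] = []
    for g in GENES:
        g_ = int(g)

        def a_prod(m, d, b, g_=g_):
            return p.beta if not b[g_].any() else 0.0

        rxns.append(Reaction("production", g, None, p.beta, a_prod))
        rxns.append(Reaction("mono_decay", g, None, p.mu_M,
                             lambda m, d, b, g_=g_: p.mu_M * m[g_]))
        rxns.append(Reaction("dimer_decay", g, None, p.mu_D,
                             lambda m, d, b, g_=g_: p.mu_D * d[g_]))
        rxns.append(Reaction("dimerize", g, None, p.kon_D,
                             lambda m, d, b, g_=g_: p.kon_D * m[g_] * (m[g_] - 1) / p.V_N))
        rxns.append(Reaction("dedimerize", g, None, p.koff_D,
                             lambda m, d, b, g_=g_: p.koff_D * d[g_]))
    for tgt in GENES:
        for rep in GENES:
            if not site[tgt, rep]:
                continue

            def a_bind(m, d, b, t_=int(tgt), r_=int(rep)):
                return 0.0 if b[t_, r_] else p.kon_R * d[r_] / p.V_N

            def a_unbind(m, d, b, t_=int(tgt), r_=int(rep), k=off[tgt, rep]):
                return k if b[t_, r_] else 0.0

            rxns.append(Reaction("bind", tgt, rep, p.kon_R, a_bind))
            rxns.append(Reaction("unbind", tgt, rep, off[tgt, rep], a_unbind))
    return rxns


# ---------------------------------------------------------------------------
# Flat key-value parameter files (TOML).
# ---------------------------------------------------------------------------

_FIELDS = [f.name for f in dataclasses.fields(ModelParams)]


def save_params(p: ModelParams, path) -> None:
    """Write a flat TOML parameter file; kappa = inf is written as "inf"."""
    lines = []
    for name in _FIELDS:
        val = getattr(p, name)
        if isinstance(val, bool):
            lines.append(f"{name} = {str(val).lower()}")
        elif isinstance(val, float) and math.isinf(val):
            lines.append(f'{name} = "inf"')
        elif isinstance(val, float):
            lines.append(f"{name} = {val!r}")
        else:
            lines.append(f"{name} = {val}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def load_params(path) -> ModelParams:
    """Read a flat TOML parameter file written by :func:`save_params`."""
    import tomllib

    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    unknown = set(raw) - set(_FIELDS)
    if unknown:
        raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
    missing = set(_FIELDS) - set(raw)
    if missing:
        raise ValueError(f"missing parameter keys: {sorted(missing)}")
    if isinstance(raw.get("kappa"), str):
        if raw["kappa"].lower() not in ("inf", "infinity"):
            raise ValueError(f"kappa must be a number or 'inf', got {raw['kappa']!r}")
        raw["kappa"] = math.inf
    raw["N_z"] = int(raw["N_z"])
    raw["N_phi"] = int(raw["N_phi"])
    raw["pinned"] = bool(raw["pinned"])
    p = ModelParams(**{k: raw[k] for k in _FIELDS})
    p.validate()
    return p
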