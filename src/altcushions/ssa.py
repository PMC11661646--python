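"""Exact spatial-stochastic simulation of the lattice model.

Nuclei are well-stirred Gillespie reactors on a cylindrical N_z x N_phi
lattice (periodic circumferentially, reflecting/no-flux at the axial
ends).  Monomers and free dimers hop between neighboring nuclei with a
total per-particle rate k_diff = 4*D_P/l**2, split as k_diff/4 per
existing neighbor, which embeds diffusion exactly into the SSA
(next-subvolume scheme).
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np

from . import _kernel
from .model import Gene, ModelParams, offrate_matrix, site_exists_matrix

__all__ = [
    "LatticeState",
    "TrajectoryRecord",
    "hop_rate",
    "init_pattern",
    "stripe_rows",
    "step",
    "advance_state",
    "run",
]


def hop_rate(p: ModelParams) -> float:
    """Total per-particle diffusive hop propensity 4*D_P/l**2 [1/s]."""
    if p.l <= 0:
        raise ValueError("lattice spacing must be positive")
    return 4.0 * p.D_P / p.l**2


@dataclasses.dataclass
class LatticeState:
    """Copy numbers and promoter occupancy of every nucleus.

    Nucleus ``(z, phi)`` has flat index ``z * N_phi + phi``.  ``bound[n, t, r]``
    is 1 when a dimer of gene ``r`` occupies its site on gene ``t``'s promoter
    (that dimer is excluded from the free pool ``dimr``).
    """

    time: float
    N_z: int
    N_phi: int
    mono: np.ndarray   # int64 (N_z*N_phi, 4)
    dimr: np.ndarray   # int64 (N_z*N_phi, 4) free dimers
    bound: np.ndarray  # uint8 (N_z*N_phi, 4, 4)

    def copy(self) -> "LatticeState":
        return LatticeState(self.time, self.N_z, self.N_phi,
                            self.mono.copy(), self.dimr.copy(), self.bound.copy())

    # -- observable accessors ------------------------------------------------

    def bound_dimers(self) -> np.ndarray:
        """Per-gene count of promoter-bound dimers, shape (4,)."""
        return self.bound.astype(np.int64).sum(axis=(0, 1))

    def totals(self) -> np.ndarray:
        """Total protein copy number per gene, counting dimers twice.

        Includes promoter-bound dimers (they are still protein copies).
        Shape (4,), order A, B, C, D.
        """
        bound_per_rep = self.bound.astype(np.int64).sum(axis=(0, 1))
        return self.mono.sum(axis=0) + 2 * (self.dimr.sum(axis=0) + bound_per_rep)

    def totals_per_row(self) -> np.ndarray:
        """Circumference-summed total copies per axial row, shape (N_z, 4)."""
        m = self.mono.reshape(self.N_z, self.N_phi, 4).sum(axis=1)
        d = self.dimr.reshape(self.N_z, self.N_phi, 4).sum(axis=1)
        b = self.bound.astype(np.int64).reshape(self.N_z, self.N_phi, 4, 4).sum(axis=(1, 2))
        return m + 2 * (d + b)

    def particle_count(self) -> int:
        """Total number of molecules (monomers + dimer particles, incl. bound)."""
        return int(self.mono.sum() + self.dimr.sum() + self.bound.sum())

    def check_bookkeeping(self) -> None:
        if (self.mono < 0).any() or (self.dimr < 0).any():
            raise AssertionError("negative copy number")
        if not np.isin(self.bound, (0, 1)).all():
            raise AssertionError("promoter occupancy must be 0 or 1")


def stripe_rows(N_z: int) -> list[np.ndarray]:
    """Axial row indices of the five stripes (A, B, C, D, A).

    Widths are N_z // 5; any remainder is distributed one extra row at a
    time starting from the anterior stripe.
    """
    base, rem = divmod(N_z, 5)
    widths = [base + (1 if i < rem else 0) for i in range(5)]
    rows, z0 = [], 0
    for w in widths:
        rows.append(np.arange(z0, z0 + w))
        z0 += w
    return rows


def init_pattern(p: ModelParams, copies_per_nucleus: int = 15) -> LatticeState:
    """Standardized five-stripe rectangular initial condition.

    Five non-overlapping stripes in the order A-B-C-D-A, each occupying an
    equal share of the axial length, with ``copies_per_nucleus`` monomers of
    the stripe-owner gene in every nucleus (no dimers, all sites free).
    """
    n_nuc = p.N_z * p.N_phi
    st = LatticeState(
        time=0.0, N_z=p.N_z, N_phi=p.N_phi,
        mono=np.zeros((n_nuc, 4), dtype=np.int64),
        dimr=np.zeros((n_nuc, 4), dtype=np.int64),
        bound=np.zeros((n_nuc, 4, 4), dtype=np.uint8),
    )
    owners = [Gene.A, Gene.B, Gene.C, Gene.D, Gene.A]
    for owner, rows in zip(owners, stripe_rows(p.N_z)):
        for z in rows:
            st.mono[z * p.N_phi:(z + 1) * p.N_phi, int(owner)] = copies_per_nucleus
    return st


# ---------------------------------------------------------------------------
# Kernel plumbing
# ---------------------------------------------------------------------------


def _neighbor_tables(N_z: int, N_phi: int) -> tuple[np.ndarray, np.ndarray]:
    """Compact neighbor lists: axial neighbors are absent beyond the ends
    (reflecting); circumferential neighbors wrap around."""
    n_nuc = N_z * N_phi
    nbr = np.full((n_nuc, 4), -1, dtype=np.int64)
    nnbr = np.zeros(n_nuc, dtype=np.int64)
    for z in range(N_z):
        for f in range(N_phi):
            n = z * N_phi + f
            cand = []
            if z > 0:
                cand.append((z - 1) * N_phi + f)
            if z < N_z - 1:
                cand.append((z + 1) * N_phi + f)
            if N_phi > 1:
                cand.append(z * N_phi + (f + 1) % N_phi)
                cand.append(z * N_phi + (f - 1) % N_phi)
            for k, m in enumerate(cand):
                nbr[n, k] = m
            nnbr[n] = len(cand)
    return nbr, nnbr


def _site_tensor(p: ModelParams) -> np.ndarray:
    """Per-nucleus site-existence mask (pinning removes A's sites in the
    first and last axial rings)."""
    bulk = site_exists_matrix(p, boundary=False)
    boundary = site_exists_matrix(p, boundary=True)
    site = np.broadcast_to(bulk, (p.N_z * p.N_phi, 4, 4)).copy()
    site[: p.N_phi] = boundary
    site[-p.N_phi:] = boundary
    return np.ascontiguousarray(site)


class _CompiledModel:
    """Packed kernel arguments for a given parameter set."""

    def __init__(self, p: ModelParams):
        p.validate()
        self.p = p
        self.site = _site_tensor(p)
        self.off = offrate_matrix(p)
        self.nbr, self.nnbr = _neighbor_tables(p.N_z, p.N_phi)
        par = np.zeros(7)
        par[_kernel.P_BETA] = p.beta
        par[_kernel.P_MUM] = p.mu_M
        par[_kernel.P_MUD] = p.mu_D
        par[_kernel.P_KOND_V] = p.kon_D / p.V_N
        par[_kernel.P_KOFFD] = p.koff_D
        par[_kernel.P_KONR_V] = p.kon_R / p.V_N
        par[_kernel.P_KDIFF4] = hop_rate(p) / 4.0
        self.par = par
        self.P = np.zeros(p.N_z * p.N_phi)


_model_cache: dict[tuple, _CompiledModel] = {}


def _compiled(p: ModelParams) -> _CompiledModel:
    key = dataclasses.astuple(p)
    cm = _model_cache.get(key)
    if cm is None:
        cm = _CompiledModel(p)
        if len(_model_cache) > 64:
            _model_cache.clear()
        _model_cache[key] = cm
    return cm


def _as_seed(rng) -> int:
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    return int(rng.integers(1, 2**31 - 1))


class AbsorbingStateError(RuntimeError):
    """All reaction and hop channels have zero propensity."""


def step(state: LatticeState, p: ModelParams, rng) -> float:
    """Execute exactly one SSA event in place; return the waiting time.

    Raises :class:`AbsorbingStateError` when no channel is enabled.
    """
    cm = _compiled(p)
    dt, alive = _kernel.one_step(state.mono, state.dimr, state.bound, cm.site,
                                 cm.off, cm.nbr, cm.nnbr, cm.par, cm.P, _as_seed(rng))
    if not alive:
        raise AbsorbingStateError("zero total propensity")
    state.time += dt
    return dt


def advance_state(state: LatticeState, p: ModelParams, t_end: float, rng) -> None:
    """Advance ``state`` in place to ``t_end`` (exact SSA)."""
    if t_end < state.time:
        raise ValueError("t_end lies before the current state time")
    if t_end == state.time:
        return
    cm = _compiled(p)
    t, alive = _kernel.advance(state.mono, state.dimr, state.bound, cm.site,
                               cm.off, cm.nbr, cm.nnbr, cm.par, cm.P,
                               state.time, t_end, _as_seed(rng))
    state.time = t
    if not alive:
        raise AbsorbingStateError("zero total propensity")


@dataclasses.dataclass
class TrajectoryRecord:
    """Observables (and optionally snapshots) sampled on a regular grid."""

    times: np.ndarray                      # [s], strictly increasing
    totals: np.ndarray                     # (n_times, 4) per-gene totals (dimers x2)
    snapshots: Optional[list[LatticeState]] = None

    def __len__(self) -> int:
        return len(self.times)


def run(
    state: LatticeState,
    p: ModelParams,
    t_end: float,
    acquisition_dt: float,
    rng,
    keep_snapshots: bool = False,
) -> TrajectoryRecord:
    """Propagate a copy of ``state`` to ``t_end``, recording every
    ``acquisition_dt`` seconds (the initial state is always recorded).

    Reproducible: the same seed/generator state yields identical records.
    The input state is not modified; the evolved final state is the last
    snapshot when ``keep_snapshots`` is set.
    """
    if t_end < state.time:
        raise ValueError("t_end lies before the current state time")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    work = state.copy()
    times = [work.time]
    totals = [work.totals()]
    snaps = [work.copy()] if keep_snapshots else None
    t_next = work.time + acquisition_dt
    while t_next <= t_end + 1e-9:
        advance_state(work, p, min(t_next, t_end), rng)
        times.append(work.time)
        totals.append(work.totals())
        if keep_snapshots:
            snaps.append(work.copy())
        t_next += acquisition_dt
    return TrajectoryRecord(np.asarray(times), np.asarray(totals), snaps)
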