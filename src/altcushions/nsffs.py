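"""Non-stationary forward flux sampling (NS-FFS).

The sampler wraps any stochastic propagator exposing a scalar progress
coordinate.  Trajectories are propagated in fixed-length chunks; when a
chunk ends above a previously uncrossed interface the event is recorded
in a per-(interface, time-bin) crossing histogram, and the trajectory is
branched (cloned with split statistical weight) in undersampled
(interface, time) regions or pruned by Russian roulette in oversampled
ones.  The aim is a roughly uniform flux of simulated trajectories
along the progress coordinate in every time bin, so that rare
progress -- e.g. stripe-pattern breakdown -- is sampled with useful
statistics while every weighted average stays unbiased.

Branching rule (per crossing of interface i in time bin b):

    n = clip(round(target / observed), 0, n_B_max)

with ``observed`` the accumulated weighted crossing count of (i, b) and
``target`` the running mean over the populated bins of interface i;
n >= 1 splits the branch into n children of weight w/n; n = 0 triggers
Russian roulette with survival probability q = max(target/observed, 1/2)
and surviving weight w/q.  Until a bin has recorded ``min_crossings``
events the decision is the identity (cold start).

The resulting ensemble of weighted trajectory *trees* is flattened into
time-stamped weighted phase-space samples for analysis; per-lineage
first-passage bookkeeping and branch-local displacement pairing are
provided here because they need the tree topology.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Callable, Optional, Protocol, Sequence

import numpy as np
import pandas as pd

from . import _kernel
from .model import ModelParams
from .observables import asymmetry_factors, shifted_differences
from .ssa import LatticeState, advance_state, init_pattern

__all__ = [
    "SamplerConfig",
    "CrossingStats",
    "TreeNode",
    "TrajectoryTree",
    "Propagator",
    "LatticePropagator",
    "BirthDeathPropagator",
    "branch_decision",
    "run_nsffs",
    "reweight",
    "first_passage_events",
    "displacement_pairs",
]


@dataclasses.dataclass(frozen=True)
class SamplerConfig:
    """Sampler controls (defaults: desk-scale pattern-breakdown sampling)."""

    interfaces: tuple[float, ...] = tuple(np.round(np.arange(0.50, 0.8401, 0.02), 4))
    time_bin: float = 900.0        #: [s] width of the crossing-statistics time bins
    t_chunk: float = 60.0          #: [s] propagation chunk between interface checks
    dt_measure: float = 60.0       #: [s] phase-point recording interval
    n_B_max: int = 4               #: maximal branching number
    T_max: float = 6.0 * 3600.0    #: [s] tree time horizon
    T_cum_target: float = 1.0e5    #: [s] total simulated-time budget
    min_crossings: int = 20        #: cold-start threshold per (interface, bin)
    q_min: float = 0.5             #: Russian-roulette survival probability floor

    def validate(self) -> None:
        ifs = np.asarray(self.interfaces)
        if len(ifs) == 0 or (np.diff(ifs) <= 0).any():
            raise ValueError("interfaces must be strictly increasing")
        if not (0 < ifs[0] and ifs[-1] <= 1.0):
            raise ValueError("interfaces must lie in (0, 1]")
        if self.t_chunk <= 0 or self.time_bin <= 0 or self.T_max <= 0:
            raise ValueError("durations must be positive")
        if self.n_B_max < 1:
            raise ValueError("n_B_max must be >= 1")
        if not 0.0 < self.q_min < 1.0:
            raise ValueError("q_min must lie in (0, 1)")

    @property
    def n_bins(self) -> int:
        return int(math.ceil(self.T_max / self.time_bin))


class CrossingStats:
    """Accumulated weighted upward-crossing counts per (interface, time bin)."""

    def __init__(self, n_interfaces: int, n_bins: int):
        self.counts = np.zeros((n_interfaces, n_bins), dtype=np.int64)
        self.wsum = np.zeros((n_interfaces, n_bins))

    def register(self, iface: int, tbin: int, weight: float) -> None:
        self.counts[iface, tbin] += 1
        self.wsum[iface, tbin] += weight

    def target_flux(self) -> float:
        """Running mean of the weighted flux over all populated
        (interface, time-bin) cells.

        Using the global mean as the target equalizes the trajectory flux
        both along the progress coordinate and across time bins:
        crossings of rarely reached interfaces fall below the target and
        trigger branching, oversampled cells trigger pruning.
        """
        pop = self.counts > 0
        if not pop.any():
            return 0.0
        return float(self.wsum[pop].mean())


def branch_decision(
    iface: int,
    tbin: int,
    weight: float,
    stats: CrossingStats,
    cfg: SamplerConfig,
    rng: np.random.Generator,
) -> tuple[int, float]:
    """(n_children, child_weight) for a registered crossing.

    n = 0 encodes pruning (the Russian roulette has already been played:
    a return of (0, 0.0) kills the branch, (1, w/q) continues it).
    """
    # Cold start: until the crossing histogram as a whole carries enough
    # events the empirical target flux is unreliable -> identity decision.
    # (A per-cell warm-up would permanently disable branching in exactly
    # the rare cells the sampler is meant to enrich.)
    if stats.counts.sum() < cfg.min_crossings:
        return 1, weight
    observed = stats.wsum[iface, tbin]
    target = stats.target_flux()
    if observed <= 0.0 or target <= 0.0:
        return 1, weight
    ratio = target / observed
    n = int(np.clip(round(ratio), 0, cfg.n_B_max))
    if n >= 1:
        return n, weight / n
    q = max(ratio, cfg.q_min)
    if rng.random() < q:
        return 1, weight / q
    return 0, 0.0


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class TreeNode:
    """One unbranched trajectory segment carrying a constant weight."""

    node_id: int
    parent_id: Optional[int]
    t_birth: float
    weight: float
    kind: str = "root"            # root | split | prune_survivor
    times: list = dataclasses.field(default_factory=list)
    coords: list = dataclasses.field(default_factory=list)
    children: list = dataclasses.field(default_factory=list)
    crossings: list = dataclasses.field(default_factory=list)  # (t, iface, direction)
    pruned: bool = False

    def record(self, t: float, coords: tuple) -> None:
        if self.times and abs(self.times[-1] - t) < 1e-9:
            return
        self.times.append(t)
        self.coords.append(coords)


@dataclasses.dataclass
class TrajectoryTree:
    """A branched, weighted trajectory ensemble member."""

    tree_id: int
    nodes: dict[int, TreeNode]
    root_id: int
    simulated_time: float = 0.0

    @property
    def root(self) -> TreeNode:
        return self.nodes[self.root_id]

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.nodes.values() if not n.children]

    def total_leaf_weight(self) -> float:
        """Sum of surviving-leaf weights (equals the root weight in the
        absence of pruning; conserved in expectation under pruning)."""
        return sum(n.weight for n in self.leaves() if not n.pruned)

    def walk(self):
        """Yield (node, parent) in depth-first pre-order."""
        stack = [(self.root_id, None)]
        while stack:
            nid, pid = stack.pop()
            node = self.nodes[nid]
            yield node, (self.nodes[pid] if pid is not None else None)
            for cid in reversed(node.children):
                stack.append((cid, nid))


# ---------------------------------------------------------------------------
# Propagators
# ---------------------------------------------------------------------------


class Propagator(Protocol):
    """Minimal interface the sampler needs from a stochastic model."""

    coord_names: tuple[str, ...]

    def initial_state(self, rng: np.random.Generator): ...

    def advance(self, state, t_end: float, rng: np.random.Generator) -> None: ...

    def copy_state(self, state): ...

    def coordinate(self, state) -> float: ...

    def phase_coords(self, state) -> tuple: ...


class LatticePropagator:
    """The stripe-pattern lattice model as an NS-FFS propagator.

    Each tree starts from the standardized five-stripe pattern relaxed for
    ``t_relax`` (default 30 min) with its own random seed; the progress
    coordinate is lambda = lambda_AC + lambda_BD.
    """

    coord_names = ("lambda_AC", "lambda_BD", "delta_AC", "delta_BD")

    def __init__(self, params: ModelParams, copies_per_nucleus: int = 15,
                 t_relax: float = 1800.0):
        params.validate()
        self.params = params
        self.copies = copies_per_nucleus
        self.t_relax = t_relax

    def initial_state(self, rng: np.random.Generator) -> LatticeState:
        st = init_pattern(self.params, self.copies)
        if self.t_relax > 0:
            advance_state(st, self.params, self.t_relax, rng)
        st.time = 0.0
        return st

    def advance(self, state: LatticeState, t_end: float, rng) -> None:
        advance_state(state, self.params, t_end, rng)

    def copy_state(self, state: LatticeState) -> LatticeState:
        return state.copy()

    def coordinate(self, state: LatticeState) -> float:
        lam_ac, lam_bd = asymmetry_factors(state)
        return lam_ac + lam_bd

    def phase_coords(self, state: LatticeState) -> tuple:
        lam_ac, lam_bd = asymmetry_factors(state)
        d_ac, d_bd = shifted_differences(state)
        return (lam_ac, lam_bd, d_ac, d_bd)


@dataclasses.dataclass
class _BDState:
    time: float
    n: int
    n_max: int

    def copy(self) -> "_BDState":
        return _BDState(self.time, self.n, self.n_max)


class BirthDeathPropagator:
    """1D birth-death chain (births at ``birth``, deaths at ``death * n``).

    Progress coordinate: running maximum count / threshold, so a crossing
    of the top interface at 1.0 means the chain has reached ``threshold``
    at least once.  Used to validate sampler unbiasedness against
    brute-force simulation.
    """

    coord_names = ("progress",)

    def __init__(self, birth: float, death: float, n0: int, threshold: int):
        self.birth = birth
        self.death = death
        self.n0 = n0
        self.threshold = threshold

    def initial_state(self, rng) -> _BDState:
        return _BDState(0.0, self.n0, self.n0)

    def advance(self, state: _BDState, t_end: float, rng) -> None:
        seed = int(rng.integers(1, 2**31 - 1))
        n, nmax = _kernel.bd_advance(state.n, state.time, t_end,
                                     self.birth, self.death, seed)
        state.n = int(n)
        state.n_max = max(state.n_max, int(nmax))
        state.time = t_end

    def copy_state(self, state: _BDState) -> _BDState:
        return state.copy()

    def coordinate(self, state: _BDState) -> float:
        return state.n_max / self.threshold

    def phase_coords(self, state: _BDState) -> tuple:
        return (state.n_max / self.threshold,)


# ---------------------------------------------------------------------------
# The sampler
# ---------------------------------------------------------------------------


def _run_tree(
    prop: Propagator,
    cfg: SamplerConfig,
    stats: CrossingStats,
    tree_id: int,
    rng: np.random.Generator,
) -> TrajectoryTree:
    interfaces = np.asarray(cfg.interfaces)
    next_id = 0

    def new_node(parent: Optional[TreeNode], t: float, w: float, kind: str) -> TreeNode:
        nonlocal next_id
        node = TreeNode(next_id, parent.node_id if parent else None, t, w, kind)
        if parent is not None:
            parent.children.append(node.node_id)
        next_id += 1
        return node

    state0 = prop.initial_state(rng)
    root = new_node(None, state0.time, 1.0, "root")
    root.record(state0.time, prop.phase_coords(state0))
    tree = TrajectoryTree(tree_id, {root.node_id: root}, root.node_id)
    # active branch entries: (state, node, lambda at last check)
    active = [(state0, root, prop.coordinate(state0))]
    sim_time = 0.0
    eps = 1e-9
    while active:
        state, node, lam_prev = active.pop()
        while True:
            t_next = min(state.time + cfg.t_chunk, cfg.T_max)
            if t_next <= state.time + eps:
                break  # reached the horizon: leaf
            dt_sim = t_next - state.time
            prop.advance(state, t_next, rng)
            sim_time += dt_sim
            lam = prop.coordinate(state)
            t = state.time
            if _is_measure_time(t, cfg.dt_measure):
                node.record(t, prop.phase_coords(state))
            crossed = np.nonzero((interfaces > lam_prev) & (interfaces <= lam))[0]
            down = np.nonzero((interfaces <= lam_prev) & (interfaces > lam))[0]
            tbin = min(int(t / cfg.time_bin), cfg.n_bins - 1)
            for i in down:
                node.crossings.append((t, int(i), -1))
            if len(crossed) > 0:
                for i in crossed:
                    node.crossings.append((t, int(i), +1))
                    stats.register(int(i), tbin, node.weight)
                top = int(crossed[-1])
                n_children, w_child = branch_decision(top, tbin, node.weight,
                                                      stats, cfg, rng)
                node.record(t, prop.phase_coords(state))
                if n_children == 0:
                    node.pruned = True
                    break
                if n_children == 1 and w_child == node.weight:
                    lam_prev = lam
                    continue
                kind = "split" if n_children > 1 else "prune_survivor"
                for k in range(n_children):
                    child = new_node(node, t, w_child, kind)
                    child.record(t, prop.phase_coords(state))
                    tree.nodes[child.node_id] = child
                    child_state = prop.copy_state(state) if k < n_children - 1 else state
                    active.append((child_state, child, lam))
                break
            lam_prev = lam
    tree.simulated_time = sim_time
    return tree


def _is_measure_time(t: float, dt: float) -> bool:
    k = round(t / dt)
    return abs(t - k * dt) < 1e-6 * max(dt, 1.0)


def run_nsffs(
    prop: Propagator,
    cfg: SamplerConfig,
    seed: int,
) -> tuple[list[TrajectoryTree], CrossingStats]:
    """Run trajectory trees until the simulated-time budget is exhausted.

    A new tree is only started while the accumulated simulated time is
    below ``cfg.T_cum_target``; the last tree is always propagated to its
    end.  Fully reproducible for a given seed.
    """
    cfg.validate()
    stats = CrossingStats(len(cfg.interfaces), cfg.n_bins)
    trees: list[TrajectoryTree] = []
    T_cum = 0.0
    tree_idx = 0
    root_seq = np.random.SeedSequence(seed)
    while T_cum < cfg.T_cum_target:
        rng = np.random.default_rng(np.random.SeedSequence(
            entropy=root_seq.entropy, spawn_key=(tree_idx,)))
        tree = _run_tree(prop, cfg, stats, tree_idx, rng)
        trees.append(tree)
        T_cum += tree.simulated_time
        tree_idx += 1
    return trees, stats


# ---------------------------------------------------------------------------
# Tree analysis helpers
# ---------------------------------------------------------------------------


def reweight(trees: Sequence[TrajectoryTree],
             coord_names: Sequence[str]) -> pd.DataFrame:
    """Flatten trees into a weighted sample stream.

    Weights are node weights divided by the number of trees, so that the
    stream's weighted averages estimate unbiased dynamical expectations
    over the initial-condition ensemble.
    """
    n_trees = max(len(trees), 1)
    rows = []
    for tree in trees:
        for node, _ in tree.walk():
            w = node.weight / n_trees
            for t, c in zip(node.times, node.coords):
                rows.append((tree.tree_id, node.node_id, t, *c, w))
    cols = ["tree_id", "branch_id", "time", *coord_names, "weight"]
    return pd.DataFrame(rows, columns=cols)


def first_passage_events(
    trees: Sequence[TrajectoryTree],
    exited: Callable[[tuple], bool],
) -> pd.DataFrame:
    """Per-lineage first-exit events.

    Walks each tree depth-first; the first recorded point of a lineage for
    which ``exited(coords)`` is true contributes one event carrying the
    weight of that branch at that moment (normalized by the number of
    trees); all its descendants are excluded.  Re-entries are ignored.
    """
    n_trees = max(len(trees), 1)
    rows = []
    for tree in trees:
        skip: set[int] = set()
        for node, parent in tree.walk():
            if parent is not None and parent.node_id in skip:
                skip.add(node.node_id)
                continue
            hit = False
            for t, c in zip(node.times, node.coords):
                if exited(c):
                    rows.append((tree.tree_id, node.node_id, t,
                                 node.weight / n_trees))
                    hit = True
                    break
            if hit:
                skip.add(node.node_id)
    return pd.DataFrame(rows, columns=["tree_id", "branch_id", "time", "weight"])


def first_passage_probability(
    trees: Sequence[TrajectoryTree],
    exited: Callable[[tuple], bool],
) -> float:
    """Weighted probability that a lineage has ever satisfied ``exited``."""
    ev = first_passage_events(trees, exited)
    return float(ev["weight"].sum())


def displacement_pairs(
    trees: Sequence[TrajectoryTree],
    coord_names: Sequence[str],
    dt: float,
) -> pd.DataFrame:
    """Outgoing displacements over interval ``dt`` paired strictly within a
    branch (never across branching or pruning nodes).

    Returns one row per pair: starting coordinates, displacements
    (columns ``d_<name>``) and the branch weight (normalized per tree).
    """
    n_trees = max(len(trees), 1)
    rows = []
    tol = 1e-6 * max(dt, 1.0)
    for tree in trees:
        for node, _ in tree.walk():
            w = node.weight / n_trees
            ts = node.times
            cs = node.coords
            j = 0
            for i in range(len(ts)):
                while j < len(ts) and ts[j] < ts[i] + dt - tol:
                    j += 1
                if j >= len(ts):
                    break
                if abs(ts[j] - ts[i] - dt) <= tol:
                    d = tuple(b - a for a, b in zip(cs[i], cs[j]))
                    rows.append((ts[i], *cs[i], *d, w))
    cols = ["time", *coord_names, *[f"d_{c}" for c in coord_names], "weight"]
    return pd.DataFrame(rows, columns=cols)
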