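"""Numba kernels for the lattice Gillespie simulation.

The exact direct-method SSA is applied to the union of all reaction
channels of all nuclei plus diffusive hop channels between neighboring
nuclei (the hop channels make the scheme equivalent to the
next-subvolume method: a hop annihilates a copy in the origin volume and
inserts it into a uniformly chosen existing neighbor).

Event selection is two-level: a per-nucleus total propensity array is
kept up to date (only the nuclei touched by an event are recomputed) and
the nucleus is found by a linear cumulative scan, then the channel
within the nucleus by re-enumerating its channels in a fixed order.  The
running total propensity is refreshed from scratch periodically to
suppress floating-point drift.

Channel order within a nucleus (must match between `_nucleus_propensity`
and `_execute_in_nucleus`):

    per gene g = 0..3: production, monomer decay, free-dimer decay,
                       dimerization, dedimerization
    per (target, repressor) with an existing site: bind, unbind
    per species s = 0..7 (4 monomers then 4 free dimers): hop out

Bound repressor dimers are immobile, protected from degradation and
re-enter the free pool only by unbinding.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# indices into the packed float64 parameter vector
P_BETA, P_MUM, P_MUD, P_KOND_V, P_KOFFD, P_KONR_V, P_KDIFF4 = range(7)


@njit(cache=True, inline="always")
def _nucleus_propensity(n, mono, dimr, bound, site, off, nnbr, par):
    tot = 0.0
    for g in range(4):
        repressed = False
        for r in range(4):
            if bound[n, g, r]:
                repressed = True
                break
        if not repressed:
            tot += par[P_BETA]
        m = mono[n, g]
        d = dimr[n, g]
        tot += par[P_MUM] * m
        tot += par[P_MUD] * d
        tot += par[P_KOND_V] * m * (m - 1)
        tot += par[P_KOFFD] * d
    for t in range(4):
        for r in range(4):
            if site[n, t, r] == 0:
                continue
            if bound[n, t, r]:
                tot += off[t, r]
            else:
                tot += par[P_KONR_V] * dimr[n, r]
    nfree = 0
    for g in range(4):
        nfree += mono[n, g] + dimr[n, g]
    tot += par[P_KDIFF4] * nnbr[n] * nfree
    return tot


@njit(cache=True)
def _execute_in_nucleus(n, resid, mono, dimr, bound, site, off, nbr, nnbr, par):
    """Walk the channel list of nucleus ``n`` until ``resid`` is exhausted,
    execute that channel, and return the index of the other affected
    nucleus (hop destination) or -1."""
    for g in range(4):
        repressed = False
        for r in range(4):
            if bound[n, g, r]:
                repressed = True
                break
        if not repressed:
            resid -= par[P_BETA]
            if resid < 0.0:
                mono[n, g] += 1
                return -1
        m = mono[n, g]
        d = dimr[n, g]
        resid -= par[P_MUM] * m
        if resid < 0.0:
            mono[n, g] -= 1
            return -1
        resid -= par[P_MUD] * d
        if resid < 0.0:
            dimr[n, g] -= 1
            return -1
        resid -= par[P_KOND_V] * m * (m - 1)
        if resid < 0.0:
            mono[n, g] -= 2
            dimr[n, g] += 1
            return -1
        resid -= par[P_KOFFD] * d
        if resid < 0.0:
            mono[n, g] += 2
            dimr[n, g] -= 1
            return -1
    for t in range(4):
        for r in range(4):
            if site[n, t, r] == 0:
                continue
            if bound[n, t, r]:
                resid -= off[t, r]
                if resid < 0.0:
                    bound[n, t, r] = 0
                    dimr[n, r] += 1
                    return -1
            else:
                resid -= par[P_KONR_V] * dimr[n, r]
                if resid < 0.0:
                    bound[n, t, r] = 1
                    dimr[n, r] -= 1
                    return -1
    # hop channels; uniform choice among existing neighbors
    for s in range(8):
        g = s % 4
        cnt = mono[n, g] if s < 4 else dimr[n, g]
        resid -= par[P_KDIFF4] * nnbr[n] * cnt
        if resid < 0.0:
            k = int(np.random.random() * nnbr[n])
            if k >= nnbr[n]:
                k = nnbr[n] - 1
            dest = nbr[n, k]
            if s < 4:
                mono[n, g] -= 1
                mono[dest, g] += 1
            else:
                dimr[n, g] -= 1
                dimr[dest, g] += 1
            return dest
    # floating point leftover: retry the dominant channel deterministically
    # (practically unreachable; decay a particle if any, else produce)
    for g in range(4):
        if mono[n, g] > 0:
            mono[n, g] -= 1
            return -1
    mono[n, 0] += 1
    return -1


@njit(cache=True)
def recompute_propensities(mono, dimr, bound, site, off, nnbr, par, P):
    tot = 0.0
    for n in range(mono.shape[0]):
        P[n] = _nucleus_propensity(n, mono, dimr, bound, site, off, nnbr, par)
        tot += P[n]
    return tot


@njit(cache=True)
def advance(mono, dimr, bound, site, off, nbr, nnbr, par, P, t, t_end, seed):
    """Advance the lattice state in place from ``t`` to ``t_end``.

    Returns (t_final, alive): ``alive`` is False when every channel had
    zero propensity (absorbing state).
    """
    np.random.seed(seed)
    n_nuc = mono.shape[0]
    Ptot = recompute_propensities(mono, dimr, bound, site, off, nnbr, par, P)
    nevents = 0
    while True:
        if Ptot <= 1e-300:
            return t, False
        u = np.random.random()
        dt = -np.log(1.0 - u) / Ptot
        if t + dt >= t_end:
            return t_end, True
        t += dt
        target = np.random.random() * Ptot
        n = 0
        acc = P[0]
        while acc <= target and n < n_nuc - 1:
            n += 1
            acc += P[n]
        resid = target - (acc - P[n])
        dest = _execute_in_nucleus(n, resid, mono, dimr, bound, site, off, nbr, nnbr, par)
        newPn = _nucleus_propensity(n, mono, dimr, bound, site, off, nnbr, par)
        Ptot += newPn - P[n]
        P[n] = newPn
        if dest >= 0:
            newPd = _nucleus_propensity(dest, mono, dimr, bound, site, off, nnbr, par)
            Ptot += newPd - P[dest]
            P[dest] = newPd
        nevents += 1
        if nevents & 0xFFFF == 0:
            Ptot = recompute_propensities(mono, dimr, bound, site, off, nnbr, par, P)


@njit(cache=True)
def one_step(mono, dimr, bound, site, off, nbr, nnbr, par, P, seed):
    """Execute exactly one SSA event.  Returns (dt, alive)."""
    np.random.seed(seed)
    Ptot = recompute_propensities(mono, dimr, bound, site, off, nnbr, par, P)
    if Ptot <= 1e-300:
        return 0.0, False
    dt = -np.log(1.0 - np.random.random()) / Ptot
    target = np.random.random() * Ptot
    n_nuc = mono.shape[0]
    n = 0
    acc = P[0]
    while acc <= target and n < n_nuc - 1:
        n += 1
        acc += P[n]
    resid = target - (acc - P[n])
    _execute_in_nucleus(n, resid, mono, dimr, bound, site, off, nbr, nnbr, par)
    return dt, True


# ---------------------------------------------------------------------------
# 1D birth-death toy process (used to validate the rare-event sampler
# against brute-force simulation).
# ---------------------------------------------------------------------------


@njit(cache=True)
def bd_advance(n0, t, t_end, birth, death, seed):
    """Birth-death chain: births at constant rate, deaths at ``death*n``.

    Returns (n_final, n_max_seen).
    """
    np.random.seed(seed)
    n = n0
    nmax = n0
    while True:
        a = birth + death * n
        dt = -np.log(1.0 - np.random.random()) / a
        if t + dt >= t_end:
            return n, nmax
        t += dt
        if np.random.random() * a < birth:
            n += 1
            if n > nmax:
                nmax = n
        else:
            n -= 1


@njit(cache=True)
def bd_first_passage_count(n0, K, T, birth, death, n_runs, seed):
    """Number of direct runs (out of ``n_runs``) that reach count >= K by time T."""
    np.random.seed(seed)
    hits = 0
    for _ in range(n_runs):
        n = n0
        t = 0.0
        while t < T:
            a = birth + death * n
            dt = -np.log(1.0 - np.random.random()) / a
            t += dt
            if t >= T:
                break
            if np.random.random() * a < birth:
                n += 1
                if n >= K:
                    hits += 1
                    break
            else:
                n -= 1
    return hits
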