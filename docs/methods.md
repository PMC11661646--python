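# Methods

## Model

Four genes A, B, C, D are expressed in nuclei arranged on a cylindrical
lattice of `N_z x N_phi` well-stirred reaction volumes (periodic
circumferentially, no-flux at the axial ends), initialized as five
rectangular stripes in the order A-B-C-D-A.  Per nucleus and gene the
reactions are:

* production of one monomer at rate `beta`, active iff **no** repressor
  dimer is bound to any of the gene's sites (OR logic; one
  non-competitive site per foreign gene);
* monomer and free-dimer degradation at `mu_M` and `mu_D`;
* homodimerization with propensity `kon_D * n1 (n1 - 1) / V_N` and
  dedimerization at `koff_D = kon_D / V_N` (so that most protein is
  dimeric at steady state);
* repressor binding of a free dimer of gene Y to its site on gene X's
  promoter with propensity `kon_R * n2(Y) / V_N`, and unbinding at
  `koff_s` for the strongly repressing next-nearest-neighbor pairs
  {A,C} and {B,D}, or `kappa * koff_s` for the weakly repressing
  nearest-neighbor pairs.  `kappa = inf` removes the weak sites
  entirely (uncoupled limit).

Monomers and free dimers hop to each existing lattice neighbor with
propensity `k_diff/4`, `k_diff = 4 D_P / l^2`, which embeds diffusion
exactly in the stochastic simulation (next-subvolume scheme).  Bound
dimers are immobile, are protected from degradation, and return to the
free pool only by unbinding.  With *pinning* enabled, the A promoter
carries no repressor sites in the first and last axial rings, so A is
produced there unconditionally — a proxy for residual, strictly
peripheral maternal inputs.

The simulator is an exact direct-method SSA over the union of all
channels, with per-nucleus propensity caching, two-level event
selection, and periodic refresh of the running total to suppress
floating-point drift.  Transcription and translation are merged into
the single production step; bursting, enhancer dynamics,
auto-activation and gene-specific rate asymmetries are deliberately
outside the model.

## Default parameters

Anchor quantities (units; value; role):

| quantity | value | meaning |
|---|---|---|
| `l` | 8.5 um | internuclear spacing |
| `D_P` | 1 um^2/s | internuclear protein diffusion |
| `N_z x N_phi` | 40 x 8 | lattice (axial length L = 340 um) |
| effective lifetime `1/gamma` | 100 s | protein turnover (`mu_M = mu_D = 0.01/s`) |
| `H/gamma` | 0.2295 um^-3 | equilibrium expression level of the effective model |
| `lambda = sqrt(D/gamma)` | 8.62 um | interaction length of the effective model |
| `K_s` | 0.0030357 um^-3 | strong dissociation concentration (`kappa_theor = 75.6`) |
| copy number | 15 molecules/nucleus | monomers + dimer particles at steady state |
| `kon_D` | `2 kon_R` | both dimerization partners diffuse |
| `koff_D` | `kon_D / V_N` | keeps the dimer fraction high |
| `D_N`, `sigma_R` | 4 um^2/s, 0.0145 um | only set `kon_R = 4 pi sigma_R D_N` |

Every remaining microscopic rate follows algebraically from these
anchors through the stationary state: the monomer/dimer ratio
`r = X1~/X2~` is fixed by `D = D_P/(1+r) = gamma * lambda^2`, the
nuclear volume by the copy-number anchor
`V_N = 15/(X1~ + X2~)` (= 48.56 um^3), the dimerization rate by the
dimer-equilibrium condition, and `beta = H gamma (1+r) V_N` (= 0.15/s).
The copy-number anchor counts **molecules** (a dimer counts once);
counting protein units instead (a dimer counts twice) is incompatible
with the other anchors — it forces `X1~^2 < X2~/V_N` and hence a
negative dimerization rate — so the molecule convention is the only
self-consistent reading.  The defaults round-trip: mapping them back
through the effective model reproduces the anchors to machine
precision, which the test suite asserts.

## Effective model and contact-zone stability

Averaging out monomers via `X1 ~ (X1~/X2~) X2` turns the microscopic
system into a dimer-only reaction–diffusion model with Heaviside
production,

    dX2/dt = D d2X2/dx2 - gamma X2 + H theta(1 - sum_{Y!=X} Y2 / K_XY),

with `D = D_P/(1+r)`, `gamma = (mu_D + mu_M r)/(1+r)`,
`H = (beta/V_N)/(1+r)` and dissociation concentrations
`K = koff/kon_R`.  One caveat is deliberate: this mapping converts
monomer into dimer concentration one-to-one, whereas the simulator's
dimerization consumes two monomers per dimer.  The mapping is used
as-is for all theory quantities (it is what defines `H/gamma`, `K_s`
and hence `kappa_theor`); the deterministic oracle for the *simulator's*
stationary copy numbers is the mass-conserving mean field
(`theory.stationary_counts_mass_conserving`), which differs from the
mapping's closed form and matches the SSA to within sampling error.

Two contact-zone types occur in the five-stripe pattern: (i) two strong
antagonists with the weak cushion gene in the background at its
equilibrium level `H/gamma`, and (ii) two weak antagonists.  Reducing
each zone to a symmetric two-gene free-boundary problem gives the
stability variable `R = 1 - 2 gamma C~/(eps H)` and the stationary
signed width

    delta_r = sgn(R) * lambda * (-ln(1 - |R|)),   stable iff -1 < R < 1,

with `delta_r > 0` a gap between the active-production regions and
`delta_r < 0` an overlap.  Sign convention: the closed form here was
re-derived from the Green's-function integrals of the free-boundary
problem (and verified against numerical quadrature); with this
convention all landmark values come out with the physically correct
sign (gap widths positive).  Simultaneous stability of both types
requires `K_w = H/gamma`, i.e. `kappa_theor = (H/gamma)/K_s = 75.6`;
the type-(ii) width changes sign at `kappa_0 = kappa_theor/2 = 37.8`;
for `kappa -> inf` the type-(i) gap saturates at
`lambda * ln(kappa_0) = 31.4 um` (an exact identity).

The traveling-front system for asymmetric interactions,

    R_X = s - exp(( v dr - |dr| w)/(2D)) (s + v/w)
    R_Y = s - exp((-v dr - |dr| w)/(2D)) (s - v/w),
    w = sqrt(4 D gamma + v^2),  s = sgn(dr),

is solved by damped multi-start root finding over both sign branches;
an explicit finite-difference integrator with Heaviside kinetics
(forward Euler, no-flux ends, `dx <= lambda/10`, `dt <= dx^2/(2D)`
enforced; boundaries located by linear interpolation of the
activation-threshold crossing) serves as an independent oracle.  The
two routes agree to within 5% in `v` and two grid cells in `delta_r`
across the tested interaction grid.  Deterministically the five-stripe
pattern persists wherever at least one zone type is stable — on both
sides of `kappa_theor`; exactly at `kappa_theor` the Heaviside dynamics
is knife-edge (every zone wants maximal width) and the discretized
integration is not meaningful there.

## Order parameters and phase-space analysis

Pattern integrity is tracked by `lambda_AC = max([A],[C])/N` and
`lambda_BD = max([B],[D])/N`, with totals counting dimers twice
(including promoter-bound dimers) and `N` the total over all species.
If both members of a pair are absent its factor is defined as 0.  The
progress coordinate is their sum.  Phase space is partitioned at
`lambda_AC <= 0.45`, `lambda_BD <= 0.43` into the stable region `R_S`,
the two single-loss regions and the double-loss remainder; the
thresholds are fixed for all `kappa` (they are exposed as overrides).

Survival `S(t)` is the weighted probability that a trajectory lineage
has never left `R_S` up to `t`; re-entries are not counted, and a
lineage contributes the weight it carries at its first exit.  The
destruction rate is obtained by the lag-scan protocol: for each
`t_start` on a grid (default every 15 min up to half the horizon) fit
`exp(-k_D (t - t_lag))` on `[t_start, t_end]` and accept the fit
minimizing `|t_lag - t_start|`; a linear control fit of `k (t - t_lag)`
to `1 - S` is reported alongside.  Start windows where `S` has already
decayed below 0.1 are excluded — on the flat tail the selection rule
would otherwise lock onto a meaningless floor fit.  Fluxes into the
destroyed-pattern regions are slopes of linear fits to the region
occupations (intercepts discarded).

Drift and diffusion of the reduced dynamics are estimated from
displacements over a fixed interval `Delta t`, paired strictly within
one branch of the trajectory tree (never across a branching or pruning
node) and assigned to the bin the displacement *leaves*:

    v(bin)        = <Delta lambda> / Delta t                    [PSU/h]
    D_lambda(bin) = (<|Delta lambda|^2> - |<Delta lambda>|^2)/(4 Delta t)

(the standard 2D variance decomposition).  The pseudopotential is
`-log p~` of the per-bin weighted outgoing-sample density, smoothed by
a square median filter (default 4 x 4, edge replication); bins never
visited are masked, not zeroed.  Default binning is 50 x 50 over the
unit square.

## Rare-event sampler

Breakdown events are sampled by non-stationary forward flux sampling:
trajectories are propagated in 60 s chunks; at chunk ends the progress
coordinate is evaluated against interfaces (default 0.50 to 0.84 in
steps of 0.02) and crossings are accumulated per (interface, 15-min
time bin).  On a crossing the branch is split into
`n = clip(round(target/observed), 0, 4)` children of weight `w/n`,
where `observed` is the cell's accumulated weighted crossing count and
`target` the running mean over all populated cells — the global mean is
what makes rarely reached interfaces branch and oversampled cells
prune, equalizing the flux in both the coordinate and the time
direction.  `n = 0` triggers Russian roulette with survival probability
`q = max(target/observed, 1/2)` and surviving weight `w/q`, so all
operations conserve weight exactly (splits) or in expectation
(roulette).  Decisions are the identity until the histogram holds 20
crossings.  Each tree starts from the standardized stripe pattern
relaxed for 30 min with its own seed; trees are started until the
cumulative simulated-time budget is exhausted, and the last tree always
runs to its horizon.  Every source of randomness derives from one root
seed through spawned generators, so runs are exactly reproducible.

Unbiasedness is validated on a birth–death toy process (births at
constant rate, deaths proportional to the count, progress coordinate =
running maximum over the threshold): the weighted first-passage
estimate agrees with brute-force direct simulation within combined
statistical error, at substantially enhanced coverage beyond the first
interface.

## Perturbation experiments

Relaxed patterns are perturbed by axial copy-shift: for a "C expansion"
every nucleus more than `Delta` rows posterior to the midline receives
the pre-perturbation configuration from `Delta` rows anterior (the
first `Delta` rows past the midline all receive the mid-row
configuration; the posterior-most ring is exempt so pinning is
preserved); an "A expansion" applies the same shift anchored at row 5
(1-based), overwriting only rows up to the midline.  Full nucleus
configurations (counts and promoter occupancy) are copied, so repressor
bookkeeping stays valid by construction.  Severity `Delta` in {4, 8,
12} rows; after perturbing, ensembles of 10 replicates are re-simulated
for 20 h and the centers of mass of the five domains (A split at
mid-system) are recorded every 10 min and averaged.

## Synthetic generators

`altcushions.synthetic` produces data with known ground truth in the
exact formats the estimators consume: one-step Euler–Maruyama
displacement pairs and full trajectories of a 2D overdamped Langevin
process, exponential first-exit lineages, and noisy exponential
survival curves.  They emulate the *statistical structure* of sampler
output — weighted, branch-local displacements and weighted exit
events — not the lattice dynamics itself: estimator-recovery results
therefore certify the estimators, and say nothing about whether the
reduced Langevin description is adequate for the lattice model (that
adequacy is an assumption of the phase-space analysis, as usual for
projections onto slow coordinates).

## Problem sizes and known limitations

* Test and example runs use desk-scale sizes chosen as the package's
  defaults: single-nucleus validation runs of ~4e5 simulated seconds,
  toy-sampler budgets of ~1.5e4 simulated seconds against 1e5 direct
  runs, and stability scans on a 20 x 4 lattice with ~24 trajectories
  and 6 h horizons.  Full-scale stability times at the optimum require
  cumulative simulated times of order 2–5e7 s; the corresponding
  optima (`kappa_opt = 31.6` pinned, `100` unpinned) are recorded in
  `experiments.FULL_SCALE_TARGETS` as reference points rather than
  re-estimated.
* At reduced lattice sizes the fixed region thresholds interact with
  the geometry: with pinning, the constitutively expressing boundary
  rings are 10% of all nuclei on a 20-row lattice (5% at 40 rows),
  which inflates `lambda_AC` toward its 0.45 threshold and makes the
  pinned system *appear* less stable than the unpinned one at equal
  `kappa` — a threshold artifact, not a property of the dynamics.
  Separately, at strong weak-repression (`kappa ~ 3`) the pattern can
  melt into a fine-grained mosaic whose global pair totals stay
  balanced; the count-based asymmetry factors are blind to this failure
  mode, so low-`kappa` destruction estimated from `R_S` exits is a
  lower bound.  Both effects are documented outcomes of the scaled-down
  surrogate experiments.
* The theory treats each contact zone in isolation; near `kappa_theor`
  where widths diverge, and for spatial variation of all four genes at
  once, it is a qualitative guide rather than a quantitative predictor.
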