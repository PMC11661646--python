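"""Densities, survival fits, flux and drift/diffusion estimator recovery."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from altcushions.observables import RegionBounds
from altcushions.phase_analysis import (EmptyWindowError, SurvivalCurve,
                                        average_flux, fit_destruction_rate,
                                        phase_diffusion, pseudopotential,
                                        region_occupation,
                                        survival_probability, velocity_field,
                                        weighted_histogram)
from altcushions.synthetic import (exponential_exit_events, langevin_pairs,
                                   langevin_trajectory_samples,
                                   noisy_exponential_survival)


def _samples(points, weights=None, t=0.0):
    points = np.atleast_2d(points)
    n = len(points)
    w = np.ones(n) if weights is None else np.asarray(weights)
    return pd.DataFrame({"time": np.full(n, t), "lambda_AC": points[:, 0],
                         "lambda_BD": points[:, 1], "weight": w})


def test_weighted_histogram_point_masses():
    H, _, _ = weighted_histogram(_samples([(0.305, 0.305)]), 0.0, bins=10)
    assert H.sum() == pytest.approx(1.0)
    assert H.max() == pytest.approx(1.0)
    H, _, _ = weighted_histogram(_samples([(0.15, 0.15), (0.85, 0.85)]), 0.0, bins=10)
    assert np.sort(H[H > 0]) == pytest.approx([0.5, 0.5])
    with pytest.raises(EmptyWindowError):
        weighted_histogram(_samples([(0.5, 0.5)], t=10_000.0), 0.0)


def test_weighted_histogram_uniform_within_multinomial_error(rng):
    n = 20000
    pts = rng.uniform(0, 1, size=(n, 2))
    H, _, _ = weighted_histogram(_samples(pts), 0.0, bins=5)
    expected = 1.0 / 25
    se = math.sqrt(expected * (1 - expected) / n)
    assert np.all(np.abs(H - expected) < 5 * se)


def test_survival_trivial_cases():
    t = np.linspace(0, 10, 11)
    S = survival_probability(pd.DataFrame(columns=["time", "weight"]), t)
    assert np.all(S.S == 1.0)
    ev = pd.DataFrame({"time": [3.0, 3.0], "weight": [0.5, 0.5]})
    S = survival_probability(ev, t)
    assert np.all(S.S[t < 3.0] == 1.0) and np.all(S.S[t >= 3.0] == 0.0)
    assert np.all(np.diff(S.S) <= 1e-12)   # monotone non-increasing


def test_survival_exponential_lineages_ks(rng):
    k = 1.0 / 3600.0
    ev = exponential_exit_events(k, t_lag=0.0, n_lineages=800, rng=rng)
    res = sps.kstest(ev["time"], "expon", args=(0.0, 1.0 / k))
    assert res.pvalue > 0.01
    t = np.linspace(0, 4 / k, 200)
    S = survival_probability(ev, t)
    assert np.max(np.abs(S.S - np.exp(-k * t))) < 0.06


def test_fit_destruction_rate_exact_input():
    t = np.arange(0, 40_000.0, 300.0)
    S = np.exp(-1e-4 * np.clip(t - 2000.0, 0, None))
    fit = fit_destruction_rate(SurvivalCurve(t, S))
    assert fit.k_D == pytest.approx(1e-4, rel=1e-3)
    assert fit.t_lag == pytest.approx(2000.0, abs=30.0)
    assert fit.tau_D == pytest.approx(1e4, rel=1e-3)


def test_fit_destruction_rate_flat_curve_sentinel():
    t = np.arange(0, 10_000.0, 300.0)
    fit = fit_destruction_rate(SurvivalCurve(t, np.ones_like(t)))
    assert fit.k_D == 0.0 and math.isinf(fit.tau_D)


def test_fit_destruction_rate_noisy_recovery(rng):
    k_true, lag_true = 2e-4, 1500.0
    t = np.arange(0, 30_000.0, 300.0)
    S = noisy_exponential_survival(k_true, lag_true, t, noise=0.05, rng=rng)
    fit = fit_destruction_rate(SurvivalCurve(t, S))
    assert fit.k_D == pytest.approx(k_true, rel=0.10)
    assert fit.k_lin > 0


def test_average_flux_examples():
    t = np.linspace(0, 100, 50)
    assert average_flux(t, 0.01 * t) == pytest.approx(0.01)
    assert average_flux(t, np.full_like(t, 0.3)) == pytest.approx(0.0, abs=1e-12)


def test_region_occupation_conserves_probability(rng):
    n = 500
    pts = rng.uniform(0, 1, size=(n, 2))
    df = _samples(pts)
    df["time"] = rng.integers(0, 5, n) * 10.0
    occ = region_occupation(df)
    assert np.allclose(occ.sum(axis=1), 1.0)
    # fluxes into destroyed-pattern regions balance the survival loss:
    # d(R_S)/dt = -(sum of influxes) for a closed system
    slopes = [average_flux(occ.index.to_numpy(), occ[c].to_numpy())
              for c in occ.columns]
    assert sum(slopes) == pytest.approx(0.0, abs=1e-12)


def test_velocity_field_recovers_known_drift(rng):
    """Constant-drift Langevin pairs: every populated bin reports the drift
    (PSU/h) within 3 standard errors."""
    v_true = np.array([0.02, -0.01])     # PSU/s
    D = 1e-4
    dt = 1.0
    pairs = langevin_pairs(lambda x: np.tile(v_true, (len(x), 1)), D, dt,
                           n_pairs=40000, rng=rng)
    grid = velocity_field(pairs, dt, bins=4)
    se = math.sqrt(2 * D * dt) / math.sqrt(40000 / 16) * 3600.0
    assert np.nanmax(np.abs(grid.vx - v_true[0] * 3600.0)) < 3 * se
    assert np.nanmax(np.abs(grid.vy - v_true[1] * 3600.0)) < 3 * se


def test_velocity_field_isotropic_walk_averages_to_zero(rng):
    D, dt, n = 1e-4, 1.0, 50000
    pairs = langevin_pairs(lambda x: np.zeros_like(x), D, dt, n_pairs=n, rng=rng)
    grid = velocity_field(pairs, dt, bins=2)
    se = math.sqrt(2 * D * dt) / math.sqrt(n / 4) * 3600.0
    assert np.nanmax(np.abs(grid.vx)) < 3 * se
    assert np.nanmax(np.abs(grid.vy)) < 3 * se
    assert grid.counts.sum() == n


def test_phase_diffusion_deterministic_lines_and_brownian(rng):
    dt = 1.0
    pairs = langevin_pairs(lambda x: np.tile([0.01, 0.01], (len(x), 1)),
                           0.0, dt, n_pairs=5000, rng=rng)
    grid = phase_diffusion(pairs, dt, bins=3)
    assert np.nanmax(np.abs(grid.D_lambda)) < 1e-12
    D_true = 2e-4
    pairs = langevin_pairs(lambda x: np.zeros_like(x), D_true, dt,
                           n_pairs=60000, rng=rng)
    grid = phase_diffusion(pairs, dt, bins=3)
    assert np.nanmean(grid.D_lambda) == pytest.approx(D_true * 3600.0, rel=0.05)


def test_joint_drift_diffusion_recovery_from_trajectories(rng):
    """Linear restoring drift + diffusion recovered jointly from full
    trajectories of the overdamped Langevin generator."""
    k_relax = 0.05
    center = np.array([0.5, 0.5])
    D_true = 5e-5
    dt = 1.0

    def drift(x):
        return -k_relax * (x - center)

    samples = langevin_trajectory_samples(drift, D_true, dt, n_steps=200,
                                          n_traj=200, rng=rng)
    from altcushions.cli import _pairs_from_samples
    pairs = _pairs_from_samples(
        samples.assign(delta_AC=0.0, delta_BD=0.0), dt)
    vf = velocity_field(pairs, dt, bins=4, range_=((0.3, 0.7), (0.3, 0.7)))
    centers = 0.5 * (vf.x_edges[:-1] + vf.x_edges[1:])
    # drift toward the center: x-velocity positive left of center, negative right
    left = np.nanmean(vf.vx[0, :])
    right = np.nanmean(vf.vx[-1, :])
    expect_left = k_relax * (center[0] - centers[0]) * 3600.0
    assert left == pytest.approx(expect_left, rel=0.25)
    assert right == pytest.approx(-expect_left, rel=0.25)
    df = phase_diffusion(pairs, dt, bins=2, range_=((0.3, 0.7), (0.3, 0.7)))
    assert np.nanmean(df.D_lambda) == pytest.approx(D_true * 3600.0, rel=0.10)


def test_pseudopotential_flat_spike_and_barrier(rng):
    # uniform density -> flat potential
    pairs = langevin_pairs(lambda x: np.zeros_like(x), 1e-6, 1.0,
                           n_pairs=40000, rng=rng)
    grid = pseudopotential(pairs, bins=5, n_filt=3)
    pot = grid.potential
    assert np.nanmax(pot) - np.nanmin(pot) < 0.2
    # a single spike on a flat background is removed by the median filter
    spiked = pd.concat([pairs, pairs.iloc[:1].assign(weight=500.0)])
    g2 = pseudopotential(spiked, bins=5, n_filt=3)
    assert np.nanmax(g2.potential) - np.nanmin(g2.potential) < 0.4
    # two-Gaussian mixture: two minima separated by a saddle whose height
    # equals the -log density ratio of the analytic mixture
    from scipy.stats import multivariate_normal

    n, sig = 150000, 0.12
    m1, m2 = np.array([0.35, 0.35]), np.array([0.65, 0.65])
    comp = rng.random(n) < 0.5
    pts = np.where(comp[:, None], rng.normal(m1, sig, (n, 2)),
                   rng.normal(m2, sig, (n, 2)))
    pts = np.clip(pts, 0.001, 0.999)
    df = pd.DataFrame({"time": 0.0, "lambda_AC": pts[:, 0],
                       "lambda_BD": pts[:, 1],
                       "d_lambda_AC": 0.0, "d_lambda_BD": 0.0, "weight": 1.0})
    bins = 40
    g3 = pseudopotential(df, bins=bins, n_filt=3)
    pot = g3.potential
    centers = 0.5 * (g3.x_edges[:-1] + g3.x_edges[1:])
    diag = np.array([pot[i, i] for i in range(bins)])
    mid = np.argmin(np.abs(centers - 0.5))
    barrier = np.nanmin(diag[mid - 1:mid + 2])
    depth = np.nanmin(pot)

    def mix(x):
        return 0.5 * multivariate_normal.pdf(x, m1, sig**2) \
            + 0.5 * multivariate_normal.pdf(x, m2, sig**2)

    expected = math.log(mix(m1) / mix([0.5, 0.5]))
    assert barrier - depth == pytest.approx(expected, rel=0.25)
    # the two minima sit at the mixture modes
    i1 = np.unravel_index(np.nanargmin(np.where(np.isnan(pot), np.inf, pot)), pot.shape)
    assert abs(centers[i1[0]] - m1[0]) < 0.1 or abs(centers[i1[0]] - m2[0]) < 0.1
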