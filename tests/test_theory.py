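"""Effective mapping, contact-zone stability and the traveling-front oracle."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from altcushions.model import default_params
from altcushions import theory as th


@pytest.fixture(scope="module")
def eff():
    return th.map_effective(default_params())


rate = st.floats(1e-4, 10.0)


@given(beta=st.floats(1e-3, 10.0), muM=rate, muD=rate, konD=st.floats(1e-3, 10.0),
       VN=st.floats(5.0, 200.0))
@settings(max_examples=100, deadline=None)
def test_stationary_solution_satisfies_defining_equations(beta, muM, muD, konD, VN):
    p = default_params().replace(beta=beta, mu_M=muM, mu_D=muD,
                                 kon_D=konD, V_N=VN)
    try:
        X1, X2 = th.stationary_monomer_dimer(p)
    except th.InvalidRegimeError:
        return
    beta_c = beta / VN
    r1 = -muM * X1 - konD * X1**2 + p.koff_D * X2 + beta_c
    r2 = -(p.koff_D + muD) * X2 + konD * X1**2
    scale = max(1.0, beta_c, muM * X1, konD * X1**2, (p.koff_D + muD) * X2)
    assert abs(r1) < 1e-7 * scale
    assert abs(r2) < 1e-7 * scale


def test_stationary_vanishes_without_production():
    p = default_params().replace(beta=1e-300)
    X1, X2 = th.stationary_monomer_dimer(p)
    assert X1 == pytest.approx(0.0, abs=1e-12)
    assert X2 == pytest.approx(0.0, abs=1e-12)


def test_map_effective_reference_landmarks(eff):
    assert eff.H_over_gamma == pytest.approx(0.23, rel=0.01)
    assert eff.lambda_char == pytest.approx(8.62, rel=0.01)
    assert eff.K_s == pytest.approx(0.003, rel=0.02)


def test_gamma_equals_mu_when_rates_equal():
    p = default_params().replace(mu_M=0.004, mu_D=0.004)
    assert th.map_effective(p).gamma == pytest.approx(0.004)


def test_kappa_values(eff):
    kt = th.kappa_theor(eff)
    k0 = th.kappa_zero(eff)
    assert kt == pytest.approx(76.0, rel=0.02)
    assert k0 == pytest.approx(38.0, rel=0.02)
    assert k0 == pytest.approx(kt / 2.0)         # exact identity
    # doubling K_s halves kappa_theor
    assert th.kappa_theor(dataclasses.replace(eff, K_s=2 * eff.K_s)) \
        == pytest.approx(kt / 2.0)
    assert th.kappa_theor(dataclasses.replace(eff, K_s=eff.H_over_gamma)) \
        == pytest.approx(1.0)


def test_contact_zone_landmarks(eff):
    # type (i) without weak interactions: gap saturating near +31.3 um
    zi = th.contact_zone("i", dataclasses.replace(eff, K_w=math.inf))
    assert zi.stable and zi.delta_r == pytest.approx(31.3, rel=0.02)
    # exact identity |dr_i(inf)| = lambda * ln(kappa_0)
    assert zi.delta_r == pytest.approx(eff.lambda_char * math.log(th.kappa_zero(eff)))
    # type (ii) at kappa_0: zero width
    zii = th.contact_zone("ii", eff.with_kappa(th.kappa_zero(eff)))
    assert zii.stable and zii.delta_r == pytest.approx(0.0, abs=1e-9)
    assert th.delta_r_from_R(0.0, eff.lambda_char) == 0.0


def test_width_curves_shape(eff):
    """Signed widths versus kappa follow the characteristic curve shape."""
    kt, k0 = th.kappa_theor(eff), th.kappa_zero(eff)
    lam = eff.lambda_char
    # type (ii): positive gap below kappa_0, overlap between kappa_0 and
    # kappa_theor, diverging towards kappa_theor, unstable beyond
    for k in (2.0, 10.0, 0.8 * k0):
        assert th.contact_zone("ii", eff.with_kappa(k)).delta_r > 0
    for k in (1.1 * k0, 0.9 * kt):
        z = th.contact_zone("ii", eff.with_kappa(k))
        assert z.stable and z.delta_r < 0
    assert th.contact_zone("ii", eff.with_kappa(0.999 * kt)).delta_r < -3 * lam
    assert not th.contact_zone("ii", eff.with_kappa(1.1 * kt)).stable
    # type (i): unstable below kappa_theor, diverging just above, then
    # monotone decrease to the saturation limit
    assert not th.contact_zone("i", eff.with_kappa(0.9 * kt)).stable
    assert th.contact_zone("i", eff.with_kappa(1.001 * kt)).delta_r > 3 * lam
    ks = [1.2 * kt, 2 * kt, 10 * kt, 100 * kt]
    widths = [th.contact_zone("i", eff.with_kappa(k)).delta_r for k in ks]
    assert all(np.diff(widths) < 0)
    limit = th.contact_zone("i", dataclasses.replace(eff, K_w=math.inf)).delta_r
    assert widths[-1] > limit and widths[-1] == pytest.approx(limit, rel=0.01)


def test_stability_conditions(eff):
    hg = eff.H_over_gamma
    both = th.stability_conditions(dataclasses.replace(eff, K_w=hg))
    assert both.simultaneous
    only_i = th.stability_conditions(dataclasses.replace(eff, K_w=2 * hg))
    assert only_i.type_i_stable and not only_i.type_ii_stable
    only_ii = th.stability_conditions(dataclasses.replace(eff, K_w=0.5 * hg))
    assert only_ii.type_ii_stable and not only_ii.type_i_stable
    # the type-(i) K_s bound is finite for finite K_w > H/gamma
    assert math.isfinite(only_i.K_s_max_type_i)
    assert math.isinf(th.stability_conditions(
        dataclasses.replace(eff, K_w=hg)).K_s_max_type_i)


def test_traveling_front_symmetric_consistency(eff):
    """Symmetric interactions force v = 0 with the closed-form width, on and
    off the simultaneous-stability manifold."""
    for kappa in (200.0, 50.0):
        ek = eff.with_kappa(kappa)
        zone = "i" if kappa > th.kappa_theor(eff) else "ii"
        Ct, eps = th.zone_constants(zone, ek)
        fs = th.solve_traveling(ek, Ct, Ct, eps, eps)
        assert fs.v == pytest.approx(0.0, abs=1e-12)
        assert fs.delta_r == pytest.approx(th.contact_zone(zone, ek).delta_r)


def test_traveling_front_matches_pde(eff):
    """Asymmetric activation thresholds: algebraic (v, delta_r) agrees with
    direct finite-difference integration."""
    ek = eff.with_kappa(200.0)
    Ct, eps = th.zone_constants("i", ek)
    fs = th.solve_traveling(ek, 1.15 * Ct, Ct, eps, eps)
    track = th.pde_front_tracker(ek, 1.15 * Ct, Ct, eps, eps, t_end=6000.0)
    v_pde = track.late_velocity()
    assert fs.v == pytest.approx(v_pde, rel=0.05)
    assert abs(fs.delta_r - track.late_separation()) < 2 * 0.8   # 2 grid cells
    assert fs.v > 0   # the harder-to-repress gene advances


def test_pde_refuses_unstable_discretization(eff):
    with pytest.raises(ValueError):
        th.pde_front_tracker(eff, 1.0, 1.0, 1.0, 1.0, dx=5.0)
    with pytest.raises(ValueError):
        th.pde_front_tracker(eff, 1.0, 1.0, 1.0, 1.0, dx=0.8, dt=10.0)


def test_pde_profile_plateaus_at_equilibrium(eff):
    """Away from the contact zone the expressed profile saturates at H/gamma."""
    ek = eff.with_kappa(200.0)
    Ct, eps = th.zone_constants("i", ek)
    track = th.pde_front_tracker(ek, Ct, Ct, eps, eps, t_end=3000.0)
    # stationary boundaries far from the domain ends
    assert 100.0 < track.q_X[-1] < 300.0
    # (plateau value is checked through the four-gene integration below)


def test_four_gene_pattern_persists_across_stable_range(eff):
    """Deterministically, the five-stripe pattern persists wherever at least
    one contact-zone type is stable (both below and above kappa_theor);
    interior profiles plateau at H/gamma."""
    for kappa in (3.0, 31.6, 1000.0):
        res = th.simulate_four_gene(eff.with_kappa(kappa), t_end=8000.0)
        assert res.five_domains_present(), kappa
    assert res.profiles.max() == pytest.approx(eff.H_over_gamma, rel=0.05)
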