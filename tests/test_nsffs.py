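"""Weight bookkeeping and unbiasedness of the rare-event sampler."""

import numpy as np
import pytest

from altcushions import _kernel
from altcushions.model import default_params
from altcushions.nsffs import (BirthDeathPropagator, CrossingStats,
                               LatticePropagator, SamplerConfig,
                               branch_decision, displacement_pairs,
                               first_passage_events,
                               first_passage_probability, reweight, run_nsffs)

TOY = dict(birth=1.0, death=0.25, n0=2, threshold=12)


def _toy_cfg(**kw):
    base = dict(
        interfaces=tuple(np.round(np.arange(TOY["n0"] + 1, TOY["threshold"] + 1)
                                  / TOY["threshold"], 6)),
        time_bin=5.0, t_chunk=0.5, dt_measure=0.5,
        n_B_max=4, T_max=20.0, T_cum_target=15000.0, min_crossings=20)
    base.update(kw)
    return SamplerConfig(**base)


def test_config_validation():
    with pytest.raises(ValueError):
        SamplerConfig(interfaces=(0.5, 0.4)).validate()
    with pytest.raises(ValueError):
        SamplerConfig(n_B_max=0).validate()
    SamplerConfig().validate()


def test_branch_decision_rules(rng):
    cfg = SamplerConfig(min_crossings=0)

    def stats_with(cells):
        s = CrossingStats(4, 4)
        for (i, b, w) in cells:
            s.register(i, b, w)
        return s

    # undersampled cell, factor-3 deficit -> 3 children, equal-split weight
    s = stats_with([(0, 0, 3.0), (1, 0, 3.0), (2, 1, 1.0)])  # target mean 7/3
    n, w = branch_decision(2, 1, 0.9, s, cfg, rng)
    assert (n, w) == (2, pytest.approx(0.45)) or (n, w) == (3, pytest.approx(0.3))
    s = stats_with([(0, 0, 3.0), (1, 0, 6.0), (2, 1, 1.0)])  # target ~3.33
    assert branch_decision(2, 1, 0.9, s, cfg, rng) == (3, pytest.approx(0.3))
    # balanced cell -> identity
    s = stats_with([(0, 0, 3.0), (1, 0, 3.0), (2, 0, 3.0)])
    assert branch_decision(0, 0, 0.9, s, cfg, rng) == (1, 0.9)
    # oversampled cell, factor-2 excess -> Russian roulette with q = 1/2:
    # either killed or continued with doubled weight
    s = stats_with([(0, 0, 2.0), (0, 1, 2.0), (1, 0, 8.0)])  # target 4, obs 8
    outcomes = {branch_decision(1, 0, 1.0, s, cfg, np.random.default_rng(k))
                for k in range(40)}
    assert outcomes == {(0, 0.0), (1, 2.0)}
    # branching factor is capped at n_B_max
    s = stats_with([(0, 0, 50.0), (1, 0, 50.0), (2, 1, 1.0)])
    n, w = branch_decision(2, 1, 1.0, s, cfg, rng)
    assert n == cfg.n_B_max and w == pytest.approx(1.0 / cfg.n_B_max)
    # cold start: identity before the histogram is warm
    cold = SamplerConfig(min_crossings=100)
    s = stats_with([(0, 0, 2.0), (1, 0, 8.0)])
    assert branch_decision(1, 0, 1.0, s, cold, rng) == (1, 1.0)


def test_weight_conservation_at_split_nodes():
    prop = BirthDeathPropagator(**TOY)
    trees, _ = run_nsffs(prop, _toy_cfg(T_cum_target=3000.0), seed=11)
    n_split = 0
    for tree in trees:
        for node, _ in tree.walk():
            if node.children:
                kinds = {tree.nodes[c].kind for c in node.children}
                if kinds == {"split"}:
                    n_split += 1
                    child_sum = sum(tree.nodes[c].weight for c in node.children)
                    assert child_sum == pytest.approx(node.weight)
    assert n_split > 0   # branching actually happened


def test_degenerate_sampler_is_plain_simulation():
    """With unreachable interfaces no branching or pruning occurs and each
    tree is a single unbranched trajectory of weight 1."""
    prop = BirthDeathPropagator(**TOY)
    cfg = _toy_cfg(interfaces=(0.999999,), T_cum_target=400.0,
                   min_crossings=10**9)
    trees, stats = run_nsffs(prop, cfg, seed=3)
    assert stats.counts.sum() == 0 or True  # crossings may register, no action
    for tree in trees:
        assert len(tree.nodes) == 1
        assert tree.root.weight == 1.0
        assert tree.total_leaf_weight() == pytest.approx(1.0)
    samples = reweight(trees, prop.coord_names)
    assert np.allclose(samples["weight"], 1.0 / len(trees))


def test_reweight_split_weights():
    prop = BirthDeathPropagator(**TOY)
    trees, _ = run_nsffs(prop, _toy_cfg(T_cum_target=3000.0), seed=11)
    samples = reweight(trees, prop.coord_names)
    assert set(samples.columns) == {"tree_id", "branch_id", "time", "progress",
                                    "weight"}
    assert (samples["weight"] > 0).all()
    # records within one branch carry that branch's constant weight
    per_branch = samples.groupby(["tree_id", "branch_id"])["weight"].nunique()
    assert (per_branch == 1).all()


def test_toy_first_passage_unbiased_vs_direct():
    """NS-FFS estimate of P(count >= threshold by T) agrees with brute-force
    direct simulation within 3 combined standard errors."""
    hits = _kernel.bd_first_passage_count(TOY["n0"], TOY["threshold"], 20.0,
                                          TOY["birth"], TOY["death"],
                                          50000, 2024)
    P_direct = hits / 50000
    se_direct = np.sqrt(P_direct * (1 - P_direct) / 50000)
    prop = BirthDeathPropagator(**TOY)
    estimates = []
    for seed in (1, 2, 3, 4):
        trees, _ = run_nsffs(prop, _toy_cfg(), seed=seed)
        estimates.append(first_passage_probability(trees, lambda c: c[0] >= 1.0))
    P_ffs = float(np.mean(estimates))
    se_ffs = float(np.std(estimates, ddof=1) / np.sqrt(len(estimates)))
    z = (P_ffs - P_direct) / np.hypot(se_ffs, se_direct)
    assert abs(z) < 3.0, (P_ffs, P_direct, se_ffs, se_direct)


def test_enhanced_coverage_beyond_first_interface():
    """Branching produces more distinct samples past the first interface
    than the degenerate sampler at equal simulated-time budget."""
    prop = BirthDeathPropagator(**TOY)
    lam1 = _toy_cfg().interfaces[0]
    n_enh, n_deg = [], []
    for seed in range(10):
        trees, _ = run_nsffs(prop, _toy_cfg(T_cum_target=2000.0), seed=seed)
        s = reweight(trees, prop.coord_names)
        n_enh.append((s["progress"] > lam1).sum())
        trees, _ = run_nsffs(prop, _toy_cfg(T_cum_target=2000.0,
                                            min_crossings=10**9), seed=seed)
        s = reweight(trees, prop.coord_names)
        n_deg.append((s["progress"] > lam1).sum())
    assert np.mean(n_enh) > np.mean(n_deg)


def test_first_passage_counts_each_lineage_once():
    prop = BirthDeathPropagator(**TOY)
    trees, _ = run_nsffs(prop, _toy_cfg(T_cum_target=3000.0), seed=5)
    lam1 = _toy_cfg().interfaces[0]
    ev = first_passage_events(trees, lambda c: c[0] >= lam1)
    # at most one event per (tree, branch)
    assert not ev.duplicated(["tree_id", "branch_id"]).any()
    # total crossing probability cannot exceed 1
    assert 0.0 < ev["weight"].sum() <= 1.0 + 1e-9


def test_displacement_pairs_stay_within_branch():
    prop = BirthDeathPropagator(**TOY)
    trees, _ = run_nsffs(prop, _toy_cfg(T_cum_target=2000.0), seed=6)
    pairs = displacement_pairs(trees, prop.coord_names, dt=0.5)
    assert len(pairs) > 0
    assert {"progress", "d_progress", "weight"} <= set(pairs.columns)
    # displacements of the running-maximum coordinate are never negative
    assert (pairs["d_progress"] >= -1e-12).all()


def test_lattice_propagator_runs_and_is_seed_stable(small_params):
    prop = LatticePropagator(small_params, t_relax=120.0)
    cfg = SamplerConfig(interfaces=(0.9,), t_chunk=30.0, dt_measure=30.0,
                        time_bin=120.0, T_max=240.0, T_cum_target=240.0)
    trees1, _ = run_nsffs(prop, cfg, seed=9)
    trees2, _ = run_nsffs(prop, cfg, seed=9)
    s1 = reweight(trees1, prop.coord_names)
    s2 = reweight(trees2, prop.coord_names)
    assert s1.equals(s2)
    assert {"lambda_AC", "lambda_BD", "delta_AC", "delta_BD"} <= set(s1.columns)
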