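"""Forward simulation engine: stepping, pedigree, ancestry, observables."""

import math

import numpy as np
import pytest

import genident as gi
from conftest import walk_ancestors


# --- growth schedule -------------------------------------------------------

def test_growth_schedule_constant_and_geometric():
    const = gi.GrowthSchedule(100, 100, 5, "constant").sizes()
    assert (const == 100).all()
    geo = gi.GrowthSchedule(10_000, 100_000, 20, "geometric").sizes()
    assert geo[0] == 10_000 and geo[-1] == 100_000
    assert (np.diff(geo) > 0).all()
    ratios = geo[1:] / geo[:-1]
    assert np.allclose(ratios, 10 ** (1 / 20), rtol=1e-3)


@pytest.mark.parametrize("kwargs", [
    dict(n0=1, n_final=10, T=5, mode="geometric"),
    dict(n0=10, n_final=10, T=0, mode="constant"),
    dict(n0=10, n_final=20, T=5, mode="constant"),
    dict(n0=10, n_final=20, T=5, mode="linear"),
])
def test_growth_schedule_rejects_bad_inputs(kwargs):
    with pytest.raises(ValueError):
        gi.GrowthSchedule(**kwargs)


# --- single-generation stepping -------------------------------------------

def test_initial_population_composition():
    st = gi.initial_population(10, 0.2)
    assert st.n == 10 and st.x == 0.2
    assert (st.g == (st.tau == gi.TYPE1)).all()
    st.validate()


def test_next_generation_all_type2(rng):
    state = gi.initial_population(50, 0.0)
    child, _ = gi.next_generation(state, gi.MatingModel(0.5), 100, rng)
    assert (child.tau == gi.TYPE2).all() and not child.g.any()


def test_next_generation_preserves_fraction_alpha1(rng):
    state = gi.initial_population(10_000, 0.2)
    child, _ = gi.next_generation(state, gi.MatingModel(1.0), 100_000, rng)
    assert abs(child.x - 0.2) < 3 * math.sqrt(0.2 * 0.8 / 100_000)
    child.validate()


def test_next_generation_gflag_fraction_panmictic(rng):
    """Under random mating only children of two type-2 founders lack the flag:
    expected fraction p22 = (1-x)^2 = 0.64."""
    state = gi.initial_population(100_000, 0.2)
    child, _ = gi.next_generation(state, gi.MatingModel(0.0), 100_000, rng)
    frac_g0 = np.mean(~child.g)
    assert abs(frac_g0 - 0.64) < 3 * math.sqrt(0.64 * 0.36 / 100_000)


def test_next_generation_rejects_bad_size(rng):
    state = gi.initial_population(10, 0.2)
    with pytest.raises(ValueError):
        gi.next_generation(state, gi.MatingModel(0.5), 0, rng)


# --- full simulation invariants -------------------------------------------

def test_simulate_no_founders_no_spread():
    cfg = gi.ScenarioConfig(n0=500, generations=20, x0=0.0, alpha=0.5, seed=3)
    res = gi.simulate(cfg)
    assert (res.summary["F_sim"] == 0.0).all()
    assert gi.first_passage_generation(res) is None


def test_simulate_state_space_closure_and_consistency(tracked_run):
    for st in tracked_run.states:
        st.validate()
    s = tracked_run.summary
    # F_sim = 1 - (1 - x) q_sim holds by construction wherever q is defined
    defined = s["q_sim"].notna()
    lhs = s.loc[defined, "F_sim"]
    rhs = 1.0 - (1.0 - s.loc[defined, "x"]) * s.loc[defined, "q_sim"]
    assert np.allclose(lhs, rhs, atol=1e-12)


def test_gflag_descent(tracked_run):
    """Every g=False individual has two g=False parents."""
    for t, layer in enumerate(tracked_run.pedigree, start=1):
        child = tracked_run.states[t]
        parent = tracked_run.states[t - 1]
        g0 = ~child.g
        assert not parent.g[layer.parent1[g0]].any()
        assert not parent.g[layer.parent2[g0]].any()


def test_simulate_reproducible():
    cfg = gi.ScenarioConfig(n0=200, generations=6, x0=0.2, alpha=0.7, seed=11,
                            track_pedigree=True)
    a, b = gi.simulate(cfg), gi.simulate(cfg)
    assert a.summary.equals(b.summary)
    for la, lb in zip(a.pedigree, b.pedigree):
        assert (la.parent1 == lb.parent1).all()
        assert (la.parent2 == lb.parent2).all()


def test_martingale_type1_fraction():
    """The expected type-1 fraction is conserved: mean x(T) over replicates
    within three standard errors of x0."""
    xs = []
    for r in range(60):
        cfg = gi.ScenarioConfig(n0=2000, generations=10, x0=0.2, alpha=0.5,
                                seed=500 + r)
        xs.append(gi.simulate(cfg).summary["x"].iloc[-1])
    xs = np.asarray(xs)
    se = xs.std(ddof=1) / math.sqrt(len(xs))
    assert abs(xs.mean() - 0.2) < 3 * se


def test_theory_agreement_moderate_preference():
    """Simulated F(t) tracks the deterministic recursion at large n."""
    for alpha in (0.0, 0.9):
        cfg = gi.ScenarioConfig(n0=100_000, generations=20, x0=0.2,
                                alpha=alpha, seed=2)
        dev = gi.compare_theory_sim(gi.simulate(cfg),
                                    gi.theory_trajectory(0.2, alpha, 20))
        assert dev["abs_dev"].max() <= 0.01


# --- ancestry sets and oracles --------------------------------------------

def test_founder_ancestor_sets_tiny_pedigree():
    layer = gi.PedigreeLayer(parent1=np.array([0, 2]), parent2=np.array([1, 2]))
    sets = gi.founder_ancestor_sets([layer], n0=4)
    assert sets[0].to_set(0) == {0}
    assert sets[1].to_set(0) == {0, 1}
    assert sets[1].to_set(1) == {2}
    # union of overlapping parent sets deduplicates
    layer2 = gi.PedigreeLayer(parent1=np.array([0]), parent2=np.array([1]))
    sets2 = gi.founder_ancestor_sets([layer, layer2], n0=4)
    assert sets2[2].to_set(0) == {0, 1, 2}


def test_founder_ancestor_sets_index_error():
    layer = gi.PedigreeLayer(parent1=np.array([5]), parent2=np.array([0]))
    with pytest.raises(IndexError, match="layer 0"):
        gi.founder_ancestor_sets([layer], n0=4)


def test_ancestor_sets_match_recursive_walk(tracked_run):
    """Bitset forward DP equals a plain recursive pedigree walk, everywhere."""
    for t, sets in enumerate(tracked_run.ancestry):
        for i in range(sets.n):
            assert sets.to_set(i) == walk_ancestors(tracked_run.pedigree, t, i)


@pytest.mark.parametrize("seed", range(20))
def test_gflag_oracle_equivalence(seed):
    """Brute-force pedigree-walk g flags equal the incremental flags."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(8, 65))
    cfg = gi.ScenarioConfig(n0=n, generations=int(rng.integers(1, 7)),
                            x0=float(rng.uniform(0.1, 0.9)),
                            alpha=float(rng.uniform(0, 1)), seed=seed,
                            track_pedigree=True, track_ancestry=True)
    res = gi.simulate(cfg)
    oracle = gi.brute_force_gflags(res.pedigree, res.states[0].tau)
    mask = gi.AncestrySets.mask_for(
        np.flatnonzero(res.states[0].tau == gi.TYPE1), cfg.n0)
    for t, st in enumerate(res.states):
        assert (oracle[t] == st.g).all()
        assert (res.ancestry[t].intersects(mask) == st.g).all()


def test_ancestor_type1_fraction_boundaries(tracked_run):
    founders = tracked_run.states[0]
    a0 = tracked_run.ancestry[0]
    assert gi.ancestor_type1_fraction(a0, founders.tau, founders, gi.TYPE1) == 1.0
    assert gi.ancestor_type1_fraction(a0, founders.tau, founders, gi.TYPE2) == 0.0


def test_ancestor_type1_fraction_alpha1_stays_pure():
    cfg = gi.ScenarioConfig(n0=100, generations=6, x0=0.2, alpha=1.0, seed=5,
                            track_pedigree=True, track_ancestry=True)
    res = gi.simulate(cfg)
    s = res.summary
    assert (s["A1_type1"].dropna() == 1.0).all()
    assert (s["A1_type2"].dropna() == 0.0).all()


def test_ancestor_type1_fraction_missing_identity_is_nan():
    cfg = gi.ScenarioConfig(n0=50, generations=2, x0=0.0, alpha=0.5, seed=1,
                            track_pedigree=True, track_ancestry=True)
    res = gi.simulate(cfg)
    assert math.isnan(res.summary["A1_type1"].iloc[-1])


def test_pairwise_overlap_boundaries(rng):
    founders = gi.AncestrySets.founders(10)
    assert gi.pairwise_shared_ancestor_fraction(founders, 500, rng) == 0.0
    # full siblings share the identical ancestor set
    layer = gi.PedigreeLayer(parent1=np.zeros(4, dtype=int),
                             parent2=np.full(4, 1))
    sibs = gi.founder_ancestor_sets([layer], n0=10)[1]
    assert gi.pairwise_shared_ancestor_fraction(sibs, 200, rng) == 1.0


def test_pairwise_overlap_panmixia_saturates(rng):
    """Under random mating a constant population rapidly approaches complete
    shared ancestry: mean Jaccard overlap near one by generation 20."""
    cfg = gi.ScenarioConfig(n0=500, generations=20, x0=0.2, alpha=0.0, seed=9,
                            track_pedigree=True, track_ancestry=True)
    res = gi.simulate(cfg)
    overlap = gi.pairwise_shared_ancestor_fraction(res.ancestry[-1], 1000, rng)
    assert overlap > 0.99


def test_track_ancestry_founder_cap():
    with pytest.raises(gi.ConfigError, match="track_ancestry"):
        gi.ScenarioConfig(n0=30_000, n_final=30_000, generations=2, x0=0.2,
                          alpha=0.5, track_ancestry=True)
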