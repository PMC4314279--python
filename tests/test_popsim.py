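"""Step-4 contracts: founders, Mendelian enumeration against a brute-force
oracle, visitation sampling, generation stepping, conservation laws,
neutrality, and the scenario grid."""

from itertools import product

import numpy as np
import pytest

from ophrysim import (
    SimulationConfig,
    classify_genotype,
    initialize_population,
    mate,
    run_scenario_grid,
    run_simulation,
    step_generation,
)
from ophrysim.popsim import AttractionCache, PopulationState, _weighted_pairs


def uniform_cache(value=0.5):
    return AttractionCache(weights=np.full((27, 2), float(value)))


# ---------------------------------------------------------------------------
# configuration and founders

def test_config_validation():
    with pytest.raises(ValueError):
        SimulationConfig(n_init=2000, n_max=1000).validate()
    with pytest.raises(ValueError):
        SimulationConfig(mu=1.5).validate()
    with pytest.raises(ValueError):
        SimulationConfig(founder_scenario="martians").validate()
    with pytest.raises(ValueError):
        SimulationConfig(sus_regime="sometimes").validate()
    with pytest.raises(ValueError):
        SimulationConfig(pollinator_ratio=(0, 0)).validate()
    with pytest.raises(ValueError):
        SimulationConfig(visitation="telepathy").validate()
    SimulationConfig().validate()


def test_founder_scenarios():
    mix = initialize_population(SimulationConfig(founder_scenario="mix_1to1")).genotypes
    assert (mix[:500] == (2, 0, 0)).all() and (mix[500:] == (0, 2, 0)).all()

    f1 = initialize_population(SimulationConfig(founder_scenario="all_F1")).genotypes
    assert (f1 == (1, 1, 0)).all()

    sph = initialize_population(
        SimulationConfig(founder_scenario="sphegodes_plus_one_SAD5A")
    ).genotypes
    assert (sph[:, 1] == 1).sum() == 1  # exactly one heterozygous carrier
    assert (sph[:, 0] == 2).all()

    exa = initialize_population(
        SimulationConfig(founder_scenario="exaltata_plus_one_SAD2A")
    ).genotypes
    assert (exa[:, 0] == 1).sum() == 1
    assert (exa[:, 1] == 2).all()


def test_founder_sus_regimes():
    mix = initialize_population(
        SimulationConfig(founder_scenario="mix_1to1", sus_regime="fixed_in_sphegodes")
    ).genotypes
    assert (mix[:500, 2] == 2).all()  # SS in sphegodes-type founders
    assert (mix[500:, 2] == 0).all()  # ss in exaltata-type founders
    f1 = initialize_population(
        SimulationConfig(founder_scenario="all_F1", sus_regime="fixed_in_sphegodes")
    ).genotypes
    assert (f1[:, 2] == 1).all()  # Ss in F1 founders


# ---------------------------------------------------------------------------
# Mendelian enumeration

def brute_force_offspring(a, b):
    """Independent oracle: unordered allele lists per locus, Cartesian
    product of the 4 ordered transmissions per locus."""
    def alleles(count):
        return [1] * count + [0] * (2 - count)

    per_locus = []
    for locus in range(3):
        ma, mb = alleles(a[locus]), alleles(b[locus])
        per_locus.append([ma[i] + mb[j] for i in range(2) for j in range(2)])
    return sorted(product(*per_locus))


def test_mate_oracle_all_parent_pairs():
    """Every distinct (count_a, count_b) parent pattern over all three
    loci matches the brute-force enumeration."""
    counts = (0, 1, 2)
    for a in product(counts, repeat=3):
        for b in product(counts, repeat=3):
            out = mate(np.array(a, dtype=np.int8), np.array(b, dtype=np.int8))
            assert out.shape == (64, 3)
            assert sorted(map(tuple, out)) == brute_force_offspring(a, b)


def test_mate_examples():
    # homozygous pure-species cross: 64 identical F1
    out = mate(np.array([2, 0, 0]), np.array([0, 2, 0]))
    assert (out == (1, 1, 0)).all()
    # self of triple homozygote: 64 identical copies
    out = mate(np.array([2, 2, 2]), np.array([2, 2, 2]))
    assert (out == (2, 2, 2)).all()
    # het x het: 1:2:1 per locus
    out = mate(np.array([1, 1, 1]), np.array([1, 1, 1]))
    for locus in range(3):
        vals, freq = np.unique(out[:, locus], return_counts=True)
        assert list(vals) == [0, 1, 2]
        assert list(freq) == [16, 32, 16]


def test_classify_genotype():
    assert classify_genotype(np.array([2, 0, 0])) == "sphegodes_like"
    assert classify_genotype(np.array([1, 0, 2])) == "sphegodes_like"  # SUS ignored
    assert classify_genotype(np.array([0, 1, 0])) == "exaltata_like"
    assert classify_genotype(np.array([1, 1, 0])) == "F1_like"
    assert classify_genotype(np.array([0, 0, 0])) == "null"


# ---------------------------------------------------------------------------
# visitation sampling

def test_weighted_pairs_distinct_and_supported(rng):
    weights = np.array([0.0, 1.0, 0.5, 0.0, 0.25])
    first, second = _weighted_pairs(weights, 4000, rng)
    assert len(first) == 4000
    assert (first != second).all()
    chosen = np.unique(np.concatenate([first, second]))
    assert set(chosen) <= {1, 2, 4}  # zero-weight plants never chosen
    # first-draw frequencies proportional to weights (loose bound)
    freq = np.bincount(first, minlength=5) / 4000
    expected = weights / weights.sum()
    assert np.allclose(freq, expected, atol=0.04)


def test_weighted_pairs_degenerate_cases(rng):
    first, second = _weighted_pairs(np.array([1.0, 0.0]), 10, rng)
    assert len(first) == 0  # fewer than two attractive plants: no events
    first, second = _weighted_pairs(np.zeros(5), 10, rng)
    assert len(first) == 0
    first, second = _weighted_pairs(np.ones(5), 0, rng)
    assert len(first) == 0


# ---------------------------------------------------------------------------
# generation stepping

def test_step_zero_pollinators_unchanged(rng):
    cfg = SimulationConfig(founder_scenario="all_F1", n_pollinators=0, mu=0.0)
    state = initialize_population(cfg)
    before = state.genotypes.copy()
    after = step_generation(state, cfg, uniform_cache(), rng)
    assert np.array_equal(after.genotypes, before)
    assert after.generation == 1


def test_step_monomorphic_closure(rng):
    """mu=0, all ++/--/ss: mating identical homozygotes cannot create
    heterozygosity."""
    cfg = SimulationConfig(founder_scenario="mix_1to1", mu=0.0)
    state = PopulationState(0, np.tile(np.array([2, 0, 0], dtype=np.int8), (1000, 1)))
    for _ in range(5):
        state = step_generation(state, cfg, uniform_cache(), rng)
    assert (state.genotypes == (2, 0, 0)).all()


def test_step_population_cap_and_pool_size(rng):
    cfg = SimulationConfig(founder_scenario="all_F1", mu=0.0, n_pollinators=500)
    state = initialize_population(cfg)
    after = step_generation(state, cfg, uniform_cache(), rng)
    assert after.size == cfg.n_max  # 500 events x 64 = 32,000 capped at 1000
    # a tiny pool is kept whole: 1 pollinator -> exactly 64 offspring
    tiny = SimulationConfig(founder_scenario="all_F1", mu=0.0, n_pollinators=1)
    after = step_generation(initialize_population(tiny), tiny, uniform_cache(), rng)
    assert after.size == 64


def test_mutation_is_irreversible_loss(rng):
    """mu=1 removes every functional allele in one step; counts never
    increase across mutation."""
    cfg = SimulationConfig(founder_scenario="all_F1", mu=1.0, sus_regime="fixed_in_sphegodes")
    after = step_generation(initialize_population(cfg), cfg, uniform_cache(), rng)
    assert (after.genotypes == 0).all()


def test_mutation_respects_mutate_sus_switch(rng):
    # zero pollinators isolate the mutation step from mating
    cfg = SimulationConfig(
        founder_scenario="all_F1", mu=1.0, sus_regime="fixed_in_sphegodes",
        mutate_sus=False, n_pollinators=0,
    )
    after = step_generation(initialize_population(cfg), cfg, uniform_cache(), rng)
    assert (after.genotypes[:, :2] == 0).all()
    assert (after.genotypes[:, 2] == 1).all()  # S alleles spared


def test_bernoulli_mode_runs(rng):
    cfg = SimulationConfig(founder_scenario="mix_1to1", visitation="bernoulli", mu=0.0)
    after = step_generation(initialize_population(cfg), cfg, uniform_cache(0.9), rng)
    assert after.size <= cfg.n_max
    assert after.size > 0


def test_neutrality_no_systematic_trend():
    """Equal attraction to all genotypes: allele frequencies drift with no
    systematic trend (mean change ~ 0 over 50 replicates).  Class
    frequencies are NOT drift-stable here — random mating moves them to
    Hardy-Weinberg proportions — so neutrality is asserted on alleles."""
    cache = uniform_cache()
    d2, d5 = [], []
    for seed in range(50):
        cfg = SimulationConfig(founder_scenario="mix_1to1", mu=0.0, seed=seed)
        state = initialize_population(cfg)
        rng = np.random.default_rng(cfg.seed)
        start = state.genotypes.mean(axis=0) / 2.0
        for _ in range(40):
            state = step_generation(state, cfg, cache, rng)
        end = state.genotypes.mean(axis=0) / 2.0
        d2.append(end[0] - start[0])
        d5.append(end[1] - start[1])
    for changes in (np.asarray(d2), np.asarray(d5)):
        se = changes.std(ddof=1) / np.sqrt(len(changes))
        assert abs(changes.mean()) < max(4 * se, 0.02)


# ---------------------------------------------------------------------------
# trajectories and the grid

def test_run_simulation_records_and_determinism(truth_cache):
    cfg = SimulationConfig(generations=100, record_every=20, seed=42)
    a = run_simulation(cfg, truth_cache)
    b = run_simulation(cfg, truth_cache)
    assert a.class_freq.equals(b.class_freq)
    assert a.genotype_freq.equals(b.genotype_freq)
    assert list(a.class_freq.index) == [0, 20, 40, 60, 80, 100]
    assert a.genotype_freq.shape[1] == 27
    # conservation at every record
    assert np.allclose(a.class_freq.sum(axis=1), 1.0, atol=1e-12)
    assert np.allclose(a.genotype_freq.sum(axis=1), 1.0, atol=1e-12)


def test_run_simulation_zero_generations(truth_cache):
    traj = run_simulation(SimulationConfig(generations=0), truth_cache)
    assert list(traj.class_freq.index) == [0]
    assert traj.class_freq.iloc[0]["sphegodes_like"] == pytest.approx(0.5)


def test_scenario_grid_shape(truth_cache):
    cfg = SimulationConfig(generations=40, record_every=20, seed=7)
    table, trajectories = run_scenario_grid(cfg, truth_cache)
    assert len(trajectories) == 40  # 5 ratios x 4 founders x 2 sus regimes
    assert table["scenario_id"].nunique() == 40
    records = table.groupby("scenario_id")["generation"].nunique()
    assert (records == 3).all()  # generations 0, 20, 40
    sums = table.groupby(["scenario_id", "generation"])["frequency"].sum()
    assert np.allclose(sums, 1.0, atol=1e-12)
    seeds = {t.config.seed for t in trajectories.values()}
    assert len(seeds) == 40  # every scenario gets its own derived seed
    assert all(0 <= s < 2 ** 31 for s in seeds)
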