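"""Step 4 — stochastic simulation of pollinator-mediated divergence.

A population of diploid plants (three unlinked loci: SAD2, SAD5, SUS) is
pollinated each generation by a fixed pool of bees split between the two
species.  Each pollinator visits two distinct plants — chosen with
probability proportional to the plants' scaled attraction to that bee
species, clipped to [0, 1] — producing one pollination event.  Every
event yields 64 offspring: the Cartesian product, across the three loci,
of the four ordered (maternal allele x paternal allele) transmissions,
i.e. the loci segregate independently.  Generations do not overlap: the
offspring pool replaces the parents, down-sampled uniformly to the
population ceiling when it is larger; an empty pool leaves the previous
population in place.  Finally, each functional "+" allele (and each S
allele, switchable) is lost independently with the per-allele
loss-of-function mutation probability.  Mutation is irreversible.

Populations are stored as integer arrays of functional-allele counts,
shape (n, 3) with columns (sad2, sad5, sus).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from itertools import product

import numpy as np
import pandas as pd

from .alkenes import AlkeneModel, predict_alkenes
from .attraction import AttractionModel, predict_attraction
from .landscape import Genotype, enumerate_genotypes, genotype_expression, reference_genotype

__all__ = [
    "SimulationConfig",
    "PopulationState",
    "Trajectory",
    "AttractionCache",
    "build_attraction_cache",
    "initialize_population",
    "mate",
    "classify_genotype",
    "step_generation",
    "run_simulation",
    "run_scenario_grid",
]

logger = logging.getLogger(__name__)

FOUNDER_SCENARIOS = (
    "mix_1to1",
    "all_F1",
    "sphegodes_plus_one_SAD5A",
    "exaltata_plus_one_SAD2A",
)
SUS_REGIMES = ("absent", "fixed_in_sphegodes")
POLLINATOR_RATIOS = ((1, 0), (3, 1), (1, 1), (1, 3), (0, 1))
CLASS_LABELS = ("sphegodes_like", "exaltata_like", "F1_like", "null")


@dataclass(frozen=True)
class SimulationConfig:
    """Scenario configuration for one simulation run.

    ``pollinator_ratio`` is (A. nigroaenea share, C. cunicularius share);
    ``mu`` is the per-allele loss-of-function probability per generation.
    """

    n_init: int = 1000
    n_max: int = 1000
    mu: float = 1e-5
    n_pollinators: int = 500
    pollinator_ratio: tuple[int, int] = (1, 1)
    generations: int = 1000
    record_every: int = 20
    founder_scenario: str = "mix_1to1"
    sus_regime: str = "absent"
    visitation: str = "weighted"  # or "bernoulli"
    mutate_sus: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.n_init > self.n_max:
            raise ValueError("n_init must be <= n_max")
        if not (0.0 <= self.mu <= 1.0):
            raise ValueError("mu must be in [0, 1]")
        if self.founder_scenario not in FOUNDER_SCENARIOS:
            raise ValueError(f"unknown founder scenario {self.founder_scenario!r}")
        if self.sus_regime not in SUS_REGIMES:
            raise ValueError(f"unknown sus regime {self.sus_regime!r}")
        if self.visitation not in ("weighted", "bernoulli"):
            raise ValueError(f"unknown visitation mode {self.visitation!r}")
        if sum(self.pollinator_ratio) <= 0:
            raise ValueError("pollinator ratio shares must sum to a positive value")
        if self.record_every < 1 or self.generations < 0:
            raise ValueError("record_every >= 1 and generations >= 0 required")


@dataclass
class PopulationState:
    """Population at one generation: allele-count rows (sad2, sad5, sus)."""

    generation: int
    genotypes: np.ndarray  # shape (n, 3), int8

    @property
    def size(self) -> int:
        return len(self.genotypes)


@dataclass
class Trajectory:
    """Recorded genotype-class and raw-genotype frequencies over time."""

    class_freq: pd.DataFrame     # index: generation; columns: CLASS_LABELS
    genotype_freq: pd.DataFrame  # index: generation; columns: full genotype labels
    extinct: bool = False
    config: SimulationConfig | None = field(default=None, repr=False)


# ---------------------------------------------------------------------------
# attraction cache

@dataclass
class AttractionCache:
    """Scaled attraction (clipped to [0, 1]) per genotype and pollinator.

    ``weights`` has shape (27, 2): rows indexed by the genotype code
    9*sad2 + 3*sad5 + sus, columns (A. nigroaenea, C. cunicularius).
    """

    weights: np.ndarray

    def lookup(self, pop: np.ndarray) -> np.ndarray:
        codes = pop[:, 0] * 9 + pop[:, 1] * 3 + pop[:, 2]
        return self.weights[codes]


def build_attraction_cache(
    alkene_model: AlkeneModel,
    attraction_models: dict[str, AttractionModel],
    ref_expr: tuple[float, float],
) -> AttractionCache:
    """Precompute plug-in scaled attraction for all 27 genotypes.

    Uses the unperturbed coefficient estimates; attraction is scaled by
    the pure-species reference per pollinator and clipped to [0, 1] for
    use as visitation weights.
    """
    weights = np.zeros((27, 2))
    refs = {}
    for p in ("A_nigroaenea", "C_cunicularius"):
        ref_g = reference_genotype(p)
        amounts = predict_alkenes(alkene_model, *genotype_expression(ref_g, ref_expr))
        refs[p] = float(predict_attraction(attraction_models[p], amounts))
    for g in enumerate_genotypes(include_sus=True):
        code = g.sad2 * 9 + g.sad5 * 3 + g.sus
        amounts = predict_alkenes(alkene_model, *genotype_expression(g, ref_expr))
        for j, p in enumerate(("A_nigroaenea", "C_cunicularius")):
            raw = float(predict_attraction(attraction_models[p], amounts))
            weights[code, j] = min(max(raw / refs[p], 0.0), 1.0)
    return AttractionCache(weights=weights)


# ---------------------------------------------------------------------------
# founders, mating, classification

def initialize_population(config: SimulationConfig) -> PopulationState:
    """Build the founder population for the configured scenario."""
    config.validate()
    n = config.n_init
    sus_fixed = config.sus_regime == "fixed_in_sphegodes"

    if config.founder_scenario == "mix_1to1":
        n_sph = n // 2
        pop = np.zeros((n, 3), dtype=np.int8)
        pop[:n_sph] = (2, 0, 2 if sus_fixed else 0)   # O. sphegodes-like
        pop[n_sph:] = (0, 2, 0)                        # O. exaltata-like
    elif config.founder_scenario == "all_F1":
        pop = np.tile(np.array([1, 1, 1 if sus_fixed else 0], dtype=np.int8), (n, 1))
    elif config.founder_scenario == "sphegodes_plus_one_SAD5A":
        pop = np.tile(np.array([2, 0, 2 if sus_fixed else 0], dtype=np.int8), (n, 1))
        pop[0, 1] = 1  # one heterozygous carrier of the novel SAD5A allele
    elif config.founder_scenario == "exaltata_plus_one_SAD2A":
        pop = np.tile(np.array([0, 2, 0], dtype=np.int8), (n, 1))
        pop[0, 0] = 1  # one heterozygous carrier of the novel SAD2A allele
    else:  # pragma: no cover - guarded by validate()
        raise ValueError(config.founder_scenario)
    return PopulationState(generation=0, genotypes=pop)


def _transmit(count: np.ndarray, allele_index: np.ndarray) -> np.ndarray:
    """Functional-allele contribution (0/1) of one ordered transmission.

    A parent's two alleles at a locus are listed functional-first, so a
    heterozygote transmits "+" for allele index 0 and "-" for index 1.
    """
    count = np.asarray(count)
    allele_index = np.asarray(allele_index)
    return np.where(count == 2, 1, np.where(count == 0, 0, (allele_index == 0).astype(int)))


def _offspring_from_offsets(
    a: np.ndarray, b: np.ndarray, offsets: np.ndarray
) -> np.ndarray:
    """Offspring allele counts for parents ``a``/``b`` at pool offsets.

    ``offsets`` in [0, 64) index the Cartesian product of the 4 ordered
    per-locus transmissions: base-4 digits (sad2, sad5, sus from most to
    least significant), each digit = 2*maternal_allele + paternal_allele.
    """
    a = np.atleast_2d(a)
    b = np.atleast_2d(b)
    offsets = np.asarray(offsets)
    out = np.empty(offsets.shape + (3,), dtype=np.int8)
    for locus, shift in enumerate((16, 4, 1)):
        digit = (offsets // shift) % 4
        m_idx, p_idx = digit // 2, digit % 2
        out[..., locus] = _transmit(a[..., locus], m_idx) + _transmit(b[..., locus], p_idx)
    return out


def mate(parent_a, parent_b) -> np.ndarray:
    """All 64 offspring genotypes of one pollination event.

    Enumerates, for each of the three loci, the four ordered
    (maternal allele x paternal allele) transmissions and takes the
    Cartesian product (4^3 = 64).  Every offspring allele occurs in the
    contributing parent at that locus.
    """
    a = _as_counts(parent_a)
    b = _as_counts(parent_b)
    return _offspring_from_offsets(a, b, np.arange(64))


def _as_counts(g) -> np.ndarray:
    if isinstance(g, Genotype):
        return np.array([g.sad2, g.sad5, g.sus], dtype=np.int8)
    return np.asarray(g, dtype=np.int8)


def classify_genotype(g) -> str:
    """Class label from functional-allele presence (SUS ignored).

    (+ at SAD2, + at SAD5): (yes, no) -> sphegodes_like; (no, yes) ->
    exaltata_like; (yes, yes) -> F1_like; (no, no) -> null.
    """
    c = _as_counts(g)
    has2, has5 = c[0] >= 1, c[1] >= 1
    if has2 and not has5:
        return "sphegodes_like"
    if has5 and not has2:
        return "exaltata_like"
    if has2 and has5:
        return "F1_like"
    return "null"


def _class_frequencies(pop: np.ndarray) -> dict[str, float]:
    n = len(pop)
    has2 = pop[:, 0] >= 1
    has5 = pop[:, 1] >= 1
    return {
        "sphegodes_like": float((has2 & ~has5).sum() / n),
        "exaltata_like": float((~has2 & has5).sum() / n),
        "F1_like": float((has2 & has5).sum() / n),
        "null": float((~has2 & ~has5).sum() / n),
    }


# ---------------------------------------------------------------------------
# generation step

def _weighted_pairs(weights: np.ndarray, k: int, rng) -> tuple[np.ndarray, np.ndarray]:
    """Sample k pairs of distinct plants with probability proportional to
    ``weights``, without replacement within a pair (exact, vectorized)."""
    total = float(weights.sum())
    if total <= 0.0 or (weights > 0).sum() < 2 or k == 0:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    cw = np.cumsum(weights)
    u1 = rng.random(k) * total
    first = np.searchsorted(cw, u1, side="right")
    w_first = weights[first]
    left = cw[first] - w_first
    u2 = rng.random(k) * (total - w_first)
    target = np.where(u2 < left, u2, u2 + w_first)
    second = np.searchsorted(cw, target, side="right")
    return first, second


def _bernoulli_pairs(weights: np.ndarray, k: int, rng) -> tuple[np.ndarray, np.ndarray]:
    """Alternative visitation: two uniformly chosen distinct plants, the
    event accepted with probability = product of the two attractions."""
    n = len(weights)
    if n < 2 or k == 0:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    first = rng.integers(0, n, size=k)
    shift = rng.integers(1, n, size=k)
    second = (first + shift) % n
    accept = rng.random(k) < weights[first] * weights[second]
    return first[accept], second[accept]


def step_generation(
    state: PopulationState,
    config: SimulationConfig,
    cache: AttractionCache,
    rng: np.random.Generator,
) -> PopulationState:
    """Advance the population by one non-overlapping generation.

    The surviving offspring are drawn directly as uniform indices into
    the virtual (n_events x 64) pool, which is distributionally identical
    to materializing all offspring and subsampling without replacement.
    """
    pop = state.genotypes
    an_share, cc_share = config.pollinator_ratio
    n_an = int(round(config.n_pollinators * an_share / (an_share + cc_share)))
    n_cc = config.n_pollinators - n_an

    weights = cache.lookup(pop)  # (n, 2): columns (an, cc)
    pairs_fn = _weighted_pairs if config.visitation == "weighted" else _bernoulli_pairs
    mothers, fathers = [], []
    for j, k in ((0, n_an), (1, n_cc)):
        first, second = pairs_fn(weights[:, j], k, rng)
        mothers.append(first)
        fathers.append(second)
    mothers = np.concatenate(mothers)
    fathers = np.concatenate(fathers)
    n_events = len(mothers)

    if n_events == 0:
        # no pollination: previous population persists unchanged
        new_pop = pop.copy()
    else:
        pool_size = n_events * 64
        if pool_size > config.n_max:
            idx = rng.choice(pool_size, size=config.n_max, replace=False)
        else:
            idx = np.arange(pool_size)
        event = idx // 64
        offset = idx % 64
        new_pop = _offspring_from_offsets(
            pop[mothers[event]], pop[fathers[event]], offset
        )

    # irreversible loss-of-function mutation, per allele
    if config.mu > 0:
        for locus in (0, 1) + ((2,) if config.mutate_sus else ()):
            losses = rng.binomial(new_pop[:, locus].astype(np.int64), config.mu)
            new_pop[:, locus] = new_pop[:, locus] - losses.astype(np.int8)
    return PopulationState(generation=state.generation + 1, genotypes=new_pop)


def run_simulation(
    config: SimulationConfig,
    cache: AttractionCache,
) -> Trajectory:
    """Run one scenario and record frequencies every ``record_every``
    generations (including generation 0).  Deterministic given the seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    state = initialize_population(config)
    labels = [g.full_label for g in enumerate_genotypes(include_sus=True)]
    codes_order = [g.sad2 * 9 + g.sad5 * 3 + g.sus for g in enumerate_genotypes(include_sus=True)]

    class_rows, geno_rows, gens = [], [], []

    def record(st: PopulationState) -> None:
        gens.append(st.generation)
        class_rows.append(_class_frequencies(st.genotypes))
        codes = st.genotypes[:, 0] * 9 + st.genotypes[:, 1] * 3 + st.genotypes[:, 2]
        counts = np.bincount(codes, minlength=27) / len(codes)
        geno_rows.append(counts[codes_order])

    record(state)
    for gen in range(1, config.generations + 1):
        state = step_generation(state, config, cache, rng)
        if gen % 100 == 0:
            logger.info(
                "%s/%s an:cc=%s gen %d", config.founder_scenario, config.sus_regime,
                config.pollinator_ratio, gen,
            )
        if gen % config.record_every == 0:
            record(state)

    class_freq = pd.DataFrame(class_rows, index=pd.Index(gens, name="generation"))
    genotype_freq = pd.DataFrame(
        np.vstack(geno_rows), index=pd.Index(gens, name="generation"), columns=labels
    )
    return Trajectory(class_freq=class_freq, genotype_freq=genotype_freq, config=config)


def run_scenario_grid(
    base_config: SimulationConfig,
    cache: AttractionCache,
) -> tuple[pd.DataFrame, dict[str, Trajectory]]:
    """Sweep 5 pollinator ratios x 4 founder scenarios x 2 SUS regimes.

    Each of the 40 scenarios gets its own seed derived from the base
    config's seed.  Returns a tidy long table (scenario_id, founder,
    sus_regime, an_share, cc_share, generation, class, frequency) and the
    trajectories keyed by scenario id.
    """
    seeds = np.random.SeedSequence(base_config.seed).spawn(
        len(POLLINATOR_RATIOS) * len(FOUNDER_SCENARIOS) * len(SUS_REGIMES)
    )
    rows = []
    trajectories: dict[str, Trajectory] = {}
    i = 0
    for founder in FOUNDER_SCENARIOS:
        for sus_regime in SUS_REGIMES:
            for ratio in POLLINATOR_RATIOS:
                cfg = replace(
                    base_config,
                    founder_scenario=founder,
                    sus_regime=sus_regime,
                    pollinator_ratio=ratio,
                    seed=int(seeds[i].generate_state(1)[0] % (2 ** 31)),
                )
                i += 1
                scenario_id = f"{founder}|{sus_regime}|an{ratio[0]}:cc{ratio[1]}"
                traj = run_simulation(cfg, cache)
                trajectories[scenario_id] = traj
                long = traj.class_freq.reset_index().melt(
                    id_vars="generation", var_name="class", value_name="frequency"
                )
                long.insert(0, "scenario_id", scenario_id)
                long.insert(1, "founder", founder)
                long.insert(2, "sus_regime", sus_regime)
                long.insert(3, "an_share", ratio[0])
                long.insert(4, "cc_share", ratio[1])
                rows.append(long)
    return pd.concat(rows, ignore_index=True), trajectories
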