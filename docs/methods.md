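# Methods

This document specifies the statistical and simulation models implemented
in `ophrysim`, the conventions chosen where the biology leaves freedom,
and the known limitations.

## Notation

Two desaturase loci, **SAD2** and **SAD5**, each carry 0–2 functional
(“A”) alleles; a third locus carries 0–2 copies of the dominant
suppressor **SUS**, which silences SAD5. Genotypes are written
`SAD2/SAD5` with `+` for a functional allele, e.g. `+-/--` (one SAD2A,
no SAD5A). Three alkene classes are tracked: 7-, 9- and 12-alkenes
(double-bond position). Pollinators: *C. cunicularius* (cc) and
*A. nigroaenea* (an).

## Step 1 — expression → alkene amounts (OLS)

For each alkene class *c* the model is

    ln(amount_c + 1) = β₀ + β₂·√E₂ + β₅·√E₅ + β₂₅·√E₂·√E₅ + ε

where E₂, E₅ are SAD2A/SAD5A expression levels. Terms are selected by
AIC over all 2³ = 8 subsets of {√E₂, √E₅, interaction}; the intercept is
always kept. Fitting uses `statsmodels.OLS`; 95% CIs are Wald intervals.
`fit_alkene_models` requires ≥ 5 rows and at least as many rows as
parameters; a constant response column yields a warned intercept-only fit
with R² defined as 0. Predictions back-transform as
`max(exp(latent) − 1, 0)`.

Two selection engines share a common core (`ophrysim.selection`):

- `exhaustive_aic` — fits every admissible subset, returns the global
  AIC minimum (ties → smaller model, then candidate order). This is the
  reference engine and the default.
- `stepwise_aic` — classical bidirectional stepwise search. The default
  `start="both"` runs greedy descents from the full and the empty model
  and keeps the lower-AIC endpoint: a single descent can stall in a
  local minimum when collinear terms mask each other (dropping either of
  two terms raises AIC although dropping both lowers it). On every
  candidate space in this package, the two-start variant agrees with the
  exhaustive oracle; the test suite asserts this.

## Step 2 — alkenes → pollinator visits (Poisson GLM)

Behavioural choice trials come in four groups (sphegodes scent,
sphegodes + added 7-alkenes, exaltata scent, exaltata + added 9/12-
alkenes). Because individual trials pair a scent sample with a visit
count only loosely, the scent↔count pairing is permuted **within each
group** (`permute_within_groups`, default 300 rounds, both pollinators'
counts travel together), and the pooled expanded table is fitted by a
Poisson log-link GLM:

    ln E[visits] = γ₀ + Σ_c (γ_c·a_c + γ_cc·a_c²)

with AIC selection over the 27 subsets respecting the hierarchy “a
quadratic term requires its linear term”. Permutation pooling reuses
each observation `n_perm` times, so naive standard errors are too small
by roughly √n_perm; `fit_attraction_glm(..., ci_inflation=...)` widens
the reported CIs by a caller-chosen factor when the expanded table is
used for inference. Pseudo-R² is 1 − deviance/null-deviance.

## Step 3 — genotype landscape

`genotype_expression` maps allele dosage to expression additively:
half the homozygote reference expression per functional allele, with any
SUS copy forcing SAD5 expression to 0 (dominant silencing). The
reference expression defaults to the fixture's species means
(E₂, E₅) = (4.0, 9.0).

For each genotype, `predict_genotype_landscape` draws `n_perturb`
(default 500) coefficient vectors uniformly and independently within each
coefficient's 95% CI, pushes them through the step-1 and step-2 models,
and reports per-genotype means (and SDs / 2.5–97.5% quantiles for
attraction). Attraction is **scaled per pollinator** by its own pure
host genotype — `--/++` for *C. cunicularius*, `++/--` for
*A. nigroaenea* — so 1.0 means “as attractive as the plant this
pollinator actually visits”. Scaled values are not clipped in the
landscape table; the simulator clips to [0, 1] when converting to
visitation weights.

`net_allele_gain_effect(landscape, locus, pollinator)` averages, over
the 6 ordered dosage backgrounds, the change in scaled attraction from
gaining one functional allele at the focal locus. On the fixture truth
models this gives +0.209 for SAD5→*C. cunicularius* and −0.0015 for
SAD2→*A. nigroaenea*: the landscape is asymmetric, and no genotype
exceeds 0.5 for both pollinators simultaneously.

`truth_models(params)` wraps the generator's own coefficients as models
with degenerate point CIs, so the landscape's structural properties can
be checked deterministically through the same code path used for fitted
models.

## Step 4 — population simulation

Discrete non-overlapping generations, default configuration: 1000
plants, 500 pollinators, 1000 generations.

1. **Attraction weights.** Each plant's genotype is looked up in a
   27-entry cache of scaled attraction (means of the landscape
   computation), clipped to [0, 1].
2. **Visitation.** Each pollinator (an individual of one species, with
   the species mix set by `pollinator_ratio`) performs one mating event:
   a *distinct* pair of plants drawn proportionally to that species'
   weights (exact without-replacement sampling). Events with fewer than
   two attractive plants are dropped. A `bernoulli` mode instead accepts
   each plant with probability equal to its weight and pairs the
   acceptances.
3. **Offspring.** Each event enumerates all 4×4×4 = 64 ordered
   transmission combinations across the three loci (`mate`), exactly the
   Mendelian distribution. The next generation is drawn uniformly from
   the virtual pool of (events × 64) offspring, capped at `n_max`; the
   pool is never materialized.
4. **Mutation.** Each functional allele is independently lost with
   probability μ = 10⁻⁵ per generation; loss is irreversible. SUS
   alleles mutate likewise unless `mutate_sus=False`.

Founder scenarios: `mix_1to1` (500 `++/--` + 500 `--/++`), `all_F1`
(all `+-/+-`), `sphegodes_plus_one_SAD5A`, `exaltata_plus_one_SAD2A`.
SUS regimes: `absent`, or `fixed_in_sphegodes` (SS in sphegodes-type
founders, ss in exaltata-type, Ss in F1). `run_scenario_grid` sweeps
5 pollinator ratios × 4 founders × 2 SUS regimes = 40 scenarios with
independently derived seeds.

Emergent behaviour (tested): hybrid-founded populations collapse out of
the F1 class toward the parental corners; one SAD5A allele under pure
*C. cunicularius* pollination can sweep a sphegodes-like population to
an exaltata-like majority; a fixed SUS suppressor blocks that sweep; the
mirror-image SAD2A introduction under *A. nigroaenea* never produces a
sphegodes-like majority. Under uniform attraction, allele frequencies
are drift-neutral (class frequencies are not — random mating moves them
to Hardy–Weinberg proportions).

## Synthetic fixture

`paper_like_fixture()` commits one ground-truth parameter set chosen to
satisfy the calibration targets: per-class R² mostly in [0.3, 0.85] at
n = 30 per species; a concave (interior-maximum) 7-alkene response for
*C. cunicularius*; essentially flat, very slightly negative 9/12-alkene
effects for *A. nigroaenea* (its attraction is carried by the background
blend, so gaining SAD2 never pays under that pollinator alone); no
dual-attractive genotype; net allele-gain effects with
g(SAD5→cc) ≥ 3·g(SAD2→an). Generators use `numpy.random.default_rng`;
all randomness is seed-derived (`SeedSequence` spawning, seeds < 2³¹).

## Limitations

- **Permutation inference.** Pooled-permutation GLM fitting reuses data;
  reported CIs on permuted tables understate uncertainty unless
  `ci_inflation` is applied. Parameter-recovery checks therefore run on
  unpermuted trials.
- **AIC is not selection-consistent.** A spurious term survives with
  probability ≈ P(χ²₁ > 2) ≈ 0.157 at any sample size, so exact
  selected-set equality is only asserted where the design guarantees it;
  tests otherwise check that generating terms are recovered and that
  extras are rare/near-zero.
- **Fitted-model landscapes inherit CI width.** Under the fixture's
  collinearity between √E₂ and √E₅ within species, CI-uniform
  perturbation can produce wide attraction spreads for fitted models;
  deterministic structural checks use `truth_models` point CIs.
- **Demography is deliberately minimal.** No spatial structure, no seed
  bank, no selfing, a hard population cap, and mutation only as
  irreversible loss.
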