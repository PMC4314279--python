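# ophrysim

Modeling pollinator-mediated floral divergence at the *Ophrys* desaturase
loci **SAD2** and **SAD5**.

Sexually deceptive *Ophrys* orchids attract their pollinators with alkene
blends: *O. sphegodes* produces 9-/12-alkenes (via SAD2) and is visited by
the bee *Andrena nigroaenea*; *O. exaltata* produces 7-alkenes (via SAD5)
and is visited by *Colletes cunicularius*. `ophrysim` implements that causal
chain as four linked, individually testable model steps:

1. **Scent production** (`ophrysim.alkenes`) — OLS regressions of
   ln(alkene amount + 1) on √-transformed desaturase expression, with
   AIC term selection (exhaustive search over the 8 candidate subsets;
   a bidirectional stepwise engine is provided and agrees with it).
2. **Pollinator attraction** (`ophrysim.attraction`) — within-group
   permutation of scent↔visit-count pairings, then Poisson log-link GLMs
   of visit counts on linear + quadratic alkene terms, AIC-selected over
   the 27 hierarchy-respecting subsets (a quadratic term requires its
   linear term).
3. **Genotype landscape** (`ophrysim.landscape`) — maps the 9 SAD2×SAD5
   genotypes (27 with the dominant **SUS** suppressor, which silences
   SAD5) to predicted blends and to attraction of both pollinators,
   scaled per pollinator so its own host genotype reads 1.0; uncertainty
   via uniform perturbation within the models' 95% CIs.
4. **Population simulation** (`ophrysim.popsim`) — discrete generations
   of 1000 plants and 500 pollinator visitation events; each event mates
   a weighted distinct pair and enumerates all 64 Mendelian offspring
   combinations across the three loci; offspring are downsampled to the
   population cap; functional alleles suffer irreversible loss mutation
   (μ = 10⁻⁵).

A synthetic-data module (`ophrysim.synthetic`) carries a committed
ground-truth parameter set (`paper_like_fixture()`) so every step can be
tested against known coefficients, and `ophrysim.pipeline` + a CLI glue
the steps together.

## Quick start (library)

```python
from ophrysim import (
    fit_alkene_models, fit_attraction_glm, generate_choice_trials,
    generate_expression_scent, paper_like_fixture, permute_within_groups,
)

params = paper_like_fixture()
expression = generate_expression_scent(params, n_per_species=50, seed=11)
alkenes = fit_alkene_models(expression)

trials = generate_choice_trials(params, n_trials_per_group=50, seed=12)
expanded = permute_within_groups(trials, n_perm=300, seed=13)
cc = fit_attraction_glm(expanded, "cc")
```

Running `python examples/01_fit_models.py` prints, on the committed
fixture:

```
alkene class  7: R^2 = 0.547  terms: sqrt_sad5
alkene class  9: R^2 = 0.527  terms: sqrt_sad2, sqrt_sad5
alkene class 12: R^2 = 0.331  terms: sqrt_sad2
...
C. cunicularius: ... expected visits: sphegodes blend 0.031, exaltata blend 13.031
A. nigroaenea:   ... expected visits: sphegodes blend 16.386, exaltata blend 0.548
```

and `examples/02_genotype_landscape.py` reproduces the two headline
landscape properties: **no genotype is attractive to both pollinators**,
and the fitness effect of gaining an allele is strongly asymmetric
(+SAD5A raises *C. cunicularius* attraction by ≈ 0.21 of the host-plant
reference, while +SAD2A changes *A. nigroaenea* attraction by ≈ 0).
`examples/03_divergence_simulation.py` shows the population-level
consequence: a single SAD5A allele introduced into a sphegodes-like
population with *C. cunicularius* present sweeps to an exaltata-like
majority, a fixed SUS suppressor blocks the sweep, and the mirror-image
SAD2A introduction under *A. nigroaenea* never takes over.

## Quick start (CLI)

```bash
# full pipeline: synthetic data -> fits -> landscapes -> 40-scenario grid
ophrysim pipeline --seed 0 --out-dir runs/demo

# or step by step
ophrysim simdata --seed 0 --out-dir runs/data
ophrysim fit-alkenes --in runs/data/expression_scent.csv --out runs/alkenes.json
ophrysim fit-attraction --in runs/data/choice_trials.csv --pollinator cc \
    --n-perm 300 --seed 1 --out runs/attraction_cc.json
ophrysim fit-attraction --in runs/data/choice_trials.csv --pollinator an \
    --n-perm 300 --seed 2 --out runs/attraction_an.json
ophrysim landscape --alkene-model runs/alkenes.json \
    --attraction-cc runs/attraction_cc.json --attraction-an runs/attraction_an.json \
    --sus present --out runs/landscape.csv
ophrysim simulate --config sim.yaml --alkene-model runs/alkenes.json \
    --attraction-cc runs/attraction_cc.json --attraction-an runs/attraction_an.json \
    --out-dir runs/sims
```

`ophrysim pipeline` writes a `manifest.json` with SHA-256 checksums of
every output; all commands are deterministic given `--seed`.

## Testing and acceptance

```bash
pytest -q                      # full suite
python scripts/acceptance.py --seed 0 --out acceptance.json
```

The acceptance script recomputes the headline quantities (genotype
enumeration counts, the 64-offspring Mendelian oracle, OLS/GLM 95% CI
coverage over 100 seeds, stepwise/exhaustive agreement, the landscape
postconditions, divergence-dynamics replicate fractions, conservation
checks) and writes them as JSON `{"id": {"value": ..., "n": ...}}`.

## Layout

- `src/ophrysim/` — library (synthetic, alkenes, attraction, selection,
  landscape, popsim, io, pipeline, cli)
- `tests/` — pytest suite, including `tests/test_acceptance.py`
- `examples/` — narrative walkthroughs of the three modeling stages
- `scripts/acceptance.py` — headline-quantity report
- `docs/methods.md` — model equations, design decisions, limitations
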