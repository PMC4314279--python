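"""Fit the scent-production and pollinator-attraction models.

Walks the first two modeling steps on synthetic data:

1. generate an expression/scent table and a behavioural choice-trial
   table from the committed parameter set;
2. regress ln(alkene amount + 1) on sqrt-transformed desaturase
   expression, selecting terms by exhaustive AIC search;
3. expand the choice trials by within-group permutation of the
   scent <-> visit-count pairing and fit Poisson GLMs of visit counts
   on alkene amounts for each pollinator.

Run: python examples/01_fit_models.py
"""

from ophrysim import (
    fit_alkene_models,
    fit_attraction_glm,
    generate_choice_trials,
    generate_expression_scent,
    paper_like_fixture,
    permute_within_groups,
    predict_alkenes,
    predict_attraction,
)

params = paper_like_fixture()

# --- step 1: expression -> alkene regressions ------------------------------
expression = generate_expression_scent(params, n_per_species=50, seed=11)
print(f"expression/scent table: {len(expression)} plants")
print(expression.head(3).to_string(index=False), "\n")

alkene_model = fit_alkene_models(expression, selection="exhaustive")
for c, fit in alkene_model.classes.items():
    terms = ", ".join(fit.terms) or "(intercept only)"
    print(f"alkene class {c:>2}: R^2 = {fit.r_squared:.3f}  terms: {terms}")

# predicted scent blend for a sphegodes-like expression profile
blend = predict_alkenes(alkene_model, sad2a_expr=4.0, sad5a_expr=0.1)
print(f"\npredicted blend at (SAD2A=4.0, SAD5A=0.1): "
      f"7-enes {blend[0]:.1f}, 9-enes {blend[1]:.1f}, 12-enes {blend[2]:.1f}\n")

# --- step 2: alkenes -> pollinator visits ----------------------------------
trials = generate_choice_trials(params, n_trials_per_group=50, seed=12)
expanded = permute_within_groups(trials, n_perm=300, seed=13)
print(f"choice trials: {len(trials)} rows expanded to {len(expanded)} "
      f"permuted rows")

for pollinator, code in (("C. cunicularius", "cc"), ("A. nigroaenea", "an")):
    model = fit_attraction_glm(expanded, code)
    terms = ", ".join(model.terms) or "(intercept only)"
    print(f"{pollinator}: pseudo-R^2 = {model.pseudo_r_squared:.3f}  "
          f"terms: {terms}")
    # attraction of the two pure-species prototype blends
    sph = predict_attraction(model, params.group_prototypes["sphegodes_scent"])
    exa = predict_attraction(model, params.group_prototypes["exaltata_scent"])
    print(f"  expected visits: sphegodes blend {float(sph):.3f}, "
          f"exaltata blend {float(exa):.3f}")
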