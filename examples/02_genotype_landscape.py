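"""Build the genotype attraction landscape.

Takes fitted (here: ground-truth) alkene and attraction models and maps
every SAD2/SAD5 genotype — optionally crossed with the dominant SUS
suppressor — to predicted alkene amounts and scaled attraction of the
two pollinators. Attraction is scaled per pollinator so that its own
pure-species host genotype reads 1.0.

Run: python examples/02_genotype_landscape.py
"""

from ophrysim import (
    enumerate_genotypes,
    net_allele_gain_effect,
    paper_like_fixture,
    predict_genotype_landscape,
    truth_models,
)

params = paper_like_fixture()
alkene_model, attraction_models = truth_models(params)

# homozygote reference expression: the fixture's species means
REF_EXPR = (4.0, 9.0)

# --- 9-genotype landscape (no suppressor) -----------------------------------
nine = predict_genotype_landscape(
    enumerate_genotypes(include_sus=False),
    alkene_model,
    attraction_models,
    ref_expr=REF_EXPR,
    n_perturb=500,
    seed=0,
)
cols = ["genotype", "alkene_7_mean", "alkene_9_mean", "alkene_12_mean",
        "attr_cc_mean", "attr_an_mean"]
print("9-genotype landscape (means over 500 CI perturbations):")
print(nine[cols].round(3).to_string(index=False))

dual = ((nine["attr_cc_mean"] > 0.5) & (nine["attr_an_mean"] > 0.5)).sum()
print(f"\ngenotypes attractive (>0.5) to BOTH pollinators: {dual}")

# net effect of gaining one functional allele, averaged over backgrounds
g5 = net_allele_gain_effect(nine, locus="SAD5", pollinator="C_cunicularius")
g2 = net_allele_gain_effect(nine, locus="SAD2", pollinator="A_nigroaenea")
print(f"net gain effect: +SAD5A on C. cunicularius attraction = {g5:+.4f}")
print(f"                 +SAD2A on A. nigroaenea attraction   = {g2:+.4f}")
print("-> the landscape is asymmetric: gaining SAD5 opens the new niche,"
      "\n   gaining SAD2 does nothing for the old one.\n")

# --- 27-genotype landscape (with the dominant SUS suppressor) ---------------
full = predict_genotype_landscape(
    enumerate_genotypes(include_sus=True),
    alkene_model,
    attraction_models,
    ref_expr=REF_EXPR,
    n_perturb=500,
    seed=0,
)
carriers = full[full["sus_count"] > 0]
print(f"27-genotype landscape: {len(full)} rows, "
      f"{len(carriers)} SUS-carrier genotypes")
silenced = full[(full["sad5"] == 2) & (full["sad2"] == 2)]
print("SAD2/SAD5 double homozygote with 0/1/2 SUS alleles "
      "(dominant SUS silences SAD5, erasing the 7-alkenes):")
print(silenced[["genotype", "sus_count", "alkene_7_mean", "alkene_9_mean",
                "attr_cc_mean", "attr_an_mean"]].round(3).to_string(index=False))
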