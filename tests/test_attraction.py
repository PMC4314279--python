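"""Step-2 GLM contracts: permutation invariants, term selection with the
quadratic-implies-linear hierarchy, known-truth recovery, prediction."""

import numpy as np
import pandas as pd
import pytest

from ophrysim import (
    fit_attraction_glm,
    generate_choice_trials,
    permute_within_groups,
    predict_attraction,
)
from ophrysim.attraction import AttractionModel
from ophrysim.synthetic import CHOICE_GROUPS


def test_permutation_row_count_and_multisets(choice_df):
    n_perm = 20
    out = permute_within_groups(choice_df, n_perm=n_perm, seed=3)
    assert len(out) == n_perm * len(choice_df)
    assert "perm_round" in out.columns
    for group in CHOICE_GROUPS:
        orig = choice_df[choice_df["group"] == group]
        base_cc = sorted(orig["visits_cc"])
        base_an = sorted(orig["visits_an"])
        base_scent = sorted(map(tuple, orig[["alkene_7", "alkene_9", "alkene_12"]].to_numpy()))
        for r in range(n_perm):
            block = out[(out["group"] == group) & (out["perm_round"] == r)]
            assert sorted(block["visits_cc"]) == base_cc
            assert sorted(block["visits_an"]) == base_an
            assert sorted(map(tuple, block[["alkene_7", "alkene_9", "alkene_12"]].to_numpy())) == base_scent


def test_permutation_keeps_trial_count_pairs_together(choice_df):
    """The two pollinators' counts were recorded in the same trial, so
    they must travel together through the permutation."""
    out = permute_within_groups(choice_df, n_perm=10, seed=5)
    orig_pairs = set(map(tuple, choice_df[["group", "visits_cc", "visits_an"]].itertuples(index=False)))
    perm_pairs = set(map(tuple, out[["group", "visits_cc", "visits_an"]].itertuples(index=False)))
    assert perm_pairs == orig_pairs


def test_permutation_determinism_and_single_row_group(choice_df):
    a = permute_within_groups(choice_df, n_perm=5, seed=9)
    b = permute_within_groups(choice_df, n_perm=5, seed=9)
    pd.testing.assert_frame_equal(a, b)

    single = choice_df.groupby("group", sort=False).head(1).reset_index(drop=True)
    out = permute_within_groups(single, n_perm=7, seed=0)
    assert len(out) == 7 * 4
    # with one row per group, every round is the identical pairing
    for group in CHOICE_GROUPS:
        block = out[out["group"] == group]
        assert block["visits_cc"].nunique() == 1


def test_permutation_validation(choice_df):
    with pytest.raises(ValueError, match="n_perm"):
        permute_within_groups(choice_df, n_perm=0)
    missing = choice_df[choice_df["group"] != "sphegodes_plus7"]
    with pytest.raises(ValueError, match="sphegodes_plus7"):
        permute_within_groups(missing, n_perm=2)
    renamed = choice_df.copy()
    renamed.loc[0, "group"] = "mystery_blend"
    with pytest.raises(ValueError, match="mystery_blend"):
        permute_within_groups(renamed, n_perm=2)


def _trials_from_log_mean(rng, n, fn):
    """Choice-type table with visits_cc ~ Poisson(exp(fn(a7, a9, a12)))."""
    a = rng.uniform(0, 30, size=(n, 3))
    mu = np.exp(fn(a[:, 0], a[:, 1], a[:, 2]))
    return pd.DataFrame(
        {
            "group": np.resize(list(CHOICE_GROUPS), n),
            "alkene_7": a[:, 0],
            "alkene_9": a[:, 1],
            "alkene_12": a[:, 2],
            "visits_cc": rng.poisson(mu),
            "visits_an": rng.poisson(1.0, size=n),
        }
    )


def test_glm_recovers_known_linear_truth(rng):
    """Counts generated from log-mean 0.5 + 0.1*a7 select exactly that
    term and bracket the slope."""
    trials = _trials_from_log_mean(rng, 2000, lambda a7, a9, a12: 0.5 + 0.1 * a7)
    model = fit_attraction_glm(trials, "cc")
    # AIC is not selection-consistent, so spurious small terms may ride
    # along; the generating term must be selected and recovered.
    assert "alkene_7" in model.terms
    lo, hi = model.ci["alkene_7"]
    assert lo <= 0.1 <= hi
    assert model.coef["alkene_7"] == pytest.approx(0.1, abs=0.01)


def test_glm_constant_counts_intercept_only():
    trials = pd.DataFrame(
        {
            "group": np.resize(list(CHOICE_GROUPS), 40),
            "alkene_7": np.linspace(0, 20, 40),
            "alkene_9": np.linspace(5, 10, 40),
            "alkene_12": np.linspace(1, 3, 40),
            "visits_cc": 4,
            "visits_an": 4,
        }
    )
    model = fit_attraction_glm(trials, "cc")
    assert model.terms == ()
    assert model.coef["intercept"] == pytest.approx(np.log(4.0))
    assert model.pseudo_r_squared == 0.0


def test_glm_hierarchy_never_violated(choice_df):
    expanded = permute_within_groups(choice_df, n_perm=30, seed=2)
    for pollinator in ("cc", "an"):
        model = fit_attraction_glm(expanded, pollinator)
        for quad, lin in (("alkene_7_sq", "alkene_7"), ("alkene_9_sq", "alkene_9"), ("alkene_12_sq", "alkene_12")):
            if quad in model.terms:
                assert lin in model.terms


def test_glm_stepwise_equals_exhaustive(choice_df, rng):
    expanded = permute_within_groups(choice_df, n_perm=10, seed=8)
    for pollinator in ("cc", "an"):
        a = fit_attraction_glm(expanded, pollinator, selection="exhaustive")
        b = fit_attraction_glm(expanded, pollinator, selection="stepwise")
        assert a.terms == b.terms
    trials = _trials_from_log_mean(rng, 500, lambda a7, a9, a12: 0.2 + 0.08 * a7 - 0.001 * a7 ** 2)
    assert (
        fit_attraction_glm(trials, "cc", selection="exhaustive").terms
        == fit_attraction_glm(trials, "cc", selection="stepwise").terms
    )


def test_glm_validation(choice_df):
    with pytest.raises(ValueError, match="pollinator"):
        fit_attraction_glm(choice_df, "bee")
    bad = choice_df.copy()
    bad.loc[0, "visits_cc"] = -1
    with pytest.raises(ValueError):
        fit_attraction_glm(bad, "cc")


def test_glm_ci_inflation_widens(choice_df):
    expanded = permute_within_groups(choice_df, n_perm=10, seed=8)
    base = fit_attraction_glm(expanded, "cc")
    wide = fit_attraction_glm(expanded, "cc", ci_inflation=np.sqrt(10))
    assert wide.terms == base.terms
    for name in base.ci:
        w0 = base.ci[name][1] - base.ci[name][0]
        w1 = wide.ci[name][1] - wide.ci[name][0]
        assert w1 == pytest.approx(w0 * np.sqrt(10), rel=1e-9)


def test_predict_attraction_contracts(truth_attraction):
    cc = truth_attraction["C_cunicularius"]
    # strictly positive, finite
    vals = predict_attraction(cc, np.array([[0.0, 0.0, 0.0], [30.0, 5.0, 2.0]]))
    assert (vals > 0).all() and np.isfinite(vals).all()
    # intercept-only with intercept 0 predicts exactly 1
    m = AttractionModel(
        pollinator="C_cunicularius", terms=(), coef={"intercept": 0.0},
        ci={"intercept": (0.0, 0.0)}, pseudo_r_squared=0.0, n_fit_rows=0,
    )
    assert predict_attraction(m, [3.0, 4.0, 5.0]) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        predict_attraction(
            AttractionModel("cc", (), {}, {}, 0.0, 0), [0, 0, 0]
        )


def test_predict_attraction_interior_maximum(truth_attraction):
    """Concave log-parabola in alkene_7 has an interior maximum."""
    cc = truth_attraction["C_cunicularius"]
    a7 = np.linspace(0, 120, 200)
    amounts = np.column_stack([a7, np.full_like(a7, 5.0), np.full_like(a7, 5.0)])
    vals = np.asarray(predict_attraction(cc, amounts))
    peak = vals.argmax()
    assert 0 < peak < len(a7) - 1


def test_fixture_marginal_effects_at_exaltata_point(params, choice_df):
    """Fitted C. cunicularius model: positive marginal effect of 7-alkenes
    and negative of 9+12 at the exaltata prototype blend."""
    expanded = permute_within_groups(choice_df, n_perm=30, seed=4)
    model = fit_attraction_glm(expanded, "cc")
    proto = np.asarray(params.group_prototypes["exaltata_scent"])
    eps = 1.0
    base = float(predict_attraction(model, proto))
    up7 = float(predict_attraction(model, proto + [eps, 0, 0]))
    up9_12 = float(predict_attraction(model, proto + [0, eps, eps]))
    assert up7 > base
    assert up9_12 < base


def test_model_round_trip(choice_df):
    expanded = permute_within_groups(choice_df, n_perm=5, seed=1)
    cc = fit_attraction_glm(expanded, "cc")
    clone = AttractionModel.from_dict(cc.to_dict())
    assert clone == cc
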