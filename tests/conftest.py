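"""Shared fixtures: the committed parameter set, one synthetic data set,
fitted models and the deterministic ground-truth landscape machinery.

Expensive objects are session-scoped; tests must not mutate them.
"""

from __future__ import annotations

import numpy as np
import pytest

from ophrysim import (
    build_attraction_cache,
    enumerate_genotypes,
    fit_alkene_models,
    generate_choice_trials,
    generate_expression_scent,
    paper_like_fixture,
    predict_genotype_landscape,
    truth_models,
)

#: homozygote reference expression matching the fixture's species means
#: (sqrt-scale 2.0 and 3.0 -> expression 4.0 and 9.0)
REF_EXPR = (4.0, 9.0)


@pytest.fixture(scope="session")
def params():
    return paper_like_fixture()


@pytest.fixture(scope="session")
def expression_df(params):
    return generate_expression_scent(params, seed=11)


@pytest.fixture(scope="session")
def choice_df(params):
    return generate_choice_trials(params, n_trials_per_group=50, seed=12)


@pytest.fixture(scope="session")
def alkene_model(expression_df):
    return fit_alkene_models(expression_df)


@pytest.fixture(scope="session")
def truth_model_pair(params):
    return truth_models(params)


@pytest.fixture(scope="session")
def truth_alkene(truth_model_pair):
    return truth_model_pair[0]


@pytest.fixture(scope="session")
def truth_attraction(truth_model_pair):
    return truth_model_pair[1]


@pytest.fixture(scope="session")
def truth_landscape9(truth_alkene, truth_attraction):
    # point CIs make every perturbation round identical: n_perturb=1 is exact
    return predict_genotype_landscape(
        enumerate_genotypes(include_sus=False),
        truth_alkene,
        truth_attraction,
        REF_EXPR,
        n_perturb=1,
        seed=0,
    )


@pytest.fixture(scope="session")
def truth_landscape27(truth_alkene, truth_attraction):
    return predict_genotype_landscape(
        enumerate_genotypes(include_sus=True),
        truth_alkene,
        truth_attraction,
        REF_EXPR,
        n_perturb=1,
        seed=0,
    )


@pytest.fixture(scope="session")
def truth_cache(truth_alkene, truth_attraction):
    return build_attraction_cache(truth_alkene, truth_attraction, REF_EXPR)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
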