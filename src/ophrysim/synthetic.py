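"""Synthetic expression/scent and pollinator-choice data generators.

The generators emulate the two data sets the modeling pipeline consumes:

* per-individual allelic expression of the functional desaturase alleles
  *SAD2A* and *SAD5A* together with absolute amounts of 7-, 9- and
  12-alkenes, for two species clusters (*Ophrys sphegodes*, high SAD2A /
  no SAD5A, and *O. exaltata*, the reverse);
* behavioral choice trials in which scent blends from four treatment
  groups are presented and approaches by the two pollinator bees
  (*Colletes cunicularius*, *Andrena nigroaenea*) are counted.

Expression is drawn on the square-root scale from a normal truncated at
zero (a species whose mean is exactly zero carries no functional allele
and expresses exactly zero).  Alkene amounts are produced from a
log-linear model: ``ln(amount + 1)`` is a linear function of
``sqrt(expression)`` terms plus Gaussian residual noise; the latent value
is clamped at zero before back-transforming so amounts are nonnegative
and equal ``exp(latent) - 1`` exactly.  Visit counts are Poisson with a
log-quadratic dependence on the three alkene amounts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

ALKENE_CLASSES = ("7", "9", "12")
ALKENE_COLUMNS = ("alkene_7", "alkene_9", "alkene_12")
SPECIES = ("sphegodes", "exaltata")
CHOICE_GROUPS = (
    "sphegodes_scent",
    "sphegodes_plus7",
    "exaltata_scent",
    "exaltata_plus9_12",
)
POLLINATORS = ("C_cunicularius", "A_nigroaenea")

#: candidate regressor names on the transformed scales (step-1 models)
ALKENE_TERMS = ("sqrt_sad2", "sqrt_sad5", "sqrt_sad2:sqrt_sad5")
#: candidate regressor names for the attraction GLMs (step-2 models)
ATTRACTION_TERMS = (
    "alkene_7",
    "alkene_9",
    "alkene_12",
    "alkene_7_sq",
    "alkene_9_sq",
    "alkene_12_sq",
)

EXPRESSION_COLUMNS = (
    "individual_id",
    "species",
    "sad2a_expr",
    "sad5a_expr",
    "alkene_7",
    "alkene_9",
    "alkene_12",
)
CHOICE_COLUMNS = (
    "group",
    "alkene_7",
    "alkene_9",
    "alkene_12",
    "visits_cc",
    "visits_an",
)


class ParameterError(ValueError):
    """A ground-truth parameter set failed validation."""


@dataclass(frozen=True)
class GroundTruthParams:
    """Ground truth for the synthetic generators.

    Parameters
    ----------
    alkene_coeffs
        Per alkene class (``"7"``, ``"9"``, ``"12"``): mapping from term
        name (``"intercept"`` plus names in :data:`ALKENE_TERMS`) to
        coefficient on the ``ln(amount+1)`` scale.  Absent terms are zero.
    attraction_coeffs
        Per pollinator: mapping from term name (``"intercept"`` plus
        names in :data:`ATTRACTION_TERMS`) to coefficient on the
        log-visit-rate scale.
    expr_means
        Per species: ``(sqrt_sad2a_mean, sqrt_sad5a_mean)`` — mean
        allelic expression on the square-root scale.
    expr_sd
        SD of square-root expression around the species mean (> 0).
    alkene_resid_sd
        Residual SD on the ``ln(amount+1)`` scale (>= 0).
    group_prototypes
        Per choice-trial group: prototype ``(alkene_7, alkene_9,
        alkene_12)`` amounts.
    scent_sd
        Within-group SD of trial alkene amounts, truncated at zero (> 0).
    n_per_species
        Default individuals per species cluster (>= 3).
    seed
        Default RNG seed.
    """

    alkene_coeffs: dict[str, dict[str, float]]
    attraction_coeffs: dict[str, dict[str, float]]
    expr_means: dict[str, tuple[float, float]]
    expr_sd: float
    alkene_resid_sd: float
    group_prototypes: dict[str, tuple[float, float, float]] = field(repr=False)
    scent_sd: float = 1.5
    n_per_species: int = 30
    seed: int = 0

    def validate(self) -> None:
        if not (self.expr_sd > 0 and math.isfinite(self.expr_sd)):
            raise ParameterError("expr_sd must be positive and finite")
        if not (self.alkene_resid_sd >= 0 and math.isfinite(self.alkene_resid_sd)):
            raise ParameterError("alkene_resid_sd must be nonnegative and finite")
        if not (self.scent_sd > 0 and math.isfinite(self.scent_sd)):
            raise ParameterError("scent_sd must be positive and finite")
        if self.n_per_species < 3:
            raise ParameterError("n_per_species must be >= 3")
        for sp in SPECIES:
            if sp not in self.expr_means:
                raise ParameterError(f"expr_means missing species {sp!r}")
            m2, m5 = self.expr_means[sp]
            if not (m2 >= 0 and m5 >= 0 and math.isfinite(m2) and math.isfinite(m5)):
                raise ParameterError("expression means must be nonnegative and finite")
        for c in ALKENE_CLASSES:
            coeffs = self.alkene_coeffs.get(c)
            if coeffs is None:
                raise ParameterError(f"alkene_coeffs missing class {c!r}")
            _check_finite(coeffs, f"alkene_coeffs[{c!r}]")
        for p in POLLINATORS:
            coeffs = self.attraction_coeffs.get(p)
            if coeffs is None:
                raise ParameterError(f"attraction_coeffs missing pollinator {p!r}")
            _check_finite(coeffs, f"attraction_coeffs[{p!r}]")
        for g in CHOICE_GROUPS:
            if g not in self.group_prototypes:
                raise ParameterError(f"group_prototypes missing group {g!r}")
            if any(a < 0 or not math.isfinite(a) for a in self.group_prototypes[g]):
                raise ParameterError("group prototype amounts must be nonnegative")

    def with_(self, **changes) -> "GroundTruthParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **changes)


def _check_finite(coeffs: dict[str, float], what: str) -> None:
    for name, value in coeffs.items():
        if not math.isfinite(value):
            raise ParameterError(f"{what}[{name!r}] is not finite")


def alkene_latent(coeffs: dict[str, float], sqrt_sad2: float, sqrt_sad5: float):
    """Linear predictor on the ln(amount+1) scale for one alkene class."""
    return (
        coeffs.get("intercept", 0.0)
        + coeffs.get("sqrt_sad2", 0.0) * sqrt_sad2
        + coeffs.get("sqrt_sad5", 0.0) * sqrt_sad5
        + coeffs.get("sqrt_sad2:sqrt_sad5", 0.0) * sqrt_sad2 * sqrt_sad5
    )


def attraction_log_mean(coeffs: dict[str, float], amounts) -> float:
    """Log expected visit count given (alkene_7, alkene_9, alkene_12)."""
    a7, a9, a12 = amounts
    return (
        coeffs.get("intercept", 0.0)
        + coeffs.get("alkene_7", 0.0) * a7
        + coeffs.get("alkene_9", 0.0) * a9
        + coeffs.get("alkene_12", 0.0) * a12
        + coeffs.get("alkene_7_sq", 0.0) * a7 ** 2
        + coeffs.get("alkene_9_sq", 0.0) * a9 ** 2
        + coeffs.get("alkene_12_sq", 0.0) * a12 ** 2
    )


def _truncated_normal(mean, sd, size, rng):
    """Normal truncated at zero. A mean of exactly 0 yields exact zeros
    (the species carries no functional allele, so there is nothing to
    express)."""
    mean = float(mean)
    if mean == 0.0:
        return np.zeros(size)
    a = (0.0 - mean) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size, random_state=rng)


def generate_expression_scent(
    params: GroundTruthParams,
    n_per_species: int | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Draw one expression/scent data set.

    Returns a data frame with columns ``individual_id, species,
    sad2a_expr, sad5a_expr, alkene_7, alkene_9, alkene_12``.
    Deterministic given the seed.
    """
    params.validate()
    n = params.n_per_species if n_per_species is None else int(n_per_species)
    if n < 3:
        raise ParameterError("n_per_species must be >= 3")
    rng = np.random.default_rng(params.seed if seed is None else seed)

    rows = []
    for sp in SPECIES:
        m2, m5 = params.expr_means[sp]
        e2 = _truncated_normal(m2, params.expr_sd, n, rng)
        e5 = _truncated_normal(m5, params.expr_sd, n, rng)
        amounts = {}
        for c in ALKENE_CLASSES:
            latent = alkene_latent(params.alkene_coeffs[c], e2, e5)
            if params.alkene_resid_sd > 0:
                latent = latent + rng.normal(0.0, params.alkene_resid_sd, n)
            latent = np.maximum(np.asarray(latent, dtype=float), 0.0)
            amounts[c] = np.expm1(latent)
        for i in range(n):
            rows.append(
                {
                    "individual_id": f"{sp}_{i + 1:03d}",
                    "species": sp,
                    "sad2a_expr": e2[i] ** 2,
                    "sad5a_expr": e5[i] ** 2,
                    "alkene_7": amounts["7"][i],
                    "alkene_9": amounts["9"][i],
                    "alkene_12": amounts["12"][i],
                }
            )
    return pd.DataFrame(rows, columns=list(EXPRESSION_COLUMNS))


def generate_choice_trials(
    params: GroundTruthParams,
    n_trials_per_group: int = 50,
    seed: int | None = None,
) -> pd.DataFrame:
    """Draw one pollinator-choice data set.

    Per trial, alkene amounts scatter around the treatment group's
    prototype blend (normal truncated at zero) and visit counts for each
    bee species are Poisson with the ground-truth log-quadratic mean.
    """
    params.validate()
    if n_trials_per_group < 1:
        raise ParameterError("n_trials_per_group must be >= 1")
    rng = np.random.default_rng(params.seed if seed is None else seed)

    frames = []
    for group in CHOICE_GROUPS:
        proto = params.group_prototypes[group]
        amounts = np.column_stack(
            [
                _truncated_normal(proto[j], params.scent_sd, n_trials_per_group, rng)
                if proto[j] > 0
                else np.zeros(n_trials_per_group)
                for j in range(3)
            ]
        )
        mu_cc = np.exp(
            [attraction_log_mean(params.attraction_coeffs["C_cunicularius"], a) for a in amounts]
        )
        mu_an = np.exp(
            [attraction_log_mean(params.attraction_coeffs["A_nigroaenea"], a) for a in amounts]
        )
        frames.append(
            pd.DataFrame(
                {
                    "group": group,
                    "alkene_7": amounts[:, 0],
                    "alkene_9": amounts[:, 1],
                    "alkene_12": amounts[:, 2],
                    "visits_cc": rng.poisson(mu_cc),
                    "visits_an": rng.poisson(mu_an),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)[list(CHOICE_COLUMNS)]


def paper_like_fixture() -> GroundTruthParams:
    """Fixed, versioned ground-truth parameters.

    The constants are this package's own choices, calibrated once so that
    the system they generate has the qualitative shape of the published
    *Ophrys* system: a large SAD5 effect on *C. cunicularius* attraction
    (net allele-gain effect near 20%), a small SAD2 effect on
    *A. nigroaenea* attraction (a few percent), and no genotype that is
    more than half-attractive to both pollinators.  They are not claimed
    to equal any fitted field coefficients.
    """
    alkene_coeffs = {
        # 7-alkenes: SAD5 only
        "7": {"intercept": 2.1, "sqrt_sad5": 0.6},
        # 9-alkenes: SAD2 only
        "9": {"intercept": 2.1, "sqrt_sad2": 0.8},
        # 12-alkenes: SAD2 plus SAD2 x SAD5 interaction
        "12": {"intercept": 1.8, "sqrt_sad2": 0.7, "sqrt_sad2:sqrt_sad5": 0.12},
    }
    attraction_coeffs = {
        # attracted by 7-alkenes (concave on the log scale), mildly repelled
        # by 9/12-alkenes
        "C_cunicularius": {
            "intercept": -3.5,
            "alkene_7": 0.25,
            "alkene_7_sq": -0.0023,
            "alkene_9": -0.04,
            "alkene_12": -0.04,
        },
        # repelled by 7-alkenes with a gently saturating (quadratic) dose
        # response; 9/12-alkenes very weakly dilute the attractive
        # background, so gaining SAD2 never pays under A. nigroaenea alone
        "A_nigroaenea": {
            "intercept": 5.0,
            "alkene_7": -0.308,
            "alkene_7_sq": 0.00405,
            "alkene_9": -0.0002,
            "alkene_12": -0.0001,
        },
    }
    # sqrt-scale expression: each species strongly expresses its own gene
    # (homozygote SAD2A expr 4.0 in sphegodes, SAD5A expr 9.0 in exaltata)
    # with low leaky expression of the other (minor-paralog background)
    expr_means = {"sphegodes": (2.0, 0.4), "exaltata": (0.4, 3.0)}

    # treatment-group prototype blends: pure-species blends from the alkene
    # model at species-mean expression, plus the two supplemented blends
    def _amounts(e2, e5):
        return tuple(
            float(np.expm1(max(alkene_latent(alkene_coeffs[c], e2, e5), 0.0)))
            for c in ALKENE_CLASSES
        )

    sph = _amounts(2.0, 0.4)
    exa = _amounts(0.4, 3.0)
    group_prototypes = {
        "sphegodes_scent": sph,
        "sphegodes_plus7": (30.0, sph[1], sph[2]),
        "exaltata_scent": exa,
        "exaltata_plus9_12": (exa[0], 35.0, 10.0),
    }
    return GroundTruthParams(
        alkene_coeffs=alkene_coeffs,
        attraction_coeffs=attraction_coeffs,
        expr_means=expr_means,
        expr_sd=0.35,
        alkene_resid_sd=0.7,
        group_prototypes=group_prototypes,
        scent_sd=5.0,
        n_per_species=50,
        seed=0,
    )
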