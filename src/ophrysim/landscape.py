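"""Step 3 — genotype space, expression dosage, SUS suppression and the
pollination-fitness landscape.

Genotypes carry unordered diploid allele pairs at three loci: the
desaturase genes *SAD2* and *SAD5* (functional "+" vs nonfunctional "-"
alleles) and the trans-acting dominant suppressor locus *SUS* ("S"
suppresses *SAD5* expression; "s" does not).  Allelic expression is
additive in the functional-allele count (heterozygote = half the
homozygote reference); one or more S alleles force *SAD5* expression to
zero.

The landscape pushes every genotype through the fitted step-1 and step-2
models.  To propagate estimation uncertainty, every model coefficient is
drawn independently and uniformly within its 95% confidence interval for
each of ``n_perturb`` rounds (500 by default); per round, raw attraction
is scaled by the same round's prediction for the pure-species reference
genotype of that pollinator (--/++ for *C. cunicularius*, ++/-- for
*A. nigroaenea*), so the reference maps to exactly 1.  Scaled values may
exceed 1 and are reported unclipped; clipping to [0, 1] happens only in
the population simulator's visitation weights.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd

from .alkenes import AlkeneClassFit, AlkeneModel, predict_alkenes
from .attraction import AttractionModel, predict_attraction
from .synthetic import (
    ALKENE_CLASSES,
    ALKENE_TERMS,
    ATTRACTION_TERMS,
    POLLINATORS,
    GroundTruthParams,
)

__all__ = [
    "Genotype",
    "enumerate_genotypes",
    "genotype_expression",
    "scale_attraction",
    "predict_genotype_landscape",
    "net_allele_gain_effect",
    "reference_genotype",
    "truth_models",
]

_ALLELE_PAIR = {2: "++", 1: "+-", 0: "--"}
_SUS_PAIR = {2: "SS", 1: "Ss", 0: "ss"}


@dataclass(frozen=True, order=True)
class Genotype:
    """Unordered diploid genotype, stored as functional-allele counts.

    ``sad2`` and ``sad5`` count "+" alleles (0-2); ``sus`` counts "S"
    suppressor alleles (0-2).
    """

    sad2: int
    sad5: int
    sus: int = 0

    def __post_init__(self):
        for locus in ("sad2", "sad5", "sus"):
            v = getattr(self, locus)
            if v not in (0, 1, 2):
                raise ValueError(f"{locus} allele count must be 0, 1 or 2; got {v}")

    @property
    def label(self) -> str:
        """Two-locus label, SAD2 then SAD5, e.g. '++/--'."""
        return f"{_ALLELE_PAIR[self.sad2]}/{_ALLELE_PAIR[self.sad5]}"

    @property
    def full_label(self) -> str:
        """Three-locus label including the suppressor, e.g. '++/--/Ss'."""
        return f"{self.label}/{_SUS_PAIR[self.sus]}"

    @property
    def suppressed(self) -> bool:
        """True when at least one dominant S allele silences SAD5."""
        return self.sus >= 1


#: per-pollinator pure-species reference genotype used for 0-1 scaling
_REFERENCE = {
    "C_cunicularius": Genotype(sad2=0, sad5=2, sus=0),  # O. exaltata-like
    "A_nigroaenea": Genotype(sad2=2, sad5=0, sus=0),    # O. sphegodes-like
}


def reference_genotype(pollinator: str) -> Genotype:
    """Pure-species genotype whose raw attraction defines scaled = 1."""
    return _REFERENCE[pollinator]


def enumerate_genotypes(include_sus: bool = False) -> list[Genotype]:
    """All unordered diploid genotypes in canonical order.

    Without the suppressor locus: the 9 two-locus genotypes (sus fixed at
    ss).  With it: 27.  Order: SAD2 count descending, then SAD5 count
    descending, then S count ascending (ss first).
    """
    sus_states = (0, 1, 2) if include_sus else (0,)
    return [
        Genotype(sad2=c2, sad5=c5, sus=cs)
        for c2, c5, cs in product((2, 1, 0), (2, 1, 0), sus_states)
    ]


def genotype_expression(
    g: Genotype, ref_expr: tuple[float, float]
) -> tuple[float, float]:
    """Allelic expression (sad2a_expr, sad5a_expr) for a genotype.

    Additive dosage: expression = (functional-allele count / 2) x the
    homozygote reference.  A dominant S allele forces SAD5 expression to
    zero regardless of the SAD5 genotype.
    """
    r2, r5 = ref_expr
    if not (r2 > 0 and r5 > 0):
        raise ValueError("reference expressions must be positive")
    sad2a = g.sad2 / 2.0 * r2
    sad5a = 0.0 if g.suppressed else g.sad5 / 2.0 * r5
    return sad2a, sad5a


def scale_attraction(raw: float, reference_raw: float) -> float:
    """Attraction relative to the pure-species reference (1.0 = reference).

    Values above 1 are possible and returned unclipped.
    """
    if not reference_raw > 0:
        raise ValueError("reference attraction must be positive")
    if raw < 0:
        raise ValueError("raw attraction must be nonnegative")
    return raw / reference_raw


def truth_models(
    params: GroundTruthParams,
) -> tuple[AlkeneModel, dict[str, AttractionModel]]:
    """Wrap ground-truth generator coefficients as model objects.

    The returned models carry the exact generating coefficients with
    point (zero-width) confidence intervals, so pushing them through
    :func:`predict_genotype_landscape` evaluates the noise-free landscape
    implied by the parameter set itself — the deterministic benchmark the
    committed fixture is calibrated against.  Fit-quality fields are NaN
    because nothing was fitted.
    """
    params.validate()
    alkene = AlkeneModel()
    for c, coeffs in params.alkene_coeffs.items():
        terms = tuple(t for t in ALKENE_TERMS if t in coeffs)
        coef = {"intercept": float(coeffs.get("intercept", 0.0))}
        coef.update({t: float(coeffs[t]) for t in terms})
        alkene.classes[c] = AlkeneClassFit(
            terms=terms,
            coef=coef,
            ci={k: (v, v) for k, v in coef.items()},
            resid_sd=float(params.alkene_resid_sd),
            r_squared=float("nan"),
            n_obs=0,
        )
    attraction = {}
    for p, coeffs in params.attraction_coeffs.items():
        terms = tuple(t for t in ATTRACTION_TERMS if t in coeffs)
        coef = {"intercept": float(coeffs.get("intercept", 0.0))}
        coef.update({t: float(coeffs[t]) for t in terms})
        attraction[p] = AttractionModel(
            pollinator=p,
            terms=terms,
            coef=coef,
            ci={k: (v, v) for k, v in coef.items()},
            pseudo_r_squared=float("nan"),
            n_fit_rows=0,
        )
    return alkene, attraction


def _draw_coef(fit_coef, fit_ci, rng) -> dict[str, float]:
    return {
        name: float(rng.uniform(lo, hi)) if hi > lo else float(fit_coef[name])
        for name, (lo, hi) in fit_ci.items()
    }


def predict_genotype_landscape(
    genotypes: list[Genotype],
    alkene_model: AlkeneModel,
    attraction_models: dict[str, AttractionModel],
    ref_expr: tuple[float, float],
    n_perturb: int = 500,
    seed: int | None = None,
) -> pd.DataFrame:
    """Predicted alkene composition and scaled attraction per genotype.

    Returns one row per genotype with per-class alkene means and SDs and,
    per pollinator, the mean scaled attraction and its 2.5/97.5 percentile
    interval, all aggregated over ``n_perturb`` coefficient-perturbation
    rounds.  Deterministic given the seed.
    """
    if n_perturb < 1:
        raise ValueError("n_perturb must be >= 1")
    for c, fit in alkene_model.classes.items():
        for name in ("intercept",) + fit.terms:
            if name not in fit.ci:
                raise ValueError(f"alkene class {c}: missing CI for {name!r}")
    for p, m in attraction_models.items():
        for name in ("intercept",) + m.terms:
            if name not in m.ci:
                raise ValueError(f"{p}: missing CI for {name!r}")

    rng = np.random.default_rng(seed)
    expr = np.array([genotype_expression(g, ref_expr) for g in genotypes])
    n_g = len(genotypes)

    alkene_rounds = np.empty((n_perturb, n_g, 3))
    attr_rounds = {p: np.empty((n_perturb, n_g)) for p in attraction_models}
    for r in range(n_perturb):
        alkene_coef = {
            c: _draw_coef(fit.coef, fit.ci, rng)
            for c, fit in alkene_model.classes.items()
        }
        amounts = predict_alkenes(
            alkene_model, expr[:, 0], expr[:, 1], coef_overrides=alkene_coef
        )
        alkene_rounds[r] = amounts
        for p, m in attraction_models.items():
            coef = _draw_coef(m.coef, m.ci, rng)
            raw = predict_attraction(m, amounts, coef=coef)
            ref_g = reference_genotype(p)
            ref_amounts = predict_alkenes(
                alkene_model,
                *genotype_expression(ref_g, ref_expr),
                coef_overrides=alkene_coef,
            )
            ref_raw = float(predict_attraction(m, ref_amounts, coef=coef))
            attr_rounds[p][r] = [scale_attraction(v, ref_raw) for v in raw]

    rows = []
    for i, g in enumerate(genotypes):
        row = {
            "genotype": g.label,
            "sus": _SUS_PAIR[g.sus],
            "sad2": g.sad2,
            "sad5": g.sad5,
            "sus_count": g.sus,
        }
        for j, c in enumerate(ALKENE_CLASSES):
            row[f"alkene_{c}_mean"] = float(alkene_rounds[:, i, j].mean())
            row[f"alkene_{c}_sd"] = float(alkene_rounds[:, i, j].std(ddof=0))
        for p in attraction_models:
            short = "cc" if p == "C_cunicularius" else "an"
            vals = attr_rounds[p][:, i]
            row[f"attr_{short}_mean"] = float(vals.mean())
            row[f"attr_{short}_lo"] = float(np.percentile(vals, 2.5))
            row[f"attr_{short}_hi"] = float(np.percentile(vals, 97.5))
        rows.append(row)
    return pd.DataFrame(rows)


def net_allele_gain_effect(
    landscape: pd.DataFrame,
    locus: str,
    pollinator: str,
) -> float:
    """Average change in mean scaled attraction on gaining one "+" allele.

    For every genotype with fewer than two functional alleles at the
    locus (matching SAD background and suppressor state), the change in
    mean scaled attraction when one "-" is replaced by "+" is computed;
    the unweighted mean over those background genotypes is returned.
    """
    locus = locus.upper()
    if locus not in ("SAD2", "SAD5"):
        raise ValueError(f"locus must be SAD2 or SAD5, got {locus!r}")
    short = {"C_cunicularius": "cc", "A_nigroaenea": "an", "cc": "cc", "an": "an"}[pollinator]
    col = f"attr_{short}_mean"
    key = "sad2" if locus == "SAD2" else "sad5"
    other = "sad5" if locus == "SAD2" else "sad2"

    indexed = landscape.set_index([key, other, "sus_count"])[col]
    deltas = []
    for (k, o, s), value in indexed.items():
        if k < 2:
            deltas.append(float(indexed.loc[(k + 1, o, s)]) - float(value))
    return float(np.mean(deltas))
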