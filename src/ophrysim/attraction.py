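"""Step 2 — pollinator attraction GLMs with within-group permutation.

Choice-trial data come in four treatment groups (two pure-species scent
blends and two supplemented blends).  To propagate the variance of both
the scent measurements and the behavioral counts, the scent-to-visit
pairing is permuted within each group a number of times (300 by default)
and all permutation rounds are pooled into a single Poisson log-link GLM
of visit counts on linear and quadratic alkene-amount terms, with
AIC-based subset selection under a quadratic-implies-linear hierarchy.

Pooling the rounds follows the original resampling design literally; the
resulting Wald confidence intervals are anti-conservative because the
pooled rows are pseudo-replicates.  ``ci_inflation`` can widen them by a
given factor (e.g. ``sqrt(n_perm)``); the default applies no correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .selection import exhaustive_aic, stepwise_aic
from .synthetic import ATTRACTION_TERMS, CHOICE_GROUPS

__all__ = [
    "AttractionModel",
    "FitFailureError",
    "permute_within_groups",
    "fit_attraction_glm",
    "predict_attraction",
]

#: quadratic term -> linear term it requires
TERM_HIERARCHY = {
    "alkene_7_sq": "alkene_7",
    "alkene_9_sq": "alkene_9",
    "alkene_12_sq": "alkene_12",
}

_POLLINATOR_COLUMN = {
    "C_cunicularius": "visits_cc",
    "A_nigroaenea": "visits_an",
    "cc": "visits_cc",
    "an": "visits_an",
}
_CANONICAL = {"cc": "C_cunicularius", "an": "A_nigroaenea"}


class FitFailureError(RuntimeError):
    """The GLM failed to converge for a candidate term set."""


@dataclass
class AttractionModel:
    """Fitted Poisson GLM of visit counts for one pollinator species."""

    pollinator: str
    terms: tuple[str, ...]
    coef: dict[str, float]
    ci: dict[str, tuple[float, float]]
    pseudo_r_squared: float
    n_fit_rows: int

    def linear_predictor(self, amounts, coef: dict[str, float] | None = None):
        """Log expected visit count at (alkene_7, alkene_9, alkene_12)."""
        c = self.coef if coef is None else coef
        a = np.asarray(amounts, dtype=float)
        cols = _term_columns(a[..., 0], a[..., 1], a[..., 2])
        lp = c["intercept"]
        for t in self.terms:
            lp = lp + c[t] * cols[t]
        return lp

    def to_dict(self) -> dict:
        return {
            "pollinator": self.pollinator,
            "terms": list(self.terms),
            "coef": self.coef,
            "ci": {k: list(v) for k, v in self.ci.items()},
            "pseudo_r_squared": self.pseudo_r_squared,
            "n_fit_rows": self.n_fit_rows,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AttractionModel":
        return cls(
            pollinator=d["pollinator"],
            terms=tuple(d["terms"]),
            coef={k: float(v) for k, v in d["coef"].items()},
            ci={k: (float(lo), float(hi)) for k, (lo, hi) in d["ci"].items()},
            pseudo_r_squared=float(d["pseudo_r_squared"]),
            n_fit_rows=int(d["n_fit_rows"]),
        )


def _term_columns(a7, a9, a12) -> dict[str, np.ndarray]:
    a7 = np.asarray(a7, dtype=float)
    a9 = np.asarray(a9, dtype=float)
    a12 = np.asarray(a12, dtype=float)
    return {
        "alkene_7": a7,
        "alkene_9": a9,
        "alkene_12": a12,
        "alkene_7_sq": a7 ** 2,
        "alkene_9_sq": a9 ** 2,
        "alkene_12_sq": a12 ** 2,
    }


def permute_within_groups(
    trials: pd.DataFrame,
    n_perm: int = 300,
    seed: int | None = None,
) -> pd.DataFrame:
    """Re-pair scent rows and visit counts within each treatment group.

    For each of ``n_perm`` rounds and each group independently, the visit
    counts (both pollinators' columns together, since they were recorded
    in the same trial) are randomly re-paired with the group's scent
    rows.  All rounds are concatenated; a ``perm_round`` column records
    the round index.  Deterministic given the seed.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    for group in CHOICE_GROUPS:
        if (trials["group"] == group).sum() == 0:
            raise ValueError(f"treatment group {group!r} is empty")
    unknown = set(trials["group"]) - set(CHOICE_GROUPS)
    if unknown:
        raise ValueError(f"unknown treatment group(s): {sorted(unknown)}")

    rng = np.random.default_rng(seed)
    blocks = []
    for group in CHOICE_GROUPS:
        block = trials.loc[trials["group"] == group].reset_index(drop=True)
        n = len(block)
        scent = block[["alkene_7", "alkene_9", "alkene_12"]].to_numpy(dtype=float)
        visits = block[["visits_cc", "visits_an"]].to_numpy()
        # one permutation of the visit pairs per round
        orders = np.stack([rng.permutation(n) for _ in range(n_perm)])
        blocks.append(
            pd.DataFrame(
                {
                    "perm_round": np.repeat(np.arange(n_perm), n),
                    "group": group,
                    "alkene_7": np.tile(scent[:, 0], n_perm),
                    "alkene_9": np.tile(scent[:, 1], n_perm),
                    "alkene_12": np.tile(scent[:, 2], n_perm),
                    "visits_cc": visits[orders.ravel(), 0],
                    "visits_an": visits[orders.ravel(), 1],
                }
            )
        )
    out = pd.concat(blocks, ignore_index=True)
    # rounds outermost; within a round, groups keep their canonical order
    return out.sort_values("perm_round", kind="stable", ignore_index=True)


def fit_attraction_glm(
    expanded: pd.DataFrame,
    pollinator: str,
    selection: str = "exhaustive",
    ci_inflation: float | None = None,
) -> AttractionModel:
    """Fit the Poisson log-link visit-count GLM for one pollinator.

    Candidate terms are the three alkene amounts and their squares, with
    a quadratic term admissible only alongside its linear term; the
    AIC-minimal subset is selected (exhaustively over the 27 admissible
    subsets by default).
    """
    if pollinator not in _POLLINATOR_COLUMN:
        raise ValueError(f"unknown pollinator {pollinator!r}")
    ycol = _POLLINATOR_COLUMN[pollinator]
    y = np.asarray(expanded[ycol], dtype=float)
    if (y < 0).any() or not np.allclose(y, np.round(y)):
        raise ValueError(f"{ycol} must contain nonnegative integer counts")

    cols = _term_columns(expanded["alkene_7"], expanded["alkene_9"], expanded["alkene_12"])
    n = len(expanded)

    def fit(terms: tuple[str, ...]):
        X = np.column_stack([np.ones(n)] + [cols[t] for t in terms])
        try:
            res = sm.GLM(y, X, family=sm.families.Poisson()).fit(maxiter=200)
        except Exception as exc:  # pragma: no cover - separation is data-dependent
            raise FitFailureError(f"Poisson GLM failed for terms {terms}: {exc}") from exc
        if not np.all(np.isfinite(res.params)):
            raise FitFailureError(f"Poisson GLM diverged for terms {terms}")
        return res

    def aic_of(terms: tuple[str, ...]) -> float:
        return fit(terms).aic

    if selection == "exhaustive":
        terms = exhaustive_aic(aic_of, ATTRACTION_TERMS, hierarchy=TERM_HIERARCHY)
    elif selection == "stepwise":
        terms = stepwise_aic(aic_of, ATTRACTION_TERMS, hierarchy=TERM_HIERARCHY)
    else:
        raise ValueError(f"unknown selection engine {selection!r}")

    res = fit(terms)
    names = ("intercept",) + terms
    conf = np.asarray(res.conf_int(alpha=0.05))
    if ci_inflation is not None:
        mid = np.asarray(res.params)
        half = (conf[:, 1] - conf[:, 0]) / 2.0 * float(ci_inflation)
        conf = np.column_stack([mid - half, mid + half])
    null_dev = float(fit(()).deviance)
    pseudo_r2 = 1.0 - float(res.deviance) / null_dev if null_dev > 0 else 0.0
    return AttractionModel(
        pollinator=_CANONICAL.get(pollinator, pollinator),
        terms=terms,
        coef={nm: float(b) for nm, b in zip(names, res.params)},
        ci={nm: (float(lo), float(hi)) for nm, (lo, hi) in zip(names, conf)},
        pseudo_r_squared=pseudo_r2,
        n_fit_rows=n,
    )


def predict_attraction(
    model: AttractionModel,
    amounts,
    coef: dict[str, float] | None = None,
):
    """Expected visit count at the given (alkene_7, alkene_9, alkene_12).

    Strictly positive and finite for finite inputs (log link).
    """
    if not model.coef:
        raise ValueError("model is not fitted")
    return np.exp(model.linear_predictor(amounts, coef=coef))
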