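"""Step 1 — expression-to-alkene regressions.

For each alkene class c in {7, 9, 12}, ``ln(amount_c + 1)`` is regressed
by OLS on a subset of the candidate terms ``sqrt(X_SAD2A)``,
``sqrt(X_SAD5A)`` and their product, selected by minimum AIC (exhaustive
over the 8 subsets by default; intercept always present).  Predictions
back-transform via ``exp(.) - 1`` and are floored at zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .selection import exhaustive_aic, stepwise_aic
from .synthetic import ALKENE_CLASSES, ALKENE_TERMS

__all__ = ["AlkeneClassFit", "AlkeneModel", "fit_alkene_models", "predict_alkenes"]


class UnderdeterminedFitError(ValueError):
    """Fewer observations than candidate parameters."""


def _design_columns(sad2a_expr, sad5a_expr) -> dict[str, np.ndarray]:
    e2 = np.sqrt(np.asarray(sad2a_expr, dtype=float))
    e5 = np.sqrt(np.asarray(sad5a_expr, dtype=float))
    return {"sqrt_sad2": e2, "sqrt_sad5": e5, "sqrt_sad2:sqrt_sad5": e2 * e5}


def _design_matrix(columns: dict[str, np.ndarray], terms: tuple[str, ...], n: int):
    X = np.column_stack([np.ones(n)] + [columns[t] for t in terms])
    return X


@dataclass
class AlkeneClassFit:
    """OLS fit for one alkene class (selected terms, intercept implicit)."""

    terms: tuple[str, ...]
    coef: dict[str, float]
    ci: dict[str, tuple[float, float]]
    resid_sd: float
    r_squared: float
    n_obs: int

    def linear_predictor(self, sad2a_expr, sad5a_expr, coef: dict[str, float] | None = None):
        """Evaluate the ln(amount+1)-scale predictor; ``coef`` overrides
        the fitted coefficients (used by the CI-perturbation machinery)."""
        c = self.coef if coef is None else coef
        cols = _design_columns(sad2a_expr, sad5a_expr)
        lp = np.full(np.broadcast(cols["sqrt_sad2"], cols["sqrt_sad5"]).shape or (), c["intercept"], dtype=float)
        for t in self.terms:
            lp = lp + c[t] * cols[t]
        return lp


@dataclass
class AlkeneModel:
    """The three fitted expression-to-alkene regressions."""

    classes: dict[str, AlkeneClassFit] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            c: {
                "terms": list(f.terms),
                "coef": f.coef,
                "ci": {k: list(v) for k, v in f.ci.items()},
                "resid_sd": f.resid_sd,
                "r_squared": f.r_squared,
                "n_obs": f.n_obs,
            }
            for c, f in self.classes.items()
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AlkeneModel":
        classes = {
            c: AlkeneClassFit(
                terms=tuple(v["terms"]),
                coef={k: float(x) for k, x in v["coef"].items()},
                ci={k: (float(lo), float(hi)) for k, (lo, hi) in v["ci"].items()},
                resid_sd=float(v["resid_sd"]),
                r_squared=float(v["r_squared"]),
                n_obs=int(v["n_obs"]),
            )
            for c, v in d.items()
        }
        return cls(classes=classes)


def fit_alkene_models(
    data: pd.DataFrame,
    selection: str = "exhaustive",
) -> AlkeneModel:
    """Fit the three alkene regressions with AIC term selection.

    Parameters
    ----------
    data
        Expression/scent records with columns ``sad2a_expr, sad5a_expr,
        alkene_7, alkene_9, alkene_12`` (all nonnegative).
    selection
        ``"exhaustive"`` (default, reference) or ``"stepwise"``
        (bidirectional from the full model; agrees with exhaustive).
    """
    n = len(data)
    if n < 5:
        raise UnderdeterminedFitError(
            f"need at least 5 records to fit 4 candidate parameters, got {n}"
        )
    for col in ("sad2a_expr", "sad5a_expr", "alkene_7", "alkene_9", "alkene_12"):
        if col not in data.columns:
            raise ValueError(f"missing required column {col!r}")
        if (np.asarray(data[col], dtype=float) < 0).any():
            raise ValueError(f"column {col!r} contains negative values")

    columns = _design_columns(data["sad2a_expr"], data["sad5a_expr"])
    model = AlkeneModel()
    for c in ALKENE_CLASSES:
        y = np.log1p(np.asarray(data[f"alkene_{c}"], dtype=float))
        if np.ptp(y) == 0.0:
            # degenerate: constant response carries no signal
            warnings.warn(
                f"alkene_{c}: constant response; returning intercept-only fit with R^2 = 0"
            )
            v = float(y[0])
            model.classes[c] = AlkeneClassFit(
                terms=(),
                coef={"intercept": v},
                ci={"intercept": (v, v)},
                resid_sd=0.0,
                r_squared=0.0,
                n_obs=n,
            )
            continue

        def aic_of(terms: tuple[str, ...]) -> float:
            X = _design_matrix(columns, terms, n)
            return sm.OLS(y, X).fit().aic

        if selection == "exhaustive":
            terms = exhaustive_aic(aic_of, ALKENE_TERMS)
        elif selection == "stepwise":
            terms = stepwise_aic(aic_of, ALKENE_TERMS)
        else:
            raise ValueError(f"unknown selection engine {selection!r}")

        X = _design_matrix(columns, terms, n)
        res = sm.OLS(y, X).fit()
        names = ("intercept",) + terms
        conf = res.conf_int(alpha=0.05)
        model.classes[c] = AlkeneClassFit(
            terms=terms,
            coef={nm: float(b) for nm, b in zip(names, res.params)},
            ci={nm: (float(lo), float(hi)) for nm, (lo, hi) in zip(names, conf)},
            resid_sd=float(np.sqrt(res.scale)),
            r_squared=float(min(max(res.rsquared, 0.0), 1.0)),
            n_obs=n,
        )
    return model


def predict_alkenes(
    model: AlkeneModel,
    sad2a_expr,
    sad5a_expr,
    coef_overrides: dict[str, dict[str, float]] | None = None,
) -> np.ndarray:
    """Predict (alkene_7, alkene_9, alkene_12) amounts from expression.

    Back-transforms each class's linear predictor via ``exp(.) - 1`` and
    floors at zero.  ``coef_overrides`` optionally replaces the fitted
    coefficients per class (CI perturbation).
    """
    if not model.classes:
        raise ValueError("model is not fitted")
    s2 = np.asarray(sad2a_expr, dtype=float)
    s5 = np.asarray(sad5a_expr, dtype=float)
    if not (np.all(np.isfinite(s2)) and np.all(np.isfinite(s5))):
        raise ValueError("expression values must be finite")
    if (s2 < 0).any() or (s5 < 0).any():
        raise ValueError("expression values must be nonnegative")
    out = []
    for c in ALKENE_CLASSES:
        fit = model.classes[c]
        coef = None if coef_overrides is None else coef_overrides.get(c)
        lp = fit.linear_predictor(s2, s5, coef=coef)
        out.append(np.maximum(np.expm1(lp), 0.0))
    return np.stack([np.asarray(a, dtype=float) for a in out], axis=-1)
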