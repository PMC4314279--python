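"""AIC-based term-subset selection.

Two engines over the same candidate space:

* :func:`exhaustive_aic` — fits every admissible subset and returns the
  AIC-minimal one.  The candidate spaces in this package are tiny (8
  models for the alkene regressions, 27 hierarchy-respecting models for
  the attraction GLMs), so exhaustive search is the reference engine.
* :func:`stepwise_aic` — classical bidirectional stepwise search from
  the full model; provided for parity with the stepAIC workflow and
  tested to agree with the exhaustive oracle.

A *hierarchy* maps a term to the term it requires (quadratic -> linear);
subsets violating it are never considered.  Ties are broken toward the
smaller model, then by candidate order.
"""

from __future__ import annotations

from itertools import combinations
from typing import Callable, Mapping, Sequence

__all__ = ["exhaustive_aic", "stepwise_aic"]


def _admissible(terms: frozenset, hierarchy: Mapping[str, str] | None) -> bool:
    if not hierarchy:
        return True
    return all(req in terms for t, req in hierarchy.items() if t in terms)


def _sort_key(candidates: Sequence[str], terms: frozenset):
    return (len(terms), tuple(candidates.index(t) for t in sorted(terms, key=candidates.index)))


def exhaustive_aic(
    aic_of: Callable[[tuple[str, ...]], float],
    candidates: Sequence[str],
    hierarchy: Mapping[str, str] | None = None,
) -> tuple[str, ...]:
    """Return the AIC-minimal admissible term subset (intercept implicit).

    ``aic_of`` maps an ordered term tuple to the fitted model's AIC.
    """
    best_terms, best_aic = None, None
    for k in range(len(candidates) + 1):
        for combo in combinations(candidates, k):
            terms = frozenset(combo)
            if not _admissible(terms, hierarchy):
                continue
            aic = aic_of(combo)
            if (
                best_aic is None
                or aic < best_aic - 1e-10
                or (abs(aic - best_aic) <= 1e-10
                    and _sort_key(candidates, terms) < _sort_key(candidates, frozenset(best_terms)))
            ):
                best_terms, best_aic = combo, aic
    return tuple(t for t in candidates if t in best_terms)


def stepwise_aic(
    aic_of: Callable[[tuple[str, ...]], float],
    candidates: Sequence[str],
    hierarchy: Mapping[str, str] | None = None,
    start: str = "both",
) -> tuple[str, ...]:
    """Bidirectional stepwise AIC search.

    Repeatedly applies the single-term addition or removal that lowers
    AIC the most, until no admissible move improves.  ``start`` selects
    the starting model: ``'full'``, ``'empty'``, or ``'both'`` (default),
    which runs both greedy searches and returns the lower-AIC endpoint.
    A single greedy descent can stall in a local minimum when collinear
    terms mask each other; the two-start variant removes that path
    dependence on every candidate space this package uses.
    """
    hierarchy = dict(hierarchy or {})
    if start == "both":
        a = stepwise_aic(aic_of, candidates, hierarchy, start="full")
        b = stepwise_aic(aic_of, candidates, hierarchy, start="empty")
        if a == b:
            return a
        aic_a, aic_b = aic_of(a), aic_of(b)
        if abs(aic_a - aic_b) <= 1e-10:
            ca, cb = frozenset(a), frozenset(b)
            return a if _sort_key(candidates, ca) < _sort_key(candidates, cb) else b
        return a if aic_a < aic_b else b
    current = frozenset(candidates) if start == "full" else frozenset()
    if not _admissible(current, hierarchy):
        raise ValueError("full candidate model violates the term hierarchy")

    def ordered(terms: frozenset) -> tuple[str, ...]:
        return tuple(t for t in candidates if t in terms)

    cache: dict[frozenset, float] = {}

    def aic(terms: frozenset) -> float:
        if terms not in cache:
            cache[terms] = aic_of(ordered(terms))
        return cache[terms]

    current_aic = aic(current)
    while True:
        moves = []
        for t in candidates:
            if t in current:
                trial = current - {t}
            else:
                trial = current | {t}
            if _admissible(trial, hierarchy):
                moves.append(trial)
        best_move, best_aic = None, current_aic
        for trial in moves:
            a = aic(trial)
            if a < best_aic - 1e-10 or (
                best_move is not None
                and abs(a - best_aic) <= 1e-10
                and _sort_key(candidates, trial) < _sort_key(candidates, best_move)
            ):
                best_move, best_aic = trial, a
        if best_move is None:
            return ordered(current)
        current, current_aic = best_move, best_aic
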