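"""Search the weight simplex for the best-identifying composite weighting.

The composite score depends on a weight triple (w_L, w_A, w_J) on the
probability simplex.  This module enumerates candidate triples — the
seven canonical sets evaluated in the original benchmarking (the uniform
triple plus all permutations of (1/2, 1/3, 1/6)) or a regular simplex
grid — scores a labelled cohort under each, counts correct
identifications, and selects the winner.  A record is correct when its
predicted band equals its true group; an intermediate prediction is
incorrect for both groups.  Ties are broken by candidate order, so the
search is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from itertools import permutations

from .errors import DegenerateIndexError  # noqa: F401  (re-raised from scoring)
from .scoring import (
    TABLE1_BANDS,
    CategoryBands,
    LabeledIndexCohort,
    ReferenceThresholds,
    WeightVector,
    score_performance,
)

__all__ = [
    "WeightEvaluation",
    "canonical_weight_sets",
    "simplex_grid",
    "evaluate_weights",
    "select_best_weights",
]


@dataclass(frozen=True)
class WeightEvaluation:
    """Result of scoring one cohort under one weight vector."""

    weights: WeightVector
    n_correct: int
    n_total: int
    per_performance: tuple  # of (true_group, predicted_category, rho)

    def __post_init__(self) -> None:
        if not 0 <= self.n_correct <= self.n_total:
            raise ValueError("need 0 <= n_correct <= n_total")

    @property
    def accuracy(self) -> float:
        return self.n_correct / self.n_total


def canonical_weight_sets() -> list[WeightVector]:
    """The seven benchmark weightings, in their published row order.

    Set 1 is the uniform triple; sets 2–7 are the six distinct
    permutations of (1/2, 1/3, 1/6).  Set 5, (1/2, 1/3, 1/6), is the
    weighting the search historically selected.
    """
    return [
        WeightVector(1 / 3, 1 / 3, 1 / 3),
        WeightVector(1 / 3, 1 / 6, 1 / 2),
        WeightVector(1 / 3, 1 / 2, 1 / 6),
        WeightVector(1 / 6, 1 / 3, 1 / 2),
        WeightVector(1 / 2, 1 / 3, 1 / 6),
        WeightVector(1 / 6, 1 / 2, 1 / 3),
        WeightVector(1 / 2, 1 / 6, 1 / 3),
    ]


def simplex_grid(step: Fraction | str | float) -> list[WeightVector]:
    """All weight triples on a regular simplex lattice of the given step.

    ``step`` must be the reciprocal of a positive integer m (e.g. ``1/6``,
    ``"1/6"`` or ``Fraction(1, 6)``); the grid contains every triple of
    non-negative multiples of 1/m summing to 1 — C(m + 2, 2) vectors, in
    lexicographic order of (i, j) lattice coordinates.
    """
    if isinstance(step, str):
        step = Fraction(step)
    if isinstance(step, Fraction):
        if step <= 0 or step > 1 or step.numerator != 1:
            raise ValueError(f"step must be 1/m for a positive integer m, got {step}")
        m = step.denominator
    else:
        if not 0 < step <= 1:
            raise ValueError(f"step must lie in (0, 1], got {step}")
        m = round(1 / step)
        if abs(1 / step - m) > 1e-9:
            raise ValueError(f"1/step must be an integer, got 1/{step}")
    return [
        WeightVector(i / m, j / m, (m - i - j) / m)
        for i in range(m + 1)
        for j in range(m - i + 1)
    ]


def evaluate_weights(
    weights: WeightVector,
    cohort: LabeledIndexCohort,
    thresholds: ReferenceThresholds,
    bands: CategoryBands = TABLE1_BANDS,
) -> WeightEvaluation:
    """Score every cohort record and count correct identifications."""
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    per = []
    n_correct = 0
    for indices, group in cohort.records:
        scored = score_performance(indices, thresholds, weights, bands)
        per.append((group, scored.category, scored.rho))
        n_correct += int(scored.category == group)
    return WeightEvaluation(
        weights=weights,
        n_correct=n_correct,
        n_total=len(cohort),
        per_performance=tuple(per),
    )


def select_best_weights(
    candidates: list[WeightVector],
    cohort: LabeledIndexCohort,
    thresholds: ReferenceThresholds,
    bands: CategoryBands = TABLE1_BANDS,
) -> WeightEvaluation:
    """Evaluate every candidate and return the one with most correct calls.

    Ties go to the earliest candidate in list order.
    """
    if not candidates:
        raise ValueError("candidate list is empty")
    best: WeightEvaluation | None = None
    for w in candidates:
        ev = evaluate_weights(w, cohort, thresholds, bands)
        if best is None or ev.n_correct > best.n_correct:
            best = ev
    return best
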