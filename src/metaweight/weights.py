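"""Weight analysis: per-path significance weights and predictor classes.

The weight of a predictor on a path is W = S/E, the fraction of the E
examinations of the path that reported a statistically significant effect.
Predictors are classified by (W, E):

* **best** — examined at least 5 times with W ≥ 0.800;
* **promising** — examined fewer than 5 times but with a perfect W = 1;
* **well-utilized** — examined at least 5 times, W below 0.800;
* **experimental** — the residual class (fewer than 5 examinations, W < 1).

Both thresholds are inclusive. W is computed in exact rational arithmetic
for classification and reported rounded to 3 decimals.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Sequence, TextIO

from .errors import DomainError
from .records import PathGroup

BEST_MIN_WEIGHT = Fraction(4, 5)  # 0.800, inclusive
BEST_MIN_EXAMINATIONS = 5  # inclusive

CLASS_BEST = "best"
CLASS_PROMISING = "promising"
CLASS_WELL_UTILIZED = "well-utilized"
CLASS_EXPERIMENTAL = "experimental"


@dataclass(frozen=True)
class WeightResult:
    predictor: str
    outcome: str
    S: int
    E: int
    classification: str

    @property
    def W(self) -> float:
        return self.S / self.E

    @property
    def W_exact(self) -> Fraction:
        return Fraction(self.S, self.E)


def classify_predictor(W: float | Fraction, E: int) -> str:
    """Total classification of a predictor by weight and examination count."""
    if E < 1:
        raise DomainError(f"E must be >= 1, got {E}")
    W = Fraction(W).limit_denominator(10**9) if not isinstance(W, Fraction) else W
    if not 0 <= W <= 1:
        raise DomainError(f"W must lie in [0, 1], got {float(W)}")
    if E >= BEST_MIN_EXAMINATIONS:
        if W >= BEST_MIN_WEIGHT:
            return CLASS_BEST
        return CLASS_WELL_UTILIZED
    if W == 1:
        return CLASS_PROMISING
    return CLASS_EXPERIMENTAL


def compute_weight(group: PathGroup) -> WeightResult:
    """Weight W = S/E for one path group, with its classification."""
    if group.E == 0:
        raise DomainError(
            f"path {group.predictor} -> {group.outcome} has no examinations"
        )
    return WeightResult(
        predictor=group.predictor,
        outcome=group.outcome,
        S=group.S,
        E=group.E,
        classification=classify_predictor(Fraction(group.S, group.E), group.E),
    )


def weight_table(groups: Sequence[PathGroup]) -> list[WeightResult]:
    """One weight result per group, ordered by (outcome, predictor)."""
    return [
        compute_weight(g)
        for g in sorted(groups, key=lambda g: (g.outcome, g.predictor))
    ]


def write_weight_table(
    results: Sequence[WeightResult], dest: str | Path | TextIO
) -> None:
    """CSV report: outcome, predictor, S, nonsignificant, E, W (3 decimals),
    classification."""
    if isinstance(dest, (str, Path)):
        stream: TextIO = open(dest, "w", newline="", encoding="utf-8")
        close = True
    else:
        stream, close = dest, False
    try:
        writer = csv.writer(stream)
        writer.writerow(
            [
                "outcome",
                "predictor",
                "significant",
                "nonsignificant",
                "total",
                "weight",
                "classification",
            ]
        )
        for w in results:
            writer.writerow(
                [
                    w.outcome,
                    w.predictor,
                    w.S,
                    w.E - w.S,
                    w.E,
                    f"{w.W:.3f}",
                    w.classification,
                ]
            )
    finally:
        if close:
            stream.close()
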