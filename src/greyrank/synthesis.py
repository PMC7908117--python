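"""Synthetic (blended) degrees and the descending-degree ranking step.

The two synthetic degrees are convex combinations of base degrees with a
weight ``theta`` in [0, 1], conventionally 0.5:

* the **first synthetic degree** (SDGRA) blends the absolute and relative
  degrees: ``theta * absolute + (1 - theta) * relative`` — it rewards
  comparators whose curves match the reference in both level change and
  rate of change;
* the **second synthetic degree** (SSGRA) blends Deng's and the absolute
  degree: ``theta * deng + (1 - theta) * absolute`` — point-wise closeness
  combined with the integral view.

``theta`` always weights the *first* argument. Ranking is competition
style: rank 1 is the largest degree, exact ties share the smaller rank
number (1, 1, 3, ...) and are flagged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

from .errors import EmptyInputError, InvalidThetaError
from .models import (
    DegreeResult,
    GraModel,
    absolute_degrees,
    deng_degree,
    relative_degrees,
    DEFAULT_EPSILON,
)
from .sequence import Panel

__all__ = [
    "DEFAULT_THETA",
    "RankTable",
    "first_synthetic_degree",
    "second_synthetic_degree",
    "rank_factors",
    "compute_all",
]

DEFAULT_THETA = 0.5


def _check_theta(theta: float) -> float:
    if not (0.0 <= theta <= 1.0):
        raise InvalidThetaError(f"theta must be in [0, 1], got {theta}")
    return float(theta)


def _check_component(value: float, label: str) -> float:
    if not (0.0 < value <= 1.0):
        raise InvalidThetaError(  # noqa: TRY004 - precondition on component range
            f"{label} degree must be in (0, 1], got {value}"
        )
    return float(value)


@dataclass(frozen=True)
class RankTable:
    """Degrees and descending-order competition ranks under one model."""

    model: GraModel
    degrees: dict[str, float]
    ranks: dict[str, int]
    has_ties: bool = field(default=False)

    def ordered_names(self) -> list[str]:
        """Comparator names from rank 1 downward (insertion order on ties)."""
        return sorted(self.degrees, key=lambda name: self.ranks[name])


def first_synthetic_degree(
    absolute: float, relative: float, theta: float = DEFAULT_THETA
) -> float:
    """SDGRA: theta-weighted blend of the absolute and relative degrees."""
    t = _check_theta(theta)
    a = _check_component(absolute, "absolute")
    r = _check_component(relative, "relative")
    return t * a + (1.0 - t) * r


def second_synthetic_degree(
    deng: float, absolute: float, theta: float = DEFAULT_THETA
) -> float:
    """SSGRA: theta-weighted blend of Deng's and the absolute degree."""
    t = _check_theta(theta)
    d = _check_component(deng, "deng")
    a = _check_component(absolute, "absolute")
    return t * d + (1.0 - t) * a


def rank_factors(
    degrees: Mapping[str, float], model: GraModel | None = None
) -> RankTable:
    """Competition-rank comparators by degree, largest first.

    Rank of a comparator = 1 + number of comparators with strictly larger
    degree, so exact ties share the smaller rank number and the next rank
    is skipped. Output is deterministic for a fixed input mapping.
    """
    if not degrees:
        raise EmptyInputError("no degrees to rank")
    values = {k: float(v) for k, v in degrees.items()}
    for name, v in values.items():
        if not math.isfinite(v):
            raise ValueError(f"degree for {name!r} is not finite: {v}")
    ranks = {
        name: 1 + sum(1 for other in values.values() if other > v)
        for name, v in values.items()
    }
    has_ties = len(set(values.values())) < len(values)
    return RankTable(
        model=model if model is not None else GraModel.DENG,
        degrees=values,
        ranks=ranks,
        has_ties=has_ties,
    )


def compute_all(
    panel: Panel,
    epsilon: float = DEFAULT_EPSILON,
    theta: float = DEFAULT_THETA,
) -> list[RankTable]:
    """Run all five models on a panel and rank each one.

    Returns the tables in the order Deng, absolute, relative, SDGRA, SSGRA.
    The two synthetic tables are exact theta-blends of the base tables.
    Errors from any base model are re-raised with the model named.
    """
    results: dict[GraModel, DegreeResult] = {}
    for gm, fn in (
        (GraModel.DENG, lambda p: deng_degree(p, epsilon)),
        (GraModel.ABSOLUTE, absolute_degrees),
        (GraModel.RELATIVE, relative_degrees),
    ):
        try:
            results[gm] = fn(panel)
        except Exception as exc:
            raise type(exc)(f"{gm.value} model failed: {exc}") from exc

    deng = results[GraModel.DENG].degrees
    absolute = results[GraModel.ABSOLUTE].degrees
    relative = results[GraModel.RELATIVE].degrees
    sdgra = {
        name: first_synthetic_degree(absolute[name], relative[name], theta)
        for name in panel.comparator_names
    }
    ssgra = {
        name: second_synthetic_degree(deng[name], absolute[name], theta)
        for name in panel.comparator_names
    }
    return [
        rank_factors(deng, GraModel.DENG),
        rank_factors(absolute, GraModel.ABSOLUTE),
        rank_factors(relative, GraModel.RELATIVE),
        rank_factors(sdgra, GraModel.SDGRA),
        rank_factors(ssgra, GraModel.SSGRA),
    ]
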