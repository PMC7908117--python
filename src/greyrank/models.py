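"""The three base grey relational degrees: Deng's, absolute, and relative.

All three produce a scalar in (0, 1] per comparator; 1 means the comparator
curve is indistinguishable from the reference under that model's notion of
shape.

**Deng's degree** works point-wise on mean images. With
``d_i(k) = |x0'(k) - xi'(k)|`` and the global minimum/maximum of ``d`` taken
jointly over all comparators and all observation points, the point
coefficient is::

    gamma_i(k) = (d_min + eps * d_max) / (d_i(k) + eps * d_max)

and the degree is the arithmetic mean of ``gamma_i(k)`` over k. The
resolution coefficient ``eps`` in (0, 1] damps the influence of the single
largest deviation; by convention 0.5. Because d_min and d_max are global,
Deng's degree for one comparator depends on the whole panel.

**Absolute degree** compares signed areas of zero-start images. With
``s = sum_{k=2}^{m-1} image(k) + image(m)/2`` for each zero-started series,

    eps_0i = (1 + |s0| + |si|) / (1 + |s0| + |si| + |s0 - si|)

which is 1 exactly when the two areas agree, and is invariant under
additive shifts of either raw series.

**Relative degree** applies the same area statistic to zero-start images of
*initial-value* images, so it compares relative growth away from the start
point and is invariant under positive scaling of either raw series.

Absolute and relative degrees are pairwise (reference vs one comparator);
panel-level helpers simply map over comparators.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass

import numpy as np

from .errors import InvalidEpsilonError, LengthError
from .sequence import (
    ImageKind,
    Panel,
    Series,
    initial_image,
    mean_image,
    zero_start_image,
)

__all__ = [
    "GraModel",
    "DengResult",
    "IntegralStats",
    "DegreeResult",
    "DEFAULT_EPSILON",
    "deng_coefficients",
    "deng_degree",
    "integral_stat",
    "absolute_degree",
    "relative_degree",
    "absolute_degrees",
    "relative_degrees",
]

DEFAULT_EPSILON = 0.5


class GraModel(enum.Enum):
    """Identifiers for the five degree models."""

    DENG = "deng"
    ABSOLUTE = "absolute"
    RELATIVE = "relative"
    SDGRA = "sdgra"
    SSGRA = "ssgra"


@dataclass(frozen=True)
class DengResult:
    """Point coefficients and per-comparator degrees of Deng's model.

    ``coefficients`` is an ``n x m`` matrix of gamma_i(k), row order matching
    ``names``; ``degrees`` maps comparator name to the row mean.
    """

    epsilon: float
    names: tuple[str, ...]
    coefficients: np.ndarray
    degrees: dict[str, float]


@dataclass(frozen=True)
class IntegralStats:
    """Signed-area statistic of one zero-started image."""

    s_value: float


@dataclass(frozen=True)
class DegreeResult:
    """Per-comparator degrees under one model."""

    model: GraModel
    degrees: dict[str, float]


def _check_epsilon(epsilon: float) -> float:
    if not (0.0 < epsilon <= 1.0):
        raise InvalidEpsilonError(
            f"resolution coefficient must be in (0, 1], got {epsilon}"
        )
    return float(epsilon)


def deng_coefficients(panel: Panel, epsilon: float = DEFAULT_EPSILON) -> DengResult:
    """Compute Deng's point coefficients gamma_i(k) for every comparator.

    The deviations are taken between mean images, and the min/max are global
    over the whole panel, so adding or removing a comparator changes every
    coefficient. The degenerate panel in which every comparator has the same
    mean image as the reference (d_max = 0) is defined to yield coefficient
    1 everywhere rather than 0/0.
    """
    eps = _check_epsilon(epsilon)
    ref_img = mean_image(panel.reference).values
    comp_imgs = np.vstack([mean_image(s).values for s in panel.comparators])
    delta = np.abs(comp_imgs - ref_img[np.newaxis, :])
    d_min = float(delta.min())
    d_max = float(delta.max())
    if d_max == 0.0:
        gamma = np.ones_like(delta)
    else:
        gamma = (d_min + eps * d_max) / (delta + eps * d_max)
    degrees = {
        s.name: float(gamma[i].mean()) for i, s in enumerate(panel.comparators)
    }
    return DengResult(
        epsilon=eps,
        names=tuple(panel.comparator_names),
        coefficients=gamma,
        degrees=degrees,
    )


def deng_degree(panel: Panel, epsilon: float = DEFAULT_EPSILON) -> DegreeResult:
    """Deng's grey relational degree: mean of gamma_i(k) over the m points."""
    res = deng_coefficients(panel, epsilon)
    return DegreeResult(model=GraModel.DENG, degrees=dict(res.degrees))


def integral_stat(image: Series) -> IntegralStats:
    """Signed-area statistic ``s`` of a (typically zero-started) image.

    ``s = sum_{k=2}^{m-1} image(k) + image(m) / 2`` — a trapezoid-like rule
    that gives the final point half weight. For m = 2 the middle sum is
    empty and s is half the last value.
    """
    v = image.values
    if v.size < 2:
        raise LengthError(f"series {image.name!r}: need length >= 2")
    return IntegralStats(s_value=float(v[1:-1].sum() + 0.5 * v[-1]))


def _check_pair(x0: Series, xi: Series) -> int:
    m = len(x0)
    if len(xi) != m:
        raise LengthError(
            f"length mismatch: {x0.name!r} has {m}, {xi.name!r} has {len(xi)}"
        )
    if m == 2:
        warnings.warn(
            "integral degrees on length-2 series are degenerate "
            "(the area statistic reduces to half the end point)",
            stacklevel=3,
        )
    return m


def _area_degree(s0: float, si: float) -> float:
    base = 1.0 + abs(s0) + abs(si)
    return base / (base + abs(s0 - si))


def absolute_degree(x0: Series, xi: Series) -> float:
    """Absolute degree of grey incidence between two series.

    Computed on zero-start images; equals 1 iff the two signed areas
    coincide, and is invariant under additive shifts of either series.
    """
    _check_pair(x0, xi)
    s0 = integral_stat(zero_start_image(x0)).s_value
    si = integral_stat(zero_start_image(xi)).s_value
    return _area_degree(s0, si)


def relative_degree(
    x0: Series, xi: Series, image: ImageKind = ImageKind.INITIAL
) -> float:
    """Relative degree of grey incidence between two series.

    The same area comparison as :func:`absolute_degree`, but applied to the
    zero-start images of each series' initial-value image, so it compares
    relative growth and is invariant under positive scaling of either
    series.

    ``image=ImageKind.MEAN`` is a documented alternative normalization
    (divide by the series mean instead of the first value) for users who
    prefer a mean-anchored rate-of-change comparison; the default follows
    the standard initial-value operator.
    """
    _check_pair(x0, xi)
    if image is ImageKind.MEAN:
        norm0, normi = mean_image(x0), mean_image(xi)
    else:
        norm0, normi = initial_image(x0), initial_image(xi)
    s0 = integral_stat(zero_start_image(norm0)).s_value
    si = integral_stat(zero_start_image(normi)).s_value
    return _area_degree(s0, si)


def absolute_degrees(panel: Panel) -> DegreeResult:
    """Absolute degree of every comparator against the panel reference."""
    return DegreeResult(
        model=GraModel.ABSOLUTE,
        degrees={
            s.name: absolute_degree(panel.reference, s) for s in panel.comparators
        },
    )


def relative_degrees(
    panel: Panel, image: ImageKind = ImageKind.INITIAL
) -> DegreeResult:
    """Relative degree of every comparator against the panel reference."""
    return DegreeResult(
        model=GraModel.RELATIVE,
        degrees={
            s.name: relative_degree(panel.reference, s, image=image)
            for s in panel.comparators
        },
    )
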