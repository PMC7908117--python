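"""Core sequence types and the image operators of grey relational analysis.

A grey relational model never compares raw sequences directly; it first maps
each sequence to an *image* that removes the nuisance dimension the model is
blind to:

* the **mean image** ``x(k) / mean(x)`` removes scale (units), and underlies
  Deng's point-coefficient model;
* the **initial-value image** ``x(k) / x(1)`` removes scale relative to the
  starting point, and underlies the relative (rate-of-change) degree;
* the **zero-start image** ``x(k) - x(1)`` removes location, and underlies
  the absolute (integral) degree.

:class:`Series` and :class:`Panel` are the in-memory containers shared by
every model: one reference series :math:`x_0` and ``n`` comparator series
:math:`x_1 \\dots x_n` observed at ``m`` aligned points indexed by ``k``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from .errors import LengthError, ZeroInitialError, ZeroMeanError

__all__ = [
    "Series",
    "Panel",
    "ImageKind",
    "mean_image",
    "initial_image",
    "zero_start_image",
    "apply_image",
]


@dataclass(frozen=True)
class Series:
    """A named, ordered sequence of real observations.

    Parameters
    ----------
    name:
        Non-empty text label, unique within a :class:`Panel`.
    values:
        At least two finite real numbers; observation order is preserved
        exactly as given.
    """

    name: str
    values: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 1 or arr.size < 2:
            raise LengthError(
                f"series {self.name!r}: need a 1-d sequence of length >= 2, "
                f"got shape {arr.shape}"
            )
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"series {self.name!r}: values must be finite (no NaN/inf)")
        if not self.name:
            raise ValueError("series name must be non-empty")
        object.__setattr__(self, "values", arr)

    def __len__(self) -> int:
        return int(self.values.size)

    def with_values(self, values: np.ndarray) -> "Series":
        """Return a same-named series with new values."""
        return Series(self.name, np.asarray(values, dtype=float))


@dataclass(frozen=True)
class Panel:
    """One reference series plus ``n >= 1`` comparators on ``m`` aligned points."""

    reference: Series
    comparators: tuple[Series, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        comps = tuple(self.comparators)
        if len(comps) < 1:
            raise LengthError("panel needs at least one comparator series")
        m = len(self.reference)
        for s in comps:
            if len(s) != m:
                raise LengthError(
                    f"series {s.name!r} has length {len(s)}, expected {m} "
                    f"to match reference {self.reference.name!r}"
                )
        names = [self.reference.name] + [s.name for s in comps]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate series names in panel: {names}")
        object.__setattr__(self, "comparators", comps)

    @property
    def m(self) -> int:
        """Number of observation points."""
        return len(self.reference)

    @property
    def n(self) -> int:
        """Number of comparator series."""
        return len(self.comparators)

    @property
    def comparator_names(self) -> list[str]:
        return [s.name for s in self.comparators]


class ImageKind(enum.Enum):
    """The three sequence-image operators."""

    MEAN = "mean"
    INITIAL = "initial"
    ZERO_START = "zero_start"


def mean_image(s: Series) -> Series:
    """Divide a series by its arithmetic mean.

    The resulting image has mean 1 and is invariant under positive scaling
    of the input, which is what makes Deng's coefficient unit-free.

    Raises
    ------
    ZeroMeanError
        If the series mean is zero.
    """
    mu = float(np.mean(s.values))
    if mu == 0.0:
        raise ZeroMeanError(f"series {s.name!r} has zero mean; mean image undefined")
    return s.with_values(s.values / mu)


def initial_image(s: Series) -> Series:
    """Divide a series by its first value, so the image starts at 1.

    Invariant under scaling by any nonzero constant; the basis of the
    relative degree, which compares rates of change from the start point.

    Raises
    ------
    ZeroInitialError
        If the first value is zero.
    """
    x1 = float(s.values[0])
    if x1 == 0.0:
        raise ZeroInitialError(
            f"series {s.name!r} starts at zero; initial-value image undefined"
        )
    return s.with_values(s.values / x1)


def zero_start_image(s: Series) -> Series:
    """Subtract the first value, so the image starts at 0.

    Invariant under additive shifts; the basis of the absolute degree,
    which compares the signed areas swept out by the shifted curves.
    """
    return s.with_values(s.values - s.values[0])


_IMAGE_FUNCS = {
    ImageKind.MEAN: mean_image,
    ImageKind.INITIAL: initial_image,
    ImageKind.ZERO_START: zero_start_image,
}


def apply_image(s: Series, kind: ImageKind) -> Series:
    """Apply the image operator named by ``kind``."""
    return _IMAGE_FUNCS[kind](s)
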