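"""Closed-interval scalars for cost bookkeeping.

Several ATP costs in the model are only known to within a range
(e.g. the nitrate-assimilation cost per mol N).  Those quantities are
carried through the cost algebra as closed intervals [lo, hi].  All
coefficients in the cost ledgers are positive, so endpoint arithmetic is
exact for the operations we need (+, scalar *, / by a positive scalar).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Union

Cost = Union[float, "Interval"]


@dataclass(frozen=True)
class Interval:
    """A closed real interval ``[lo, hi]`` with ``lo <= hi``."""

    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.lo) and math.isfinite(self.hi)):
            raise ValueError("interval endpoints must be finite")
        if self.lo > self.hi:
            raise ValueError(f"interval endpoints out of order: [{self.lo}, {self.hi}]")

    @property
    def mid(self) -> float:
        """Midpoint of the interval (the 'median' reporting anchor)."""
        return 0.5 * (self.lo + self.hi)

    @property
    def width(self) -> float:
        return self.hi - self.lo

    def __contains__(self, x: float) -> bool:
        return self.lo <= x <= self.hi

    # -- positive-domain endpoint arithmetic --------------------------------
    def __add__(self, other: Cost) -> "Interval":
        if isinstance(other, Interval):
            return Interval(self.lo + other.lo, self.hi + other.hi)
        return Interval(self.lo + other, self.hi + other)

    __radd__ = __add__

    def __mul__(self, k: Cost) -> "Interval":
        if isinstance(k, Interval):
            if k.lo < 0 or self.lo < 0:
                raise ValueError("interval product requires non-negative operands")
            return Interval(self.lo * k.lo, self.hi * k.hi)
        if k < 0:
            return Interval(self.hi * k, self.lo * k)
        return Interval(self.lo * k, self.hi * k)

    __rmul__ = __mul__

    def __truediv__(self, k: float) -> "Interval":
        if isinstance(k, Interval):
            raise TypeError("division by an interval is not supported")
        if k <= 0:
            raise ValueError("division only by a positive scalar")
        return Interval(self.lo / k, self.hi / k)

    def __rtruediv__(self, num: float) -> "Interval":
        # num / [lo, hi] for positive operands is [num/hi, num/lo]
        if self.lo <= 0:
            raise ValueError("reciprocal of an interval containing 0")
        if num < 0:
            raise ValueError("numerator must be non-negative")
        return Interval(num / self.hi, num / self.lo)


def as_interval(x: Cost) -> Interval:
    """Coerce a scalar to a degenerate interval; pass intervals through."""
    if isinstance(x, Interval):
        return x
    return Interval(float(x), float(x))


def lower(x: Cost) -> float:
    return x.lo if isinstance(x, Interval) else float(x)


def upper(x: Cost) -> float:
    return x.hi if isinstance(x, Interval) else float(x)


def midpoint(x: Cost) -> float:
    return x.mid if isinstance(x, Interval) else float(x)


def truncate(x: Cost, ndigits: int = 2) -> Cost:
    """Truncate toward zero at ``ndigits`` decimal places.

    This is the reporting convention used for all printed-comparable
    ratios in the package (0.5/0.33 -> 1.51, 17/9 -> 1.88, 16/9 -> 1.77),
    as opposed to round-half-even.  A small epsilon absorbs binary
    floating-point representation error so that values that are exactly a
    multiple of 10**-ndigits are not spuriously truncated down.
    """
    if isinstance(x, Interval):
        return Interval(truncate(x.lo, ndigits), truncate(x.hi, ndigits))
    f = 10.0 ** ndigits
    y = math.floor(abs(x) * f + 1e-9) / f
    return -y if x < 0 else y
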