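"""Closed-interval arithmetic for bound propagation.

Every monetary or utility quantity in the model is carried as a closed
interval ``[lower, upper]``; scalars are degenerate intervals with
``lower == upper``.  This keeps bound propagation uniform: a diagnosis
with a single literature estimate and one with an upper/lower bound flow
through the same code path.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Union

Number = Union[int, float]


@dataclass(frozen=True)
class Interval:
    """A closed real interval ``[lower, upper]`` with ``lower <= upper``."""

    lower: float
    upper: float

    def __post_init__(self) -> None:
        lo, hi = float(self.lower), float(self.upper)
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", hi)
        if lo > hi:
            raise ValueError(f"interval lower bound {lo} exceeds upper bound {hi}")

    # -- construction -------------------------------------------------
    @classmethod
    def point(cls, value: Number) -> "Interval":
        """Degenerate interval representing a scalar."""
        return cls(float(value), float(value))

    @classmethod
    def coerce(cls, value: "IntervalLike") -> "Interval":
        """Accept an Interval, a scalar, a 2-sequence or a mapping with
        ``lower``/``upper`` keys."""
        if isinstance(value, Interval):
            return value
        if isinstance(value, Mapping):
            return cls(float(value["lower"]), float(value["upper"]))
        if isinstance(value, (int, float)):
            return cls.point(value)
        try:
            lo, hi = value  # type: ignore[misc]
        except (TypeError, ValueError) as exc:
            raise TypeError(f"cannot interpret {value!r} as an interval") from exc
        return cls(float(lo), float(hi))

    # -- predicates & summaries ---------------------------------------
    @property
    def is_point(self) -> bool:
        return self.lower == self.upper

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.lower + self.upper)

    @property
    def width(self) -> float:
        return self.upper - self.lower

    def contains(self, x: Number) -> bool:
        return self.lower <= float(x) <= self.upper

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other: "IntervalLike") -> "Interval":
        o = Interval.coerce(other)
        return Interval(self.lower + o.lower, self.upper + o.upper)

    __radd__ = __add__

    def __neg__(self) -> "Interval":
        return Interval(-self.upper, -self.lower)

    def scale(self, factor: Number) -> "Interval":
        """Multiply by a scalar; a negative factor swaps the bounds so the
        result is still the set image."""
        f = float(factor)
        a, b = self.lower * f, self.upper * f
        return Interval(min(a, b), max(a, b))

    def __mul__(self, factor: Number) -> "Interval":
        return self.scale(factor)

    __rmul__ = __mul__

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        if self.is_point:
            return f"{self.lower:g}"
        return f"[{self.lower:g}, {self.upper:g}]"


IntervalLike = Union[Interval, Number, Mapping[str, Number], tuple, list]

ZERO = Interval.point(0.0)
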