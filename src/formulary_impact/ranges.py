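"""Bounded-range arithmetic with coupled-scenario semantics.

Every ranged quantity in the impact model — a prevalence, a discontinuation
rate, a patient count — is carried as a :class:`BoundedRange`, a low/high pair
in which each bound belongs to a coherent scenario: the low bound of every
input is evaluated together (the optimistic scenario), and likewise the high
bound (the pessimistic scenario).  This is *not* interval arithmetic: a
complement ``1 - d`` is evaluated at the same scenario's value of ``d``, so
the resulting pair may be numerically decreasing.  The true min/max over all
bound combinations is available separately as a conservative envelope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Union

__all__ = [
    "BoundedRange",
    "ScenarioAlignedPair",
    "scenario_product",
    "coupled_compound_rate",
    "conservative_envelope",
    "complement",
]

Rangeable = Union["BoundedRange", int, float]


@dataclass(frozen=True)
class BoundedRange:
    """A nonnegative low/high pair representing coupled optimistic and
    pessimistic scenario values of a single quantity.

    Invariants: ``0 <= low <= high``, both finite.  Scalars are modelled as
    degenerate ranges (``low == high``).
    """

    low: float
    high: float

    def __post_init__(self) -> None:
        low, high = float(self.low), float(self.high)
        if not (math.isfinite(low) and math.isfinite(high)):
            raise ValueError(f"bounds must be finite, got [{self.low}, {self.high}]")
        if low < 0:
            raise ValueError(f"bounds must be nonnegative, got low={low}")
        if low > high:
            raise ValueError(f"low must not exceed high, got [{low}, {high}]")
        object.__setattr__(self, "low", low)
        object.__setattr__(self, "high", high)

    @classmethod
    def coerce(cls, value: Rangeable) -> "BoundedRange":
        """Promote a scalar to a degenerate range; pass ranges through."""
        if isinstance(value, BoundedRange):
            return value
        return cls(float(value), float(value))

    @property
    def width(self) -> float:
        return self.high - self.low

    @property
    def is_degenerate(self) -> bool:
        return self.low == self.high

    def is_fraction(self) -> bool:
        """True when the range lies inside the unit interval."""
        return 0.0 <= self.low and self.high <= 1.0

    def scale(self, c: float) -> "BoundedRange":
        """Multiply both bounds by a nonnegative scalar."""
        if c < 0:
            raise ValueError(f"scale factor must be nonnegative, got {c}")
        return BoundedRange(self.low * c, self.high * c)

    def __iter__(self):
        yield self.low
        yield self.high

    def approx_equal(self, other: "BoundedRange", abs_tol: float = 1e-9) -> bool:
        return (
            abs(self.low - other.low) <= abs_tol
            and abs(self.high - other.high) <= abs_tol
        )

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.low:g}, {self.high:g}]"


class ScenarioAlignedPair(NamedTuple):
    """A (value-at-low-scenario, value-at-high-scenario) pair that keeps the
    scenario labels of its parent range but is *not* required to be
    increasing — the complement of a fraction range is the canonical case.
    """

    at_low: float
    at_high: float


def scenario_product(factors: Iterable[Rangeable]) -> BoundedRange:
    """Bound-wise product of nonnegative ranged factors.

    The low bound of the result is the product of all low bounds and the high
    bound the product of all highs.  Because the product of nonnegative
    factors is monotone in each factor, this coincides with the true min/max
    over all bound combinations (corner enumeration) — a fact the test suite
    exploits as an oracle.

    Raises ``ValueError`` naming the offending factor if any is negative.
    """
    low = 1.0
    high = 1.0
    for i, factor in enumerate(factors):
        if not isinstance(factor, BoundedRange):
            if float(factor) < 0:
                raise ValueError(f"factor {i} is negative: {factor}")
            factor = BoundedRange.coerce(factor)
        low *= factor.low
        high *= factor.high
    return BoundedRange(low, high)


def _require_fraction(name: str, r: BoundedRange) -> None:
    if not r.is_fraction():
        raise ValueError(f"{name} must lie in [0, 1], got [{r.low}, {r.high}]")


def coupled_compound_rate(
    d: BoundedRange, e: BoundedRange, s: BoundedRange
) -> BoundedRange:
    """Compound adverse-event rate ``e*d + s*(1 - d)`` evaluated bound-wise.

    ``d`` is the discontinuation fraction, ``e`` the event rate among
    discontinuers, ``s`` the event rate among switchers.  Each bound of the
    result evaluates the whole expression at that scenario's bounds, with the
    complement ``1 - d`` taken at the *same* scenario — the low bound uses
    ``1 - d.low``, not the interval-arithmetic corner.

    Scenario coupling preserves the bound order whenever ``e.low >= s.low``
    (discontinuing carries at least the risk of switching, the situation the
    rule models); otherwise the optimistic scenario can yield the *higher*
    rate and the coupled pair is rejected — use the conservative envelope
    for such inputs.
    """
    _require_fraction("discontinuation fraction d", d)
    _require_fraction("event-given-discontinuation rate e", e)
    _require_fraction("event-given-switch rate s", s)
    low = e.low * d.low + s.low * (1.0 - d.low)
    high = e.high * d.high + s.high * (1.0 - d.high)
    # convex combinations of fractions: clamp float spill past the unit
    # interval and snap ulp-level inversions of mathematically equal bounds
    low, high = min(max(low, 0.0), 1.0), min(max(high, 0.0), 1.0)
    if 0.0 < low - high <= 1e-12:
        low = high
    if low > high:
        raise ValueError(
            "coupled scenarios are inverted (the optimistic bound "
            f"{low:.6g} exceeds the pessimistic bound {high:.6g}); this "
            "happens when the switch event rate dominates the "
            "discontinuation event rate — use conservative_envelope instead"
        )
    return BoundedRange(low, high)


def conservative_envelope(
    d: BoundedRange, e: BoundedRange, s: BoundedRange
) -> BoundedRange:
    """True min/max of ``e*d + s*(1 - d)`` over the box ``d x e x s``.

    The expression is multilinear, so its extrema over the box are attained
    at corners; all eight corners are enumerated.  Always contains the
    coupled rate for the same inputs.
    """
    _require_fraction("discontinuation fraction d", d)
    _require_fraction("event-given-discontinuation rate e", e)
    _require_fraction("event-given-switch rate s", s)
    values = [
        eb * db + sb * (1.0 - db)
        for db in (d.low, d.high)
        for eb in (e.low, e.high)
        for sb in (s.low, s.high)
    ]
    return BoundedRange(min(values), max(values))


def complement(f: BoundedRange) -> ScenarioAlignedPair:
    """Scenario-aligned complement ``1 - f`` of a fraction range.

    Returns the pair (1 - f.low, 1 - f.high): the first element belongs to
    the low scenario, the second to the high scenario.  Numerically the pair
    is decreasing whenever ``f`` has positive width, which is why it is
    returned as a :class:`ScenarioAlignedPair` rather than a
    :class:`BoundedRange`.
    """
    _require_fraction("fraction", f)
    return ScenarioAlignedPair(1.0 - f.low, 1.0 - f.high)
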