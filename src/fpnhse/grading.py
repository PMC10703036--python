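"""Scalar grade transformations.

Three conversions drive the whole method:

* a prescribed clinical value is normalized to a fuzzy grade by dividing by
  the largest prescribed value of its attribute (``normalize_attribute_value``);
* the spread of an attribute's normalized grade range is halved to give the
  fuzzy parameterized degree chi attached to a sub-attribute tuple
  (``fuzzy_parameterized_grade``), so chi lies in [0, 0.5] by construction;
* an expert's neutrosophic judgement (t, i, f) is collapsed to a single fuzzy
  value |t - i - f| / 3 (``neutrosophic_to_fuzzy``), whose range is [0, 2/3].

Published worked examples of this method tacitly round intermediate values
(two decimals after reduction, four after weighting); ``RoundingPolicy``
makes that behaviour explicit and optional.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import TYPE_CHECKING

if TYPE_CHECKING:  # pragma: no cover
    from .model import AttributeSpec, NeutrosophicTriplet

__all__ = [
    "RoundingPolicy",
    "PAPER",
    "FULL",
    "round_half_up",
    "normalize_attribute_value",
    "fuzzy_parameterized_grade",
    "neutrosophic_to_fuzzy",
    "chi_from_spec",
]


def round_half_up(x: float, decimals: int) -> float:
    """Round to ``decimals`` places with ties going away from zero.

    Goes through ``Decimal(repr(x))`` so the decision is made on the shortest
    decimal representation of ``x``, not on its binary expansion (0.375 -> 0.38,
    0.275 -> 0.28).
    """
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class RoundingPolicy:
    """How intermediate values are rounded.

    mode
        ``"paper"`` rounds half-up: fuzzy-stage values (reductions, chi) to
        ``decimals_fuzzy`` places, weighted/composed values to
        ``decimals_weighted`` places. ``"full"`` disables all rounding.
    """

    mode: str = "paper"
    decimals_fuzzy: int = 2
    decimals_weighted: int = 4

    def __post_init__(self) -> None:
        if self.mode not in ("paper", "full"):
            raise ValueError(f"unknown rounding mode {self.mode!r}")
        if self.decimals_fuzzy < 0 or self.decimals_weighted < 0:
            raise ValueError("decimals must be non-negative")

    def fuzzy(self, x: float) -> float:
        if self.mode == "full":
            return x
        return round_half_up(x, self.decimals_fuzzy)

    def weighted(self, x: float) -> float:
        if self.mode == "full":
            return x
        return round_half_up(x, self.decimals_weighted)


PAPER = RoundingPolicy("paper")
FULL = RoundingPolicy("full")


def normalize_attribute_value(
    v: float, spec: "AttributeSpec", decimals: int | None = None
) -> float:
    """Fuzzy grade of a prescribed value: ``v`` divided by the attribute's
    largest prescribed value.

    Discrete attributes use their maximum level as denominator, range
    attributes their upper bound. Full precision unless ``decimals`` given.
    """
    lo, hi = spec.bounds()
    if hi <= 0:
        raise ValueError(
            f"attribute {spec.name!r}: cannot normalize with max prescribed value {hi}"
        )
    if spec.kind == "discrete":
        if v not in spec.prescribed_values:
            raise ValueError(
                f"attribute {spec.name!r}: value {v} is not a prescribed level"
            )
    elif not lo <= v <= hi:
        raise ValueError(
            f"attribute {spec.name!r}: value {v} outside prescribed range [{lo}, {hi}]"
        )
    g = v / hi
    return g if decimals is None else round_half_up(g, decimals)


def fuzzy_parameterized_grade(
    mu_max: float, mu_min: float, policy: RoundingPolicy = PAPER
) -> float:
    """Parameterized degree chi = (mu_max - mu_min) / 2 of a grade range."""
    if not (0.0 <= mu_min <= 1.0 and 0.0 <= mu_max <= 1.0):
        raise ValueError("fuzzy grades must lie in [0, 1]")
    if mu_max < mu_min:
        raise ValueError(f"mu_max ({mu_max}) must be >= mu_min ({mu_min})")
    return policy.fuzzy((mu_max - mu_min) / 2.0)


def neutrosophic_to_fuzzy(
    n: "NeutrosophicTriplet", policy: RoundingPolicy = PAPER
) -> float:
    """Reduce a neutrosophic triplet to the fuzzy value |t - i - f| / 3."""
    problems = n.violations()
    if problems:
        raise ValueError("; ".join(problems))
    return policy.fuzzy(abs(n.t - n.f - n.i) / 3.0)


def chi_from_spec(spec: "AttributeSpec", policy: RoundingPolicy = PAPER) -> float:
    """Parameterized degree of an attribute's full prescribed grade range.

    Normalizes the extreme prescribed values at full precision and applies
    the chi formula, rounding once at the end. Deriving chi from already
    rounded grades would shift several published degrees by one unit in the
    second decimal (e.g. a minimum level of 1 out of 3 gives chi = 1/3 ->
    0.33, whereas the 2-dp grade 0.33 would give 0.335 -> 0.34).
    """
    lo, hi = spec.bounds()
    mu_min = normalize_attribute_value(lo, spec)
    mu_max = normalize_attribute_value(hi, spec)
    return fuzzy_parameterized_grade(mu_max, mu_min, policy)
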