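"""Core data model for fuzzy-parameterized neutrosophic hypersoft expert sets.

An FpNHse-set records, for every (sub-attribute tuple, expert, opinion)
triple, a neutrosophic approximation over a universe of alternatives
(here: patients), together with a fuzzy parameterized degree chi attached to
each tuple. The tuple space is the Cartesian product of disjoint
sub-attribute value sets, one per attribute.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

__all__ = [
    "AttributeSpec",
    "SubAttributeValueSet",
    "MultiArgumentTuple",
    "TupleSpace",
    "Expert",
    "OPINIONS",
    "NeutrosophicTriplet",
    "FpNHseSet",
    "Violation",
    "build_tuple_space",
    "build_assessment_domain",
    "restrict_by_opinion",
    "validate",
    "collapse_opinions",
]

#: Admissible opinion values: 0 = disagree, 1 = agree.
OPINIONS: tuple[int, int] = (0, 1)


@dataclass(frozen=True)
class AttributeSpec:
    """One clinical attribute with its prescribed value domain.

    kind ``"discrete"`` enumerates levels in ``prescribed_values``;
    kind ``"range"`` stores ``(min, max)`` numeric bounds. ``selected_values``
    are the sub-attribute values chosen for a particular case and must lie in
    the prescribed domain.
    """

    name: str
    kind: str  # "discrete" | "range"
    prescribed_values: tuple[float, ...]
    selected_values: tuple[float, ...] = ()
    units: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "prescribed_values", tuple(self.prescribed_values))
        object.__setattr__(self, "selected_values", tuple(self.selected_values))
        if self.kind not in ("discrete", "range"):
            raise ValueError(f"attribute {self.name!r}: unknown kind {self.kind!r}")
        if self.kind == "range":
            if len(self.prescribed_values) != 2:
                raise ValueError(
                    f"attribute {self.name!r}: range kind needs (min, max) bounds"
                )
            lo, hi = self.prescribed_values
            if not lo < hi:
                raise ValueError(f"attribute {self.name!r}: range needs min < max")
            if hi <= 0:
                raise ValueError(f"attribute {self.name!r}: range max must be > 0")
        elif not self.prescribed_values:
            raise ValueError(f"attribute {self.name!r}: no prescribed levels")
        for v in self.selected_values:
            if not self.contains(v):
                raise ValueError(
                    f"attribute {self.name!r}: selected value {v} outside prescribed domain"
                )

    def bounds(self) -> tuple[float, float]:
        """(min, max) of the prescribed domain."""
        if self.kind == "range":
            return self.prescribed_values[0], self.prescribed_values[1]
        return min(self.prescribed_values), max(self.prescribed_values)

    def contains(self, v: float) -> bool:
        if self.kind == "discrete":
            return v in self.prescribed_values
        lo, hi = self.prescribed_values
        return lo <= v <= hi


@dataclass(frozen=True)
class SubAttributeValueSet:
    """Ordered, pairwise-distinct sub-attribute values of one attribute."""

    attribute: str
    values: tuple = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", tuple(self.values))
        if not self.values:
            raise ValueError(f"attribute {self.attribute!r}: empty value set")
        if len(set(self.values)) != len(self.values):
            raise ValueError(f"attribute {self.attribute!r}: values must be distinct")

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class MultiArgumentTuple:
    """One sub-attribute value per attribute, in fixed attribute order."""

    components: tuple = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "components", tuple(self.components))

    def __len__(self) -> int:
        return len(self.components)


@dataclass(frozen=True)
class TupleSpace:
    """Cartesian product of sub-attribute value sets, enumerated
    lexicographically in declared attribute order."""

    attributes: tuple[SubAttributeValueSet, ...]
    tuples: tuple[MultiArgumentTuple, ...]

    def __len__(self) -> int:
        return len(self.tuples)


@dataclass(frozen=True)
class Expert:
    id: str


@dataclass(frozen=True)
class NeutrosophicTriplet:
    """Single-valued neutrosophic grade: truth, indeterminacy, falsity.

    Each component lies in [0, 1]; the components are independent, so their
    sum may reach 3. Construction never raises — invalid triplets can be
    represented so that :func:`validate` can report them.
    """

    t: float
    i: float
    f: float

    def violations(self) -> list[str]:
        out = []
        for name, v in (("t", self.t), ("i", self.i), ("f", self.f)):
            if not 0.0 <= v <= 1.0:
                out.append(f"{name}={v} outside [0, 1]")
        return out

    def is_valid(self) -> bool:
        return not self.violations()

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.t, self.i, self.f)


#: Approximation key: (tuple, expert id, opinion).
AssessmentKey = tuple[MultiArgumentTuple, str, int]


@dataclass
class FpNHseSet:
    """Fuzzy-parameterized neutrosophic hypersoft expert set.

    ``approximations`` maps (tuple, expert id, opinion) to a mapping from
    alternative label to neutrosophic triplet; ``degrees`` holds the fuzzy
    parameterized degree chi of each tuple.
    """

    universe: tuple[str, ...]
    tuple_space: TupleSpace
    experts: tuple[Expert, ...]
    degrees: dict[MultiArgumentTuple, float] = field(default_factory=dict)
    approximations: dict[AssessmentKey, dict[str, NeutrosophicTriplet]] = field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        self.universe = tuple(self.universe)
        self.experts = tuple(self.experts)
        ids = [e.id for e in self.experts]
        if len(set(ids)) != len(ids):
            raise ValueError("expert ids must be unique within a panel")


@dataclass(frozen=True)
class Violation:
    """One broken invariant, with enough location to find it."""

    location: str
    message: str


def build_tuple_space(
    attribute_sets: Sequence[SubAttributeValueSet],
) -> TupleSpace:
    """Enumerate the full Cartesian product of the given value sets.

    Order is lexicographic in declared attribute order (last attribute varies
    fastest), hence deterministic.
    """
    if not attribute_sets:
        raise ValueError("need at least one sub-attribute value set")
    for s in attribute_sets:
        if not s.values:  # unreachable via constructor, kept for raw inputs
            raise ValueError(f"attribute {s.attribute!r}: empty value set")
    tuples = tuple(
        MultiArgumentTuple(combo)
        for combo in itertools.product(*(s.values for s in attribute_sets))
    )
    return TupleSpace(attributes=tuple(attribute_sets), tuples=tuples)


def build_assessment_domain(
    tuples: Iterable[MultiArgumentTuple],
    experts: Iterable[Expert],
    opinions: Iterable[int] = OPINIONS,
) -> list[AssessmentKey]:
    """Cartesian product tuples x experts x opinions, in that nesting order."""
    tuples = list(tuples)
    experts = list(experts)
    opinions = list(opinions)
    if not tuples or not experts or not opinions:
        raise ValueError("tuples, experts and opinions must all be non-empty")
    for o in opinions:
        if o not in OPINIONS:
            raise ValueError(f"opinion {o!r} not in {OPINIONS}")
    return [
        (tup, e.id, o) for tup in tuples for e in experts for o in opinions
    ]


def restrict_by_opinion(s: FpNHseSet, opinion: int) -> FpNHseSet:
    """Copy of ``s`` keeping only approximations carrying the given opinion."""
    if opinion not in OPINIONS:
        raise ValueError(f"opinion {opinion!r} not in {OPINIONS}")
    kept = {k: dict(v) for k, v in s.approximations.items() if k[2] == opinion}
    return replace(s, degrees=dict(s.degrees), approximations=kept)


def validate(s: FpNHseSet) -> list[Violation]:
    """Report every broken invariant of ``s``; empty list iff valid."""
    out: list[Violation] = []
    tuple_set = set(s.tuple_space.tuples)
    expert_ids = {e.id for e in s.experts}
    universe = set(s.universe)

    for tup, chi in s.degrees.items():
        where = f"degrees[{tup.components}]"
        if tup not in tuple_set:
            out.append(Violation(where, "tuple not in tuple space"))
        if not 0.0 <= chi <= 1.0:
            out.append(Violation(where, f"degree {chi} outside [0, 1]"))

    for (tup, eid, op), approx in s.approximations.items():
        where = f"approximations[({tup.components}, {eid!r}, {op})]"
        if tup not in tuple_set:
            out.append(Violation(where, "tuple not in tuple space"))
        if eid not in expert_ids:
            out.append(Violation(where, f"unknown expert {eid!r}"))
        if op not in OPINIONS:
            out.append(Violation(where, f"opinion {op!r} not in {OPINIONS}"))
        if tup in tuple_set and tup not in s.degrees:
            out.append(Violation(where, "tuple has no parameterized degree chi"))
        for alt, trip in approx.items():
            if alt not in universe:
                out.append(Violation(f"{where}[{alt!r}]", "alternative not in universe"))
            for msg in trip.violations():
                out.append(Violation(f"{where}[{alt!r}]", msg))
    return out


def _mean_triplet(trips: Sequence[NeutrosophicTriplet]) -> NeutrosophicTriplet:
    n = len(trips)
    return NeutrosophicTriplet(
        sum(x.t for x in trips) / n,
        sum(x.i for x in trips) / n,
        sum(x.f for x in trips) / n,
    )


def collapse_opinions(
    s: FpNHseSet,
) -> tuple[
    Mapping[tuple[str, MultiArgumentTuple], NeutrosophicTriplet],
    Mapping[tuple[MultiArgumentTuple, str], NeutrosophicTriplet],
]:
    """Reduce an FpNHse-set to the two opinion-free matrices the ranking
    pipeline consumes.

    The agree-restricted (opinion = 1) entries are used where present; keys
    with no agree entry fall back to all their entries. The patients x tuples
    matrix averages each tuple's triplets over experts; the tuples x experts
    matrix averages over the universe. Averaging is componentwise arithmetic
    mean, the least-committal symmetric aggregator.
    """
    agree = restrict_by_opinion(s, 1)
    source = dict(agree.approximations)
    for key, approx in s.approximations.items():
        tup, eid, _ = key
        if not any(k[0] == tup and k[1] == eid for k in source):
            source[key] = approx

    pat: dict[tuple[str, MultiArgumentTuple], NeutrosophicTriplet] = {}
    exp: dict[tuple[MultiArgumentTuple, str], NeutrosophicTriplet] = {}
    for alt in s.universe:
        for tup in s.tuple_space.tuples:
            trips = [
                a[alt] for k, a in source.items() if k[0] == tup and alt in a
            ]
            if trips:
                pat[(alt, tup)] = _mean_triplet(trips)
    for tup in s.tuple_space.tuples:
        for e in s.experts:
            trips = [
                t
                for k, a in source.items()
                if k[0] == tup and k[1] == e.id
                for t in a.values()
            ]
            if trips:
                exp[(tup, e.id)] = _mean_triplet(trips)
    return pat, exp
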