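"""Seeded generator of Cleveland-like FpNHse cases.

Emulates the structure of the worked example — p patients, q sub-attribute
tuples, r experts, a chi degree per tuple and neutrosophic assessments for
every (tuple, expert, opinion) key — at configurable dimensions, so every
pipeline stage is testable without external data. Default dimensions are the
worked example's 6 x 8 x 4.

Triplet laws:

* ``uniform-box`` (default): t, i, f i.i.d. uniform on [0, 1]; the
  single-valued neutrosophic convention allows t + i + f up to 3.
* ``constrained``: uniform on the simplex t + i + f <= 1, for experiments
  under the stricter dependent-membership reading.

chi laws: ``uniform`` draws chi uniformly on (0, 0.5]; ``from-ranges`` draws
a random normalized value range per tuple and applies the (max - min) / 2
degree formula, mirroring how degrees arise from attribute ranges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grading import FULL, fuzzy_parameterized_grade
from .model import (
    Expert,
    FpNHseSet,
    MultiArgumentTuple,
    NeutrosophicTriplet,
    SubAttributeValueSet,
    TupleSpace,
)
from .sanchez import AssessmentMatrix

__all__ = ["GeneratorConfig", "SyntheticCase", "generate_case"]

TRIPLET_LAWS = ("uniform-box", "constrained")
CHI_LAWS = ("uniform", "from-ranges")


@dataclass(frozen=True)
class GeneratorConfig:
    n_patients: int = 6
    n_tuples: int = 8
    n_experts: int = 4
    seed: int = 0
    triplet_law: str = "uniform-box"
    chi_law: str = "uniform"

    def __post_init__(self) -> None:
        for name in ("n_patients", "n_tuples", "n_experts"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.triplet_law not in TRIPLET_LAWS:
            raise ValueError(
                f"unknown triplet law {self.triplet_law!r}; choose from {TRIPLET_LAWS}"
            )
        if self.chi_law not in CHI_LAWS:
            raise ValueError(
                f"unknown chi law {self.chi_law!r}; choose from {CHI_LAWS}"
            )


@dataclass
class SyntheticCase:
    """A generated case: the expert set, the two pipeline matrices, chi."""

    expert_set: FpNHseSet
    assessment_patients: AssessmentMatrix  # p x q
    assessment_experts: AssessmentMatrix  # q x r
    chi: dict[str, float]


def _triplet(rng: np.random.Generator, law: str) -> NeutrosophicTriplet:
    if law == "uniform-box":
        t, i, f = rng.uniform(0.0, 1.0, size=3)
    else:  # uniform on the simplex t + i + f <= 1
        t, i, f = np.diff(np.concatenate([[0.0], np.sort(rng.uniform(0.0, 1.0, 3))]))
    return NeutrosophicTriplet(float(t), float(i), float(f))


def _chi(rng: np.random.Generator, law: str) -> float:
    if law == "uniform":
        return float(0.5 * (1.0 - rng.random()))  # uniform on (0, 0.5]
    lo, hi = np.sort(rng.uniform(0.0, 1.0, size=2))
    return fuzzy_parameterized_grade(float(hi), float(lo), FULL)


def generate_case(cfg: GeneratorConfig) -> SyntheticCase:
    """Generate a random case; identical output for identical config."""
    rng = np.random.default_rng(cfg.seed)
    patients = tuple(f"P{k + 1}" for k in range(cfg.n_patients))
    tuple_labels = tuple(f"v{j + 1}" for j in range(cfg.n_tuples))
    experts = tuple(Expert(f"DM{k + 1}") for k in range(cfg.n_experts))

    # one synthetic discrete attribute whose q levels index the tuples
    value_set = SubAttributeValueSet("synthetic_attribute", tuple_labels)
    tuples = tuple(MultiArgumentTuple((lab,)) for lab in tuple_labels)
    space = TupleSpace(attributes=(value_set,), tuples=tuples)

    chi = {lab: _chi(rng, cfg.chi_law) for lab in tuple_labels}
    degrees = {tup: chi[lab] for lab, tup in zip(tuple_labels, tuples)}

    approximations = {}
    for tup in tuples:
        for e in experts:
            for opinion in (0, 1):
                approximations[(tup, e.id, opinion)] = {
                    p: _triplet(rng, cfg.triplet_law) for p in patients
                }
    expert_set = FpNHseSet(
        universe=patients,
        tuple_space=space,
        experts=experts,
        degrees=degrees,
        approximations=approximations,
    )

    w_pat = AssessmentMatrix(
        row_labels=patients,
        col_labels=tuple_labels,
        cells=tuple(
            tuple(_triplet(rng, cfg.triplet_law) for _ in tuple_labels)
            for _ in patients
        ),
    )
    w_exp = AssessmentMatrix(
        row_labels=tuple_labels,
        col_labels=tuple(e.id for e in experts),
        cells=tuple(
            tuple(_triplet(rng, cfg.triplet_law) for _ in experts)
            for _ in tuple_labels
        ),
    )
    return SyntheticCase(expert_set, w_pat, w_exp, chi)
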