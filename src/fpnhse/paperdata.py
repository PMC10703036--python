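"""Packaged worked example: a 6-patient / 8-tuple / 4-expert heart-disease
case built on Cleveland-dataset attribute ranges.

All tables are stored exactly as published ("as-printed"). The published
tables contain a number of arithmetic slips; every cell whose printed value
disagrees with the method's own formulas is listed in :data:`ERRATA` with
both values, so tests and the verification command can assert the formula on
clean cells and flag the slips. The fixture is checksum-verified on load.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import pandas as pd

from .model import (
    AttributeSpec,
    Expert,
    FpNHseSet,
    NeutrosophicTriplet,
    SubAttributeValueSet,
    build_tuple_space,
)
from .sanchez import AssessmentMatrix

__all__ = ["PaperFixture", "Erratum", "ERRATA", "load_paper_fixture", "example_expert_set"]

PATIENTS = ("P1", "P2", "P24", "P25", "P75", "P303")
TUPLES = ("v1", "v2", "v3", "v4", "v5", "v6", "v7", "v8")
EXPERTS = ("DM1", "DM2", "DM3", "DM4")

# Cleveland-dataset attribute domains, one per sub-attribute tuple, in the
# order the tuples' degree table lists them: chest pain levels, resting blood
# pressure, ST slope, maximum heart rate, thallium scan result, serum
# cholesterol, fasting blood sugar, exercise-induced ST depression.
ATTRIBUTES = (
    AttributeSpec("chest_pain_type", "discrete", (1, 2, 3, 4)),
    AttributeSpec("resting_blood_pressure", "range", (90, 200), units="mmHg"),
    AttributeSpec("slope", "discrete", (1, 2, 3)),
    AttributeSpec("max_heart_rate", "range", (71, 195), units="bpm"),
    AttributeSpec("thal", "discrete", (3, 6, 7)),
    AttributeSpec("serum_cholesterol", "range", (126, 564), units="mg/dL"),
    AttributeSpec("fasting_blood_sugar", "discrete", (0, 120), units="mg/dL"),
    AttributeSpec("oldpeak", "range", (0.0, 5.6), units="mm"),
)

#: Parameterized degree chi per tuple, as printed.
CHI = dict(zip(TUPLES, (0.38, 0.28, 0.33, 0.32, 0.29, 0.36, 0.5, 0.5)))

# Neutrosophic patients x tuples matrix; only the first four tuple columns
# were published, so reduction is only verifiable there.
W1_TRIPLETS = {
    "P1": [(0.4, 0.6, 0.1), (0.3, 0.4, 0.5), (0.4, 0.6, 0.1), (0.6, 0.2, 0.3)],
    "P2": [(0.4, 0.5, 0.3), (0.6, 0.1, 0.9), (0.8, 0.4, 0.2), (0.5, 0.4, 0.2)],
    "P24": [(0.3, 0.7, 0.1), (0.2, 0.7, 0.3), (0.5, 0.3, 0.4), (0.9, 0.3, 0.1)],
    "P25": [(0.4, 0.6, 0.1), (0.1, 0.3, 0.9), (0.8, 0.1, 0.4), (0.2, 0.7, 0.3)],
    "P75": [(0.3, 0.9, 0.8), (0.2, 0.5, 0.6), (0.9, 0.3, 0.4), (0.8, 0.3, 0.1)],
    "P303": [(0.2, 0.5, 0.6), (0.3, 0.4, 0.7), (0.5, 0.4, 0.2), (0.3, 0.3, 0.5)],
}

# Neutrosophic tuples x experts matrix (complete).
W2_TRIPLETS = {
    "v1": [(0.6, 0.3, 0.2), (0.4, 0.2, 0.5), (0.4, 0.3, 0.5), (0.6, 0.2, 0.3)],
    "v2": [(0.4, 0.5, 0.3), (0.6, 0.6, 0.9), (0.9, 0.4, 0.2), (0.5, 0.4, 0.2)],
    "v3": [(0.5, 0.6, 0.1), (0.7, 0.3, 0.1), (0.5, 0.3, 0.3), (0.7, 0.3, 0.1)],
    "v4": [(0.9, 0.3, 0.1), (0.5, 0.8, 0.4), (0.2, 0.7, 0.5), (0.4, 0.5, 0.3)],
    "v5": [(0.2, 0.3, 0.8), (0.9, 0.3, 0.1), (0.2, 0.9, 0.1), (0.6, 0.3, 0.1)],
    "v6": [(0.9, 0.2, 0.1), (0.2, 0.7, 0.6), (0.4, 0.3, 0.6), (0.2, 0.9, 0.2)],
    "v7": [(0.7, 0.3, 0.5), (0.3, 0.6, 0.2), (0.7, 0.4, 0.1), (0.3, 0.7, 0.1)],
    "v8": [(0.4, 0.5, 0.3), (0.7, 0.3, 0.5), (0.2, 0.3, 0.6), (0.4, 0.3, 0.4)],
}

# Fuzzy patients x tuples matrix, as printed (all eight columns).
F_PAT = {
    "P1": [0.1, 0.2, 0.1, 0.03, 0.1, 0.1, 0.1, 0.03],
    "P2": [0.13, 0.13, 0.07, 0.03, 0.13, 0.13, 0.07, 0.17],
    "P24": [0.17, 0.27, 0.07, 0.17, 0.1, 0.13, 0.13, 0.17],
    "P25": [0.17, 0.37, 0.1, 0.27, 0.03, 0.13, 0.13, 0.03],
    "P75": [0.47, 0.3, 0.07, 0.13, 0.03, 0.07, 0.07, 0.07],
    "P303": [0.3, 0.27, 0.03, 0.17, 0.37, 0.23, 0.23, 0.13],
}

# Fuzzy tuples x experts matrix, as printed.
F_EXP = {
    "v1": [0.03, 0.1, 0.2, 0.03],
    "v2": [0.13, 0.3, 0.23, 0.03],
    "v3": [0.07, 0.3, 0.03, 0.1],
    "v4": [0.17, 0.23, 0.03, 0.13],
    "v5": [0.3, 0.17, 0.27, 0.07],
    "v6": [0.2, 0.37, 0.17, 0.3],
    "v7": [0.03, 0.17, 0.13, 0.17],
    "v8": [0.13, 0.03, 0.23, 0.17],
}

# chi-weighted matrices, as printed.
WF_PAT = {
    "P1": [0.038, 0.056, 0.033, 0.0096, 0.029, 0.036, 0.05, 0.015],
    "P2": [0.0494, 0.0364, 0.0231, 0.0096, 0.0377, 0.0468, 0.035, 0.085],
    "P24": [0.0646, 0.0756, 0.0231, 0.0544, 0.029, 0.0468, 0.065, 0.085],
    "P25": [0.0646, 0.1036, 0.033, 0.0864, 0.0087, 0.0468, 0.065, 0.015],
    "P75": [0.1786, 0.084, 0.0231, 0.0416, 0.0087, 0.0252, 0.035, 0.035],
    "P303": [0.0114, 0.0756, 0.0099, 0.0544, 0.1073, 0.0828, 0.115, 0.065],
}
WF_EXP = {
    "v1": [0.0114, 0.038, 0.076, 0.0114],
    "v2": [0.0364, 0.084, 0.0644, 0.0084],
    "v3": [0.0231, 0.099, 0.0099, 0.033],
    "v4": [0.0544, 0.0746, 0.0096, 0.0416],
    "v5": [0.087, 0.0493, 0.0783, 0.0203],
    "v6": [0.072, 0.1332, 0.0612, 0.108],
    "v7": [0.015, 0.085, 0.065, 0.085],
    "v8": [0.065, 0.015, 0.115, 0.085],
}

# Composed patients x experts diagnosis matrix, as printed.
DIAGNOSIS = {
    "P1": [0.0260, 0.0208, 0.0164, 0.0124],
    "P2": [0.0156, 0.0203, 0.0243, 0.0181],
    "P24": [0.0194, 0.0296, 0.0297, 0.0228],
    "P25": [0.0160, 0.0333, 0.0222, 0.0183],
    "P75": [0.0133, 0.0265, 0.0281, 0.0141],
    "P303": [0.0273, 0.0389, 0.0348, 0.0298],
}

#: Published final scores (row sums of the diagnosis matrix).
SCORES = {
    "P1": 0.0756, "P2": 0.0783, "P24": 0.1015,
    "P25": 0.0898, "P75": 0.0820, "P303": 0.1308,
}

#: Published ranking, highest risk first.
RANKING = ("P303", "P24", "P25", "P75", "P2", "P1")

#: Published sensitivity table: AM/GM/HM per patient, as printed.
SENSITIVITY = {
    "am": dict(zip(PATIENTS, (0.0189, 0.0196, 0.0253, 0.0224, 0.0205, 0.0327))),
    "gm": dict(zip(PATIENTS, (0.0182, 0.0193, 0.0249, 0.0215, 0.0197, 0.0323))),
    "hm": dict(zip(PATIENTS, (0.0175, 0.0182, 0.0245, 0.0208, 0.0191, 0.0320))),
}


@dataclass(frozen=True)
class Erratum:
    """A printed cell whose value disagrees with the method's own formula."""

    table: str
    row: str
    col: str
    printed: float
    recomputed: float


#: Every printed cell that a recomputation sweep of all derivable cells
#: flags as inconsistent with the stated formulas (as-printed values are kept
#: verbatim in the tables above).
ERRATA: tuple[Erratum, ...] = (
    Erratum("chi", "v6", "", 0.36, 0.39),
    Erratum("fuzzy_patients", "P25", "v1", 0.17, 0.1),
    Erratum("fuzzy_experts", "v1", "DM3", 0.2, 0.13),
    Erratum("fuzzy_experts", "v2", "DM3", 0.23, 0.1),
    Erratum("fuzzy_experts", "v3", "DM2", 0.3, 0.1),
    Erratum("fuzzy_experts", "v4", "DM3", 0.03, 0.33),
    Erratum("fuzzy_experts", "v7", "DM3", 0.13, 0.07),
    Erratum("fuzzy_experts", "v8", "DM4", 0.17, 0.1),
    Erratum("weighted_patients", "P303", "v1", 0.0114, 0.114),
    Erratum("weighted_experts", "v4", "DM2", 0.0746, 0.0736),
    Erratum("diagnosis", "P1", "DM1", 0.0260, 0.0106),
    # The published GM/HM sensitivity entries for P2 and P75 are transposed:
    # recomputing from the printed diagnosis rows gives HM(P2) = 0.0191 and
    # HM(P75) = 0.0182, the printed values swapped.
    Erratum("sensitivity_gm", "P75", "", 0.0197, 0.0193),
    Erratum("sensitivity_hm", "P2", "", 0.0182, 0.0191),
    Erratum("sensitivity_hm", "P75", "", 0.0191, 0.0182),
)


@dataclass
class PaperFixture:
    """All published tables of the worked example, as printed."""

    attributes: tuple[AttributeSpec, ...]
    patients: tuple[str, ...]
    tuples: tuple[str, ...]
    experts: tuple[str, ...]
    chi: dict[str, float]
    assessment_patients: AssessmentMatrix  # patients x tuples (4 columns published)
    assessment_experts: AssessmentMatrix  # tuples x experts
    fuzzy_patients: pd.DataFrame
    fuzzy_experts: pd.DataFrame
    weighted_patients: pd.DataFrame
    weighted_experts: pd.DataFrame
    diagnosis: pd.DataFrame
    scores: dict[str, float]
    ranking: tuple[str, ...]
    sensitivity: pd.DataFrame  # index: patients; columns: am, gm, hm
    errata: tuple[Erratum, ...] = field(default=ERRATA)


def _canonical_blob() -> bytes:
    payload = {
        "chi": CHI, "w1": W1_TRIPLETS, "w2": W2_TRIPLETS,
        "f_pat": F_PAT, "f_exp": F_EXP, "wf_pat": WF_PAT, "wf_exp": WF_EXP,
        "diagnosis": DIAGNOSIS, "scores": SCORES, "ranking": RANKING,
        "sensitivity": SENSITIVITY,
    }
    return json.dumps(payload, sort_keys=True).encode()


_SHA256 = "341eb31562979e7d430e40c8a85738e43781212b02c7a4f07645b8986624d44b"


def load_paper_fixture() -> PaperFixture:
    """Build the fixture from the packaged constants, checksum-verified."""
    digest = hashlib.sha256(_canonical_blob()).hexdigest()
    if digest != _SHA256:
        raise RuntimeError(
            f"packaged worked-example tables are corrupted (sha256 {digest})"
        )

    def triplets(grid: dict, cols: tuple[str, ...]) -> AssessmentMatrix:
        return AssessmentMatrix(
            row_labels=tuple(grid),
            col_labels=cols,
            cells=tuple(
                tuple(NeutrosophicTriplet(*c) for c in row) for row in grid.values()
            ),
        )

    def frame(grid: dict, cols: tuple[str, ...]) -> pd.DataFrame:
        return pd.DataFrame.from_dict(grid, orient="index", columns=list(cols))

    return PaperFixture(
        attributes=ATTRIBUTES,
        patients=PATIENTS,
        tuples=TUPLES,
        experts=EXPERTS,
        chi=dict(CHI),
        assessment_patients=triplets(W1_TRIPLETS, TUPLES[:4]),
        assessment_experts=triplets(W2_TRIPLETS, EXPERTS),
        fuzzy_patients=frame(F_PAT, TUPLES),
        fuzzy_experts=frame(F_EXP, EXPERTS),
        weighted_patients=frame(WF_PAT, TUPLES),
        weighted_experts=frame(WF_EXP, EXPERTS),
        diagnosis=frame(DIAGNOSIS, EXPERTS),
        scores=dict(SCORES),
        ranking=RANKING,
        sensitivity=pd.DataFrame(SENSITIVITY).loc[list(PATIENTS)],
        errata=ERRATA,
    )


def example_expert_set() -> FpNHseSet:
    """Small illustrative FpNHse-set: four cardiac conditions assessed by two
    experts over four parameter tuples, two entries per opinion side."""
    cp = SubAttributeValueSet("chest_pain_type", ("typical angina", "atypical angina"))
    bp = SubAttributeValueSet("resting_blood_pressure", (150, 180))
    chol = SubAttributeValueSet("serum_cholesterol", (320,))
    space = build_tuple_space([cp, bp, chol])
    z1, z2, z3, z4 = space.tuples
    experts = (Expert("E1"), Expert("E2"))
    universe = ("C1", "C2", "C3", "C4")

    def approx(vals) -> dict[str, NeutrosophicTriplet]:
        return {u: NeutrosophicTriplet(*v) for u, v in zip(universe, vals)}

    return FpNHseSet(
        universe=universe,
        tuple_space=space,
        experts=experts,
        degrees={z1: 0.2, z2: 0.3, z3: 0.4, z4: 0.5},
        approximations={
            (z1, "E1", 1): approx([(0.5, 0.3, 0.4), (0.6, 0.2, 0.5),
                                   (0.3, 0.4, 0.4), (0.1, 0.7, 0.2)]),
            (z2, "E2", 0): approx([(0.4, 0.5, 0.2), (0.2, 0.7, 0.3),
                                   (0.6, 0.3, 0.5), (0.4, 0.6, 0.5)]),
            (z3, "E1", 0): approx([(0.7, 0.8, 0.3), (0.9, 0.2, 0.6),
                                   (0.3, 0.7, 0.6), (0.8, 0.1, 0.2)]),
            (z4, "E2", 1): approx([(0.3, 0.7, 0.9), (0.4, 0.8, 0.5),
                                   (0.7, 0.4, 0.5), (0.6, 0.7, 0.3)]),
        },
    )
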