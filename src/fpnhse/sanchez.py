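"""Modified Sanchez matrix method.

Two neutrosophic assessment matrices — patients x tuples (W1) and
tuples x experts (W2) — are reduced elementwise to fuzzy matrices, both are
weighted by the tuples' parameterized degrees chi (column-wise on the patient
side, row-wise on the expert side), the weighted matrices are composed by
ordinary sum-of-products matrix multiplication into a patients x experts
diagnosis matrix, and each patient's risk score is their row sum. Patients
are ranked by descending score; composition is the traditional matrix
product, not the max-min composition of classic fuzzy-relation diagnosis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .grading import PAPER, RoundingPolicy, neutrosophic_to_fuzzy
from .model import NeutrosophicTriplet

__all__ = [
    "AssessmentMatrix",
    "WeightedMatrix",
    "DiagnosisResult",
    "reduce_matrix",
    "weight_columns",
    "weight_rows",
    "compose_diagnosis",
    "final_scores",
    "rank_patients",
    "run_pipeline",
    "run_fuzzy_pipeline",
]


@dataclass
class AssessmentMatrix:
    """Labeled rectangular grid of neutrosophic triplets."""

    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    cells: tuple[tuple[NeutrosophicTriplet, ...], ...]

    def __post_init__(self) -> None:
        self.row_labels = tuple(self.row_labels)
        self.col_labels = tuple(self.col_labels)
        self.cells = tuple(tuple(row) for row in self.cells)
        if len(set(self.row_labels)) != len(self.row_labels):
            raise ValueError("row labels must be unique")
        if len(set(self.col_labels)) != len(self.col_labels):
            raise ValueError("column labels must be unique")
        if len(self.cells) != len(self.row_labels):
            raise ValueError(
                f"{len(self.cells)} cell rows for {len(self.row_labels)} row labels"
            )
        for r, row in zip(self.row_labels, self.cells):
            if len(row) != len(self.col_labels):
                raise ValueError(
                    f"row {r!r}: {len(row)} cells for {len(self.col_labels)} columns"
                )

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.row_labels), len(self.col_labels))

    def cell(self, row: str, col: str) -> NeutrosophicTriplet:
        return self.cells[self.row_labels.index(row)][self.col_labels.index(col)]


@dataclass
class WeightedMatrix:
    """Fuzzy matrix after chi-weighting, with the degrees that were applied."""

    values: pd.DataFrame
    degrees: dict[str, float] = field(default_factory=dict)


@dataclass
class DiagnosisResult:
    """Composed patients x experts matrix, per-patient scores and ranking,
    with every intermediate matrix retained for inspection."""

    matrix: pd.DataFrame
    scores: pd.Series
    ranking: list[str]
    intermediates: dict[str, pd.DataFrame] = field(default_factory=dict)


def reduce_matrix(
    m: AssessmentMatrix, policy: RoundingPolicy = PAPER
) -> pd.DataFrame:
    """Elementwise neutrosophic-to-fuzzy reduction |t - i - f| / 3."""
    data = []
    for r, row in zip(m.row_labels, m.cells):
        out_row = []
        for c, trip in zip(m.col_labels, row):
            try:
                out_row.append(neutrosophic_to_fuzzy(trip, policy))
            except ValueError as exc:
                raise ValueError(f"cell ({r!r}, {c!r}): {exc}") from exc
        data.append(out_row)
    return pd.DataFrame(data, index=list(m.row_labels), columns=list(m.col_labels))


def _check_chi(labels: Sequence[str], chi: Mapping[str, float]) -> None:
    missing = [lab for lab in labels if lab not in chi]
    if missing:
        raise KeyError(f"no parameterized degree chi for tuple(s) {missing}")


def weight_columns(
    f: pd.DataFrame, chi: Mapping[str, float], policy: RoundingPolicy = PAPER
) -> WeightedMatrix:
    """Multiply each column j of a patients x tuples fuzzy matrix by chi_j."""
    _check_chi(f.columns, chi)
    out = f.copy()
    for col in out.columns:
        out[col] = [policy.weighted(chi[col] * v) for v in out[col]]
    return WeightedMatrix(out, {c: chi[c] for c in f.columns})


def weight_rows(
    f: pd.DataFrame, chi: Mapping[str, float], policy: RoundingPolicy = PAPER
) -> WeightedMatrix:
    """Multiply each row j of a tuples x experts fuzzy matrix by chi_j."""
    _check_chi(f.index, chi)
    out = f.copy()
    for row in out.index:
        out.loc[row] = [policy.weighted(chi[row] * v) for v in out.loc[row]]
    return WeightedMatrix(out, {r: chi[r] for r in f.index})


def compose_diagnosis(
    wp: WeightedMatrix | pd.DataFrame,
    we: WeightedMatrix | pd.DataFrame,
    policy: RoundingPolicy = PAPER,
) -> pd.DataFrame:
    """Ordinary matrix product of the weighted matrices (patients x experts)."""
    a = wp.values if isinstance(wp, WeightedMatrix) else wp
    b = we.values if isinstance(we, WeightedMatrix) else we
    if list(a.columns) != list(b.index):
        raise ValueError(
            f"inner labels differ: columns {list(a.columns)} vs rows {list(b.index)}"
        )
    d = a @ b
    return d.map(policy.weighted)


def final_scores(d: pd.DataFrame) -> pd.Series:
    """Per-patient score: sum of the patient's diagnosis-matrix row."""
    return d.sum(axis=1)


def rank_patients(scores: Mapping[str, float] | pd.Series) -> list[str]:
    """Patients in descending score order; ties keep input order (stable)."""
    items = list(scores.items())
    if not items:
        raise ValueError("scores must be non-empty")
    return [p for p, _ in sorted(items, key=lambda kv: -kv[1])]


def run_fuzzy_pipeline(
    f_pat: pd.DataFrame,
    f_exp: pd.DataFrame,
    chi: Mapping[str, float],
    policy: RoundingPolicy = PAPER,
) -> DiagnosisResult:
    """Pipeline entered at the fuzzy stage (already-reduced matrices)."""
    wp = weight_columns(f_pat, chi, policy)
    we = weight_rows(f_exp, chi, policy)
    d = compose_diagnosis(wp, we, policy)
    scores = final_scores(d)
    return DiagnosisResult(
        matrix=d,
        scores=scores,
        ranking=rank_patients(scores),
        intermediates={
            "fuzzy_patients": f_pat,
            "fuzzy_experts": f_exp,
            "weighted_patients": wp.values,
            "weighted_experts": we.values,
        },
    )


def run_pipeline(
    w1: AssessmentMatrix,
    w2: AssessmentMatrix,
    chi: Mapping[str, float],
    policy: RoundingPolicy = PAPER,
) -> DiagnosisResult:
    """Full pipeline: reduce -> weight -> compose -> score -> rank.

    ``w1`` is patients x tuples, ``w2`` tuples x experts; ``chi`` must cover
    the shared tuple labels. Stage errors are re-raised with the stage name.
    """
    if list(w1.col_labels) != list(w2.row_labels):
        raise ValueError(
            "tuple labels of the two matrices differ: "
            f"{list(w1.col_labels)} vs {list(w2.row_labels)}"
        )
    try:
        f_pat = reduce_matrix(w1, policy)
        f_exp = reduce_matrix(w2, policy)
    except ValueError as exc:
        raise ValueError(f"reduction stage: {exc}") from exc
    try:
        return run_fuzzy_pipeline(f_pat, f_exp, chi, policy)
    except (ValueError, KeyError) as exc:
        raise type(exc)(f"weighting/composition stage: {exc}") from exc
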