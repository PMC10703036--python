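"""Readers and writers.

JSON is the canonical interchange format for whole cases and reports (the
nested tuple/expert/opinion structure does not flatten well); CSV is
supported for single assessment matrices, with neutrosophic cells serialized
as ``"t;i;f"``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .grading import RoundingPolicy
from .model import NeutrosophicTriplet
from .sanchez import AssessmentMatrix, DiagnosisResult
from .sensitivity import SensitivityReport

__all__ = [
    "CaseDocument",
    "read_case",
    "write_case",
    "matrix_to_csv",
    "matrix_from_csv",
    "write_report",
    "read_report",
]

SCHEMA_VERSION = 1


@dataclass
class CaseDocument:
    """A self-contained decision case: labels, chi degrees, both assessment
    matrices and the rounding policy to apply."""

    patients: list[str]
    tuples: list[str]
    experts: list[str]
    chi: dict[str, float]
    assessment_patients: AssessmentMatrix
    assessment_experts: AssessmentMatrix
    rounding: str = "paper"
    schema_version: int = SCHEMA_VERSION

    def policy(self) -> RoundingPolicy:
        return RoundingPolicy(self.rounding)


def _matrix_to_obj(m: AssessmentMatrix) -> dict:
    return {
        "rows": list(m.row_labels),
        "cols": list(m.col_labels),
        "cells": [[list(t.as_tuple()) for t in row] for row in m.cells],
    }


def _matrix_from_obj(obj: dict, where: str) -> AssessmentMatrix:
    try:
        cells = tuple(
            tuple(NeutrosophicTriplet(*map(float, c)) for c in row)
            for row in obj["cells"]
        )
        return AssessmentMatrix(tuple(obj["rows"]), tuple(obj["cols"]), cells)
    except (KeyError, TypeError, ValueError) as exc:
        raise ValueError(f"{where}: malformed matrix ({exc})") from exc


def write_case(doc: CaseDocument, path: str | Path) -> None:
    payload = {
        "schema_version": doc.schema_version,
        "rounding": doc.rounding,
        "patients": doc.patients,
        "tuples": doc.tuples,
        "experts": doc.experts,
        "chi": doc.chi,
        "assessment_patients": _matrix_to_obj(doc.assessment_patients),
        "assessment_experts": _matrix_to_obj(doc.assessment_experts),
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_case(path: str | Path) -> CaseDocument:
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"{path}: not valid JSON ({exc})") from exc
    for key in ("patients", "tuples", "experts", "chi",
                "assessment_patients", "assessment_experts"):
        if key not in payload:
            raise ValueError(f"{path}: missing field {key!r}")
    return CaseDocument(
        patients=list(payload["patients"]),
        tuples=list(payload["tuples"]),
        experts=list(payload["experts"]),
        chi={k: float(v) for k, v in payload["chi"].items()},
        assessment_patients=_matrix_from_obj(
            payload["assessment_patients"], f"{path}: assessment_patients"
        ),
        assessment_experts=_matrix_from_obj(
            payload["assessment_experts"], f"{path}: assessment_experts"
        ),
        rounding=payload.get("rounding", "paper"),
        schema_version=int(payload.get("schema_version", SCHEMA_VERSION)),
    )


def matrix_to_csv(m: AssessmentMatrix, path: str | Path) -> None:
    """Header row of column labels, first column row labels, cells "t;i;f"."""
    frame = pd.DataFrame(
        [[";".join(repr(x) for x in t.as_tuple()) for t in row] for row in m.cells],
        index=list(m.row_labels),
        columns=list(m.col_labels),
    )
    frame.to_csv(path)


def matrix_from_csv(path: str | Path) -> AssessmentMatrix:
    frame = pd.read_csv(path, index_col=0, dtype=str)
    cells = []
    for r in frame.index:
        row = []
        for c in frame.columns:
            raw = frame.loc[r, c]
            parts = str(raw).split(";")
            if len(parts) != 3:
                raise ValueError(
                    f"{path}: cell ({r!r}, {c!r}): expected 't;i;f', got {raw!r}"
                )
            try:
                row.append(NeutrosophicTriplet(*(float(p) for p in parts)))
            except ValueError as exc:
                raise ValueError(
                    f"{path}: cell ({r!r}, {c!r}): {exc}"
                ) from exc
        cells.append(tuple(row))
    return AssessmentMatrix(tuple(frame.index), tuple(frame.columns), tuple(cells))


def write_report(
    result: DiagnosisResult,
    path: str | Path,
    sensitivity: SensitivityReport | None = None,
    rounding: str = "paper",
) -> None:
    """JSON report: intermediates, diagnosis, scores, ranking, sensitivity."""
    payload = {
        "tool": "fpnhse",
        "version": __version__,
        "rounding": rounding,
        "intermediates": {
            name: frame.to_dict(orient="index")
            for name, frame in result.intermediates.items()
        },
        "diagnosis": result.matrix.to_dict(orient="index"),
        "scores": {p: float(s) for p, s in result.scores.items()},
        "ranking": list(result.ranking),
        "sensitivity": None,
    }
    if sensitivity is not None:
        payload["sensitivity"] = {
            "means": sensitivity.means.to_dict(orient="index"),
            "rankings": sensitivity.rankings,
            "concordance": sensitivity.concordance,
            "kendall_tau": sensitivity.kendall_tau,
        }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
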