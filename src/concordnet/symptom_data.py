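"""Patient symptom tables: reading, validation, dichotomization, filtering.

The unit of input is a delimited table with one row per patient, a patient-ID
column, and one column per symptom. Cells are either already-binary presence
indicators {0, 1}, or three-level severity codes {0, 1, 2} recording how a
symptom impacted regular functioning (none / moderate / severe). Severity
tables are dichotomized before analysis: a symptom counts as present when it
had at least a moderate impact on functioning.

Symptom column order from the input file is preserved verbatim; every
downstream matrix (concordance, similarity, community networks) indexes
symptoms in this order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    EmptyCohortError,
    ParseError,
    ValidationError,
)

__all__ = [
    "SymptomTable",
    "SeverityTable",
    "read_symptom_table",
    "dichotomize",
    "filter_zero_patients",
]


def _validate_ids_and_labels(patient_ids, symptom_labels):
    ids = tuple(str(p) for p in patient_ids)
    labels = tuple(str(s) for s in symptom_labels)
    if any(not p for p in ids):
        raise ValidationError("patient IDs must be non-empty strings")
    if len(set(ids)) != len(ids):
        dupes = sorted({p for p in ids if list(ids).count(p) > 1})
        raise ValidationError(f"duplicate patient ID(s): {', '.join(dupes)}")
    if len(labels) != len(set(labels)):
        raise ValidationError("duplicate symptom labels")
    if len(labels) < 2:
        raise ValidationError("at least 2 symptom columns are required")
    if len(ids) < 1:
        raise ValidationError("at least 1 patient row is required")
    return ids, labels


@dataclass(frozen=True)
class SymptomTable:
    """n patients x k binary symptom indicators.

    Attributes
    ----------
    patient_ids : tuple of str
        Unique, non-empty patient identifiers, one per row.
    symptom_labels : tuple of str
        Short symptom names, one per column, in input-file order.
    values : ndarray of shape (n, k), dtype uint8
        Presence indicators; every cell is exactly 0 or 1.
    """

    patient_ids: tuple
    symptom_labels: tuple
    values: np.ndarray

    def __post_init__(self):
        ids, labels = _validate_ids_and_labels(self.patient_ids, self.symptom_labels)
        values = np.asarray(self.values)
        if values.ndim != 2 or values.shape != (len(ids), len(labels)):
            raise ValidationError(
                f"values shape {values.shape} does not match "
                f"{len(ids)} patients x {len(labels)} symptoms"
            )
        if not np.isin(values, (0, 1)).all():
            raise ValidationError("symptom table cells must be exactly 0 or 1")
        object.__setattr__(self, "patient_ids", ids)
        object.__setattr__(self, "symptom_labels", labels)
        object.__setattr__(self, "values", values.astype(np.uint8))

    @property
    def n(self) -> int:
        return len(self.patient_ids)

    @property
    def k(self) -> int:
        return len(self.symptom_labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.patient_ids), columns=list(self.symptom_labels)
        )


@dataclass(frozen=True)
class SeverityTable:
    """n patients x k three-level severity codes (0 none, 1 moderate, 2 severe)."""

    patient_ids: tuple
    symptom_labels: tuple
    values: np.ndarray

    def __post_init__(self):
        ids, labels = _validate_ids_and_labels(self.patient_ids, self.symptom_labels)
        values = np.asarray(self.values)
        if values.ndim != 2 or values.shape != (len(ids), len(labels)):
            raise ValidationError(
                f"values shape {values.shape} does not match "
                f"{len(ids)} patients x {len(labels)} symptoms"
            )
        if not np.isin(values, (0, 1, 2)).all():
            raise ValidationError("severity table cells must be 0, 1 or 2")
        object.__setattr__(self, "patient_ids", ids)
        object.__setattr__(self, "symptom_labels", labels)
        object.__setattr__(self, "values", values.astype(np.uint8))

    @property
    def n(self) -> int:
        return len(self.patient_ids)

    @property
    def k(self) -> int:
        return len(self.symptom_labels)


def read_symptom_table(
    path,
    id_column: str = "patient_id",
    missing: str = "error",
) -> Union[SymptomTable, SeverityTable]:
    """Read a patient x symptom CSV, auto-detecting binary vs severity coding.

    Parameters
    ----------
    path : str or path-like
        Comma-delimited UTF-8 text file with a header row.
    id_column : str
        Name of the patient-ID column; all other columns are symptoms.
    missing : {"error", "zero"}
        Policy for empty cells. ``"error"`` (default) rejects the file;
        ``"zero"`` maps missing to 0 (no endorsement). Silent imputation is
        deliberately opt-in.

    Returns
    -------
    SymptomTable
        If every cell is in {0, 1}.
    SeverityTable
        If any cell equals 2 (three-level severity coding detected).
    """
    if missing not in ("error", "zero"):
        raise ConfigurationError(f"unknown missing-value policy {missing!r}")
    try:
        frame = pd.read_csv(path, dtype=str, skipinitialspace=True)
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed CSV
        raise ParseError(f"could not parse {path}: {exc}") from exc
    if id_column not in frame.columns:
        raise ConfigurationError(
            f"id column {id_column!r} not found in {path} "
            f"(columns: {', '.join(frame.columns)})"
        )
    symptom_cols = [c for c in frame.columns if c != id_column]
    ids = frame[id_column].astype(str).tolist()

    values = np.zeros((len(frame), len(symptom_cols)), dtype=np.uint8)
    for j, col in enumerate(symptom_cols):
        for i, cell in enumerate(frame[col]):
            if cell is None or (isinstance(cell, float) and np.isnan(cell)) or (
                isinstance(cell, str) and cell.strip() == ""
            ):
                if missing == "zero":
                    continue
                raise ParseError(
                    f"missing value at row {i + 1} (patient {ids[i]!r}), "
                    f"column {col!r}; pass missing='zero' to treat as 0"
                )
            try:
                v = int(str(cell).strip())
            except ValueError:
                raise ParseError(
                    f"non-numeric value {cell!r} at row {i + 1} "
                    f"(patient {ids[i]!r}), column {col!r}"
                ) from None
            if v not in (0, 1, 2):
                raise ParseError(
                    f"out-of-range value {v} at row {i + 1} "
                    f"(patient {ids[i]!r}), column {col!r}; expected 0/1/2"
                )
            values[i, j] = v

    if (values == 2).any():
        return SeverityTable(tuple(ids), tuple(symptom_cols), values)
    return SymptomTable(tuple(ids), tuple(symptom_cols), values)


def dichotomize(severity: SeverityTable) -> SymptomTable:
    """Collapse severity codes to presence: 0 -> 0; moderate/severe (1, 2) -> 1.

    A symptom counts as present only when it had at least a moderate impact on
    functioning. Idempotent on tables that are already binary.
    """
    if isinstance(severity, SymptomTable):
        return severity
    return SymptomTable(
        severity.patient_ids,
        severity.symptom_labels,
        (severity.values >= 1).astype(np.uint8),
    )


def filter_zero_patients(table: SymptomTable):
    """Drop patients who endorse no symptoms; keep all symptom columns.

    Zero-symptom patients form an a-priori group carrying no co-occurrence
    information, so they are removed before similarity computation. Symptoms
    endorsed by nobody are retained as isolate nodes.

    Returns
    -------
    (SymptomTable, list of str)
        The filtered table and the removed patient IDs (input order).

    Raises
    ------
    EmptyCohortError
        If every patient would be removed.
    """
    keep = table.values.sum(axis=1) > 0
    removed = [p for p, k in zip(table.patient_ids, keep) if not k]
    if not keep.any():
        raise EmptyCohortError("all patients endorse zero symptoms")
    if keep.all():
        return table, []
    filtered = SymptomTable(
        tuple(p for p, k in zip(table.patient_ids, keep) if k),
        table.symptom_labels,
        table.values[keep],
    )
    return filtered, removed
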