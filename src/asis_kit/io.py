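"""Cohort, questionnaire and result-table readers/writers.

The canonical cohort format is one long-format CSV, UTF-8 with header,
one row per visit: ``patient_id, centre, age_years`` then one column per
subdomain (snake_case, the order of :data:`asis_kit.severity.ALL_DOMAINS`),
``seizure_observed`` (0/1) and ``treatment_start_age`` (blank if none).
Ages are decimal years; no date arithmetic is performed.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .severity import (
    ALL_DOMAINS,
    PatientSeries,
    ValidationError,
    VisitRecord,
    validate_visit,
)
from .treatment import TreatmentObservation

COHORT_COLUMNS: tuple[str, ...] = (
    ("patient_id", "centre", "age_years")
    + ALL_DOMAINS
    + ("seizure_observed", "treatment_start_age")
)


def write_cohort(cohort: Sequence[PatientSeries], path: str | Path) -> None:
    """Write a cohort to the canonical long-format CSV."""
    rows = []
    for s in cohort:
        for v in s.visits:
            row = {
                "patient_id": s.patient_id,
                "centre": v.centre,
                "age_years": f"{v.age:.3f}",
                "seizure_observed": int(v.seizure_observed),
                "treatment_start_age": (
                    "" if s.treatment_start_age is None else f"{s.treatment_start_age:.3f}"
                ),
            }
            row.update({d: v.scores[d] for d in ALL_DOMAINS})
            rows.append(row)
    pd.DataFrame(rows, columns=list(COHORT_COLUMNS)).to_csv(path, index=False)


def read_cohort(path: str | Path) -> list[PatientSeries]:
    """Read and validate a cohort CSV; rows grouped per patient, sorted by age.

    Raises :class:`ValidationError` naming the offending line for missing
    columns, non-numeric ages, duplicate (patient, age) rows, or scores
    outside their domain ranges.
    """
    df = pd.read_csv(path, dtype={"patient_id": str, "centre": str})
    missing = set(COHORT_COLUMNS) - {"treatment_start_age"} - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing column(s) {sorted(missing)}")
    ages = pd.to_numeric(df["age_years"], errors="coerce")
    if ages.isna().any():
        line = int(df.index[ages.isna()][0]) + 2  # header + 1-based
        raise ValidationError(f"{path}: non-numeric age_years at line {line}")
    df["age_years"] = ages
    dup = df.duplicated(subset=["patient_id", "age_years"])
    if dup.any():
        line = int(df.index[dup][0]) + 2
        raise ValidationError(f"{path}: duplicate (patient_id, age_years) at line {line}")

    cohort: list[PatientSeries] = []
    for pid, grp in df.groupby("patient_id", sort=True):
        grp = grp.sort_values("age_years")
        visits = []
        for idx, row in grp.iterrows():
            visit = VisitRecord(
                patient_id=pid,
                centre=str(row["centre"]),
                age=float(row["age_years"]),
                scores={d: int(row[d]) for d in ALL_DOMAINS},
                seizure_observed=bool(int(row["seizure_observed"])),
            )
            violations = validate_visit(visit)
            if violations:
                raise ValidationError(
                    f"{path}: line {int(idx) + 2}: " + "; ".join(map(str, violations))
                )
            visits.append(visit)
        tsa = None
        if "treatment_start_age" in grp.columns:
            raw = grp["treatment_start_age"].iloc[0]
            if pd.notna(raw) and str(raw).strip() != "":
                tsa = float(raw)
        cohort.append(
            PatientSeries(
                patient_id=pid,
                visits=visits,
                centre=str(grp["centre"].iloc[0]),
                treatment_start_age=tsa,
            )
        )
    return cohort


def write_treatment_series(obs: Sequence[TreatmentObservation], path: str | Path) -> None:
    pd.DataFrame(
        {
            "patient_id": [o.patient_id for o in obs],
            "time_on_treatment_years": [f"{o.time_on_treatment:.6f}" for o in obs],
            "asis": [f"{o.asis:.6f}" for o in obs],
        }
    ).to_csv(path, index=False)


def read_treatment_series(path: str | Path) -> list[TreatmentObservation]:
    df = pd.read_csv(path, dtype={"patient_id": str})
    needed = {"patient_id", "time_on_treatment_years", "asis"}
    missing = needed - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing column(s) {sorted(missing)}")
    return [
        TreatmentObservation(
            patient_id=row["patient_id"],
            time_on_treatment=float(row["time_on_treatment_years"]),
            asis=float(row["asis"]),
        )
        for _, row in df.iterrows()
    ]


def read_responses(path: str | Path) -> dict[str, pd.DataFrame]:
    """Read a questionnaire CSV (respondent_id, group, one column per item).

    Returns one respondent x item frame per respondent group.
    """
    df = pd.read_csv(path, dtype={"respondent_id": str, "group": str})
    for col in ("respondent_id", "group"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing column {col!r}")
    items = [c for c in df.columns if c not in ("respondent_id", "group")]
    out = {}
    for group, grp in df.groupby("group", sort=True):
        out[group] = grp.set_index("respondent_id")[items].astype(int)
    return out


def write_report(table: pd.DataFrame, path: str | Path, format: str = "csv") -> None:
    """Write a result table deterministically (fixed column order, 6-digit floats)."""
    path = Path(path)
    if format == "csv":
        table.to_csv(path, index=False, float_format="%.6g")
    elif format == "json":
        path.write_text(
            json.dumps(json.loads(table.to_json(orient="records")), indent=2) + "\n"
        )
    else:
        raise ValueError(f"unknown report format {format!r}")
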