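"""Trajectory prognosis scored by per-patient maximum absolute deviation (MAD).

A patient's future severity is predicted by a straight line through the
origin with slope equal to an ASIS reference — either the first-visit
ASIS or the mean of all available per-visit ASIS values.  Goodness of fit
is the maximum absolute deviation between observed and predicted severity
over the patient's visits (in severity units).  Groups (all patients,
seizure, non-seizure; follow-up windows of 0-2, 2-4 and 4-6 years) are
summarised by median and IQR of the per-patient MADs, with
Wilcoxon-Mann-Whitney (location) and Ansari-Bradley (dispersion) tests
between groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .metrics import asis, cohort_summary, location_dispersion_tests
from .severity import InsufficientDataError, PatientSeries

#: Follow-up windows in years, right-closed: a span s falls in the first
#: window with s <= upper.  Spans beyond the last bound join the last window.
FOLLOWUP_WINDOWS: tuple[tuple[float, float], ...] = ((0.0, 2.0), (2.0, 4.0), (4.0, 6.0))


@dataclass(frozen=True)
class TrajectoryRef:
    """The ASIS reference slope used for through-origin prediction."""

    mode: str  # "first" | "mean"
    asis_ref: float


@dataclass
class MadSummary:
    """Median/IQR of per-patient MADs within one group."""

    label: str
    values: list[float]
    median: float
    q1: float
    q3: float
    n: int


def trajectory_ref(series: PatientSeries, mode: str, excluded: Iterable[str] = ()) -> TrajectoryRef:
    """First-visit or mean-of-visits ASIS reference for one patient."""
    if mode not in ("first", "mean"):
        raise ValueError(f"mode must be 'first' or 'mean', got {mode!r}")
    values = [asis(v, excluded).asis for v in series.visits]
    ref = values[0] if mode == "first" else float(np.mean(values))
    return TrajectoryRef(mode=mode, asis_ref=ref)


def predict_severity(ref: TrajectoryRef, age: float) -> float:
    """Severity predicted at ``age`` by the through-origin line asis_ref * age."""
    if not age > 0:
        raise ValueError(f"age must be strictly positive, got {age}")
    return ref.asis_ref * age


def patient_mad(series: PatientSeries, mode: str, excluded: Iterable[str] = ()) -> float:
    """Maximum absolute deviation between observed and predicted severity.

    The maximum runs over all visits; for mode='first' the first visit
    deviates by zero by construction, so the maximum is attained later.
    """
    if len(series.visits) < 2:
        raise InsufficientDataError(
            f"patient {series.patient_id}: MAD needs >= 2 visits"
        )
    ref = trajectory_ref(series, mode, excluded)
    devs = [
        abs(asis(v, excluded).severity - predict_severity(ref, v.age))
        for v in series.visits
    ]
    return float(max(devs))


def mad_table(cohort: Sequence[PatientSeries], excluded: Iterable[str] = ()) -> pd.DataFrame:
    """Per-patient MADs under both reference modes, with grouping columns."""
    rows = []
    for s in cohort:
        rows.append(
            {
                "patient_id": s.patient_id,
                "seizure_group": s.seizure_group,
                "followup_years": s.followup_years,
                "mad_first": patient_mad(s, "first", excluded),
                "mad_mean": patient_mad(s, "mean", excluded),
            }
        )
    return pd.DataFrame(rows)


def _summary(label: str, values: Sequence[float]) -> MadSummary:
    s = cohort_summary(values)
    return MadSummary(
        label=label,
        values=list(map(float, values)),
        median=s["median"],
        q1=s["q1"],
        q3=s["q3"],
        n=len(values),
    )


def group_mad_summary(
    cohort: Sequence[PatientSeries],
    mode: str,
    stratify_by_seizure: bool = True,
    excluded: Iterable[str] = (),
) -> tuple[list[MadSummary], dict[str, float]]:
    """Group-level MAD summaries plus seizure vs non-seizure two-sample tests.

    Groups with fewer than 2 patients are omitted with a warning; the test
    dict is empty when either seizure group is too small.
    """
    table = mad_table(cohort, excluded)
    col = f"mad_{mode}"
    if col not in table:
        raise ValueError(f"mode must be 'first' or 'mean', got {mode!r}")
    summaries = [_summary("all", table[col].tolist())]
    tests: dict[str, float] = {}
    if stratify_by_seizure:
        groups = {
            "seizure": table.loc[table.seizure_group, col].tolist(),
            "non_seizure": table.loc[~table.seizure_group, col].tolist(),
        }
        for label, vals in groups.items():
            if len(vals) < 2:
                warnings.warn(f"group {label!r} has < 2 patients; omitted", RuntimeWarning)
            else:
                summaries.append(_summary(label, vals))
        if all(len(v) >= 2 for v in groups.values()):
            tests = location_dispersion_tests(groups["seizure"], groups["non_seizure"])
    return summaries, tests


def compare_modes(
    cohort: Sequence[PatientSeries], excluded: Iterable[str] = ()
) -> dict[str, float]:
    """Location/dispersion tests of per-patient MAD: first-ASIS vs mean-ASIS."""
    table = mad_table(cohort, excluded)
    return location_dispersion_tests(table["mad_first"], table["mad_mean"])


def assign_window(span: float) -> tuple[float, float]:
    """Follow-up window for a span, right-closed; spans > 6 join 4-6 with a warning."""
    for lo, hi in FOLLOWUP_WINDOWS:
        if lo < span <= hi or (span <= 0 and lo == 0.0):
            return (lo, hi)
    warnings.warn(
        f"follow-up span {span:.2f} y exceeds the last window; assigned to "
        f"{FOLLOWUP_WINDOWS[-1]}",
        RuntimeWarning,
    )
    return FOLLOWUP_WINDOWS[-1]


def windowed_mad(
    cohort: Sequence[PatientSeries], mode: str, excluded: Iterable[str] = ()
) -> list[MadSummary]:
    """MAD summaries per follow-up window; each patient contributes once."""
    table = mad_table(cohort, excluded)
    col = f"mad_{mode}"
    buckets: dict[tuple[float, float], list[float]] = {w: [] for w in FOLLOWUP_WINDOWS}
    for _, row in table.iterrows():
        buckets[assign_window(row["followup_years"])].append(row[col])
    out = []
    for (lo, hi), vals in buckets.items():
        if vals:
            out.append(_summary(f"{lo:g}-{hi:g}y", vals))
    return out
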