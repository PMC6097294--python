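"""ASIS (annual severity increment score) metrics.

ASIS divides a visit's total severity score by the patient's age at that
visit, giving an index of the annual rate of disease progression in
severity units per year.  If a patient's severity accrues linearly through
the origin (severity = r * age) then ASIS equals r at every visit and the
per-patient ASIS slope over time is zero — the stability hypothesis in its
exact form.  This module computes per-visit ASIS, per-patient ASIS slopes,
a Tukey-whisker stability classification over the cohort slope
distribution, quantile summaries, Silverman-bandwidth kernel density
estimates, and the standard two-sample location/dispersion tests used to
compare seizure and non-seizure groups.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .severity import (
    InsufficientDataError,
    PatientSeries,
    VisitRecord,
    total_severity,
)


@dataclass(frozen=True)
class AsisPoint:
    """Per-visit ASIS value: severity divided by age."""

    age: float
    severity: int
    asis: float


@dataclass
class AsisTrajectory:
    """Per-patient ASIS time course and its least-squares rate of change.

    ``slope`` is the OLS slope of ASIS against time since first visit
    (units: severity / year^2); ``stable`` is set only by
    :func:`classify_stability` relative to the whole cohort.
    """

    patient_id: str
    points: list[AsisPoint]
    slope: float
    intercept: float
    seizure_group: bool = False
    stable: Optional[bool] = None


def asis(visit: VisitRecord, excluded: Iterable[str] = ()) -> AsisPoint:
    """ASIS of a single visit: total severity (minus ``excluded``) over age."""
    severity = total_severity(visit, excluded)
    return AsisPoint(age=visit.age, severity=severity, asis=severity / visit.age)


def asis_slope(series: PatientSeries, excluded: Iterable[str] = ()) -> AsisTrajectory:
    """OLS fit of per-visit ASIS against time since first visit.

    Requires at least two visits at distinct ages.  Time since first visit
    is used as the regressor (rather than absolute age) for conditioning;
    the slope is identical either way.
    """
    points = [asis(v, excluded) for v in series.visits]
    ages = np.array([p.age for p in points])
    if len(points) < 2 or np.ptp(ages) == 0:
        raise InsufficientDataError(
            f"patient {series.patient_id}: ASIS slope needs >= 2 visits at distinct ages"
        )
    t = ages - ages[0]
    y = np.array([p.asis for p in points])
    slope, intercept = np.polyfit(t, y, 1)
    return AsisTrajectory(
        patient_id=series.patient_id,
        points=points,
        slope=float(slope),
        intercept=float(intercept),
        seizure_group=series.seizure_group,
    )


def tukey_fences(values: Sequence[float], k: float = 1.5) -> tuple[float, float]:
    """Classic box-plot whisker bounds [Q1 - k*IQR, Q3 + k*IQR].

    Quartiles use linear interpolation between order statistics.
    """
    arr = np.asarray(values, dtype=float)
    q1, q3 = np.quantile(arr, [0.25, 0.75])
    iqr = q3 - q1
    return float(q1 - k * iqr), float(q3 + k * iqr)


def classify_stability(trajectories: Sequence[AsisTrajectory]) -> list[AsisTrajectory]:
    """Flag each trajectory stable iff its slope lies within the cohort's Tukey whiskers.

    A patient's progression rate is called *stable* when the slope of their
    ASIS time course falls inside [Q1 - 1.5 IQR, Q3 + 1.5 IQR] of the
    cohort slope distribution; whisker outliers are the unstable group.
    Returns new trajectory objects; input order is irrelevant to the flags.
    """
    slopes = [t.slope for t in trajectories]
    if len(slopes) < 4:
        raise InsufficientDataError(
            f"stability classification needs >= 4 slopes, got {len(slopes)}"
        )
    lo, hi = tukey_fences(slopes)
    return [replace(t, stable=bool(lo <= t.slope <= hi)) for t in trajectories]


def cohort_summary(values: Sequence[float]) -> dict[str, float]:
    """Median and quartiles (linear-interpolation convention) of a sample."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise InsufficientDataError("cohort summary of an empty sample")
    q1, med, q3 = np.quantile(arr, [0.25, 0.5, 0.75])
    return {"median": float(med), "q1": float(q1), "q3": float(q3)}


def silverman_bandwidth(values: Sequence[float]) -> float:
    """Silverman's rule of thumb: h = 0.9 * min(sd, IQR/1.34) * n^(-1/5)."""
    arr = np.asarray(values, dtype=float)
    n = arr.size
    sd = float(np.std(arr, ddof=1))
    q1, q3 = np.quantile(arr, [0.25, 0.75])
    iqr = float(q3 - q1)
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    h = 0.9 * spread * n ** (-1 / 5)
    if not h > 0:
        raise InsufficientDataError("density estimate of a zero-spread sample")
    return h


def density_estimate(
    values: Sequence[float], gridsize: int = 512
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian KDE with Silverman's bandwidth on an automatic grid.

    Returns ``(grid, density)``; the trapezoid integral of the density over
    the grid is 1 to within 1%.
    """
    arr = np.asarray(values, dtype=float)
    if np.unique(arr).size < 2:
        raise InsufficientDataError("density estimate needs >= 2 distinct values")
    h = silverman_bandwidth(arr)
    # gaussian_kde scales its factor by the sample sd; divide it out so the
    # kernel bandwidth is exactly Silverman's h.
    kde = stats.gaussian_kde(arr, bw_method=h / np.std(arr, ddof=1))
    grid = np.linspace(arr.min() - 4 * h, arr.max() + 4 * h, gridsize)
    return grid, kde(grid)


def location_dispersion_tests(a: Sequence[float], b: Sequence[float]) -> dict[str, float]:
    """Two-sample comparison: Wilcoxon-Mann-Whitney (location) and Ansari-Bradley (dispersion).

    Exact small-sample handling is delegated to scipy (its default method
    switch).  Only statistics and p-values are reported.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError("two-sample tests need >= 2 observations per group")
    mw = stats.mannwhitneyu(a, b, alternative="two-sided")
    ab = stats.ansari(a, b)
    return {
        "mannwhitney_stat": float(mw.statistic),
        "mannwhitney_p": float(mw.pvalue),
        "ansari_stat": float(ab.statistic),
        "ansari_p": float(ab.pvalue),
    }
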