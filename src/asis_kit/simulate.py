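"""Seeded synthetic cohort generation.

Patient-level data behind this kind of longitudinal severity analysis are
not publishable, so the pipeline is exercised on synthetic cohorts that
emulate the study design: 38 patients across 2 centres, 2-9 visits each
spanning roughly 1-6.4 years, six latent progression-rate subgroups,
~47% of patients developing seizures, and total severity accruing
approximately linearly with age on the 0-56 composite scale.

Each synthetic patient draws a latent class with rate r (severity units
per year); per-visit severity is r * age plus Gaussian noise, clamped to
the scale, rounded to integers and (by default) made monotone
non-decreasing, then allocated to the 16 subdomains under their per-domain
maxima by largest-remainder apportionment.  Seizure-group patients get a
random onset age, seizure scores > 0 from onset onward, and an extra
patient-level slope perturbation applied after onset — the feature that
makes the seizure group's trajectories deviate more from a constant-rate
prediction, as observed clinically.  Everything is reproducible from the
config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .severity import (
    ALL_DOMAINS,
    DOMAIN_MAX,
    MAX_TOTAL,
    PatientSeries,
    VisitRecord,
)
from .treatment import TreatmentObservation


@dataclass(frozen=True)
class CohortConfig:
    """Study-design parameters of the synthetic longitudinal cohort."""

    n_patients: int = 38
    n_centres: int = 2
    #: latent-class progression rates, severity units per year
    subgroup_slopes: tuple[float, ...] = (0.2, 0.5, 0.9, 1.4, 2.1, 3.0)
    subgroup_weights: tuple[float, ...] = (0.15, 0.20, 0.25, 0.15, 0.15, 0.10)
    seizure_fraction: float = 0.47
    #: sd of the patient-level post-onset rate perturbation (severity
    #: units/yr); ~2 matches the wider ASIS-slope spread seen in seizure
    #: groups at typical entry ages (ASIS slope ~ perturbation / onset age)
    seizure_extra_slope_sd: float = 2.0
    visits_min: int = 2
    visits_max: int = 9
    followup_min: float = 0.94
    followup_max: float = 6.36
    first_age_min: float = 2.0
    first_age_max: float = 28.0
    severity_noise_sd: float = 1.0
    monotone: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        w = np.asarray(self.subgroup_weights, dtype=float)
        if len(self.subgroup_slopes) != len(w):
            raise ValueError("subgroup_slopes and subgroup_weights lengths differ")
        if not np.isclose(w.sum(), 1.0):
            raise ValueError(f"subgroup_weights must sum to 1, got {w.sum()}")
        if (w < 0).any():
            raise ValueError("subgroup_weights must be non-negative")
        for lo, hi, what in [
            (self.visits_min, self.visits_max, "visits"),
            (self.followup_min, self.followup_max, "followup_years"),
            (self.first_age_min, self.first_age_max, "first_age"),
        ]:
            if lo > hi:
                raise ValueError(f"degenerate {what} range ({lo}, {hi})")
        if self.visits_min < 2:
            raise ValueError("longitudinal cohort needs >= 2 visits per patient")
        if self.severity_noise_sd < 0 or self.seizure_extra_slope_sd < 0:
            raise ValueError("noise sds must be >= 0")
        if min(self.subgroup_slopes) * self.first_age_min > MAX_TOTAL:
            raise ValueError(
                "infeasible config: every rate saturates the severity scale "
                f"at the minimum first age {self.first_age_min}"
            )


@dataclass(frozen=True)
class TreatmentConfig:
    """Design of the synthetic on-treatment ASIS series."""

    n_patients: int = 10
    baseline_asis_min: float = 0.38
    baseline_asis_max: float = 0.80
    treatment_slope: float = -0.06  # ASIS units per year
    duration_months_min: float = 2.7
    duration_months_max: float = 21.16
    visits_min: int = 2  # on-treatment assessments, excluding baseline
    visits_max: int = 4
    noise_sd: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_asis_min > self.baseline_asis_max:
            raise ValueError("degenerate baseline ASIS range")
        if self.duration_months_min > self.duration_months_max:
            raise ValueError("degenerate duration range")
        if self.visits_min < 1 or self.visits_min > self.visits_max:
            raise ValueError("invalid on-treatment visit range")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


# fixed allocation preference: majors carry most of the burden, proportional
# to each domain's maximum score
_DEFAULT_WEIGHTS = {d: float(DOMAIN_MAX[d]) for d in ALL_DOMAINS}


def allocate_subdomains(
    total: int,
    weights: dict[str, float],
    rng: np.random.Generator,
    minima: Optional[dict[str, int]] = None,
    maxima: Optional[dict[str, int]] = None,
) -> dict[str, int]:
    """Split a total severity into per-domain scores by largest remainder.

    Scores sum exactly to ``total``, never exceed each domain's maximum,
    and honour optional per-domain minima (e.g. seizures >= 1 when a
    seizure was observed) and tightened maxima (seizures = 0 when none was
    observed).  Units beyond a domain's cap are redistributed to the
    next-largest remainders; residual ties break by a seeded shuffle.
    """
    if not 0 <= total <= MAX_TOTAL:
        raise ValueError(f"total {total} outside the scale range 0..{MAX_TOTAL}")
    minima = dict(minima or {})
    dom_max = {d: min(DOMAIN_MAX[d], (maxima or {}).get(d, DOMAIN_MAX[d])) for d in ALL_DOMAINS}
    if total > sum(dom_max.values()):
        raise ValueError(f"total {total} infeasible under tightened maxima")
    scores = {d: 0 for d in ALL_DOMAINS}
    remaining = total
    for d, m in minima.items():
        m = min(m, dom_max[d], remaining)
        scores[d] = m
        remaining -= m
    if remaining == 0:
        return scores

    w = np.array([max(weights.get(d, 0.0), 0.0) for d in ALL_DOMAINS], dtype=float)
    if w.sum() == 0:
        w[:] = 1.0
    quota = remaining * w / w.sum()
    caps = np.array([dom_max[d] - scores[d] for d in ALL_DOMAINS])
    base = np.minimum(np.floor(quota).astype(int), caps)
    leftover = remaining - int(base.sum())
    # hand out leftover units one by one, largest fractional remainder first
    remainder = quota - base
    order = np.lexsort((rng.permutation(len(ALL_DOMAINS)), -remainder))
    i = 0
    while leftover > 0:
        j = order[i % len(order)]
        if base[j] < caps[j]:
            base[j] += 1
            leftover -= 1
        i += 1
        if i > 10 * len(order) * (leftover + 1):  # pragma: no cover - guarded by total<=56
            raise RuntimeError("allocation failed to place all units")
    for d, s in zip(ALL_DOMAINS, base):
        scores[d] += int(s)
    return scores


def _visit_ages(rng: np.random.Generator, first_age: float, span: float, n: int) -> np.ndarray:
    """Strictly increasing visit ages, 3-decimal precision, first + span fixed."""
    while True:
        interior = np.sort(rng.uniform(0.0, span, size=n - 2)) if n > 2 else np.array([])
        times = np.concatenate([[0.0], interior, [span]])
        ages = np.round(first_age + times, 3)
        if np.all(np.diff(ages) > 0):
            return ages


def generate_cohort(config: CohortConfig = CohortConfig()) -> list[PatientSeries]:
    """Draw a full synthetic longitudinal cohort, reproducible from the seed."""
    rng = np.random.default_rng(config.seed)
    slopes = np.asarray(config.subgroup_slopes, dtype=float)
    weights = np.asarray(config.subgroup_weights, dtype=float)
    cohort: list[PatientSeries] = []
    for i in range(config.n_patients):
        pid = f"P{i + 1:03d}"
        centre = f"C{rng.integers(1, config.n_centres + 1)}"
        k = int(rng.choice(len(slopes), p=weights))
        rate = float(slopes[k])
        seizure_patient = bool(rng.random() < config.seizure_fraction)

        # fast progressors enter the study young, keeping severity on-scale
        age_hi = min(config.first_age_max, 0.8 * MAX_TOTAL / max(rate, 1e-9))
        age_hi = max(age_hi, config.first_age_min + 0.5)
        first_age = float(rng.uniform(config.first_age_min, age_hi))
        span = float(rng.uniform(config.followup_min, config.followup_max))
        n_visits = int(rng.integers(config.visits_min, config.visits_max + 1))
        ages = _visit_ages(rng, first_age, span, n_visits)

        onset = float(rng.uniform(ages[0], ages[-1])) if seizure_patient else np.inf
        delta = (
            float(rng.normal(0.0, config.seizure_extra_slope_sd))
            if seizure_patient
            else 0.0
        )
        noise = rng.normal(0.0, config.severity_noise_sd, size=n_visits)
        sev = rate * ages + delta * np.clip(ages - onset, 0.0, None) + noise
        sev = np.clip(np.round(sev), 0, MAX_TOTAL).astype(int)
        if config.monotone:
            sev = np.maximum.accumulate(sev)

        visits = []
        for age, total in zip(ages, sev):
            seizure_observed = seizure_patient and age >= onset
            minima = {"seizures": 1} if seizure_observed and total >= 1 else None
            maxima = None if seizure_observed else {"seizures": 0}
            total = int(min(total, MAX_TOTAL - (0 if seizure_observed else DOMAIN_MAX["seizures"])))
            scores = allocate_subdomains(total, _DEFAULT_WEIGHTS, rng, minima, maxima)
            visits.append(
                VisitRecord(
                    patient_id=pid,
                    centre=centre,
                    age=float(age),
                    scores=scores,
                    seizure_observed=seizure_observed,
                )
            )
        cohort.append(
            PatientSeries(patient_id=pid, visits=visits, centre=centre, subgroup=k + 1)
        )
    return cohort


def generate_treatment_series(
    config: TreatmentConfig = TreatmentConfig(),
) -> list[TreatmentObservation]:
    """Synthetic on-treatment ASIS observations: baseline plus 2-4 follow-ups.

    Per patient, ASIS(t) = baseline + treatment_slope * t + noise, with t in
    years on treatment and the last visit at the full treatment duration.
    """
    rng = np.random.default_rng(config.seed)
    out: list[TreatmentObservation] = []
    for i in range(config.n_patients):
        pid = f"T{i + 1:03d}"
        baseline = float(rng.uniform(config.baseline_asis_min, config.baseline_asis_max))
        duration = float(
            rng.uniform(config.duration_months_min, config.duration_months_max) / 12.0
        )
        n_follow = int(rng.integers(config.visits_min, config.visits_max + 1))
        interior = (
            np.sort(rng.uniform(0.1 * duration, duration, size=n_follow - 1))
            if n_follow > 1
            else np.array([])
        )
        times = np.concatenate([[0.0], interior, [duration]])
        for t in times:
            value = baseline + config.treatment_slope * t + rng.normal(0.0, config.noise_sd)
            out.append(
                TreatmentObservation(
                    patient_id=pid,
                    time_on_treatment=round(float(t), 6),
                    asis=round(max(float(value), 0.0), 6),
                )
            )
    return out
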