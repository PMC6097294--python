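"""Clinical severity scale for Niemann-Pick disease type C (NPC-CSS, minus hearing).

The scale sums ordinal scores over 16 neurological subdomains: 8 *major*
domains scored 0-5 and 8 *minor* domains scored 0-2.  The theoretical
maximum is 40 over the majors and 56 overall.  Hearing is not part of this
data model at all (it cannot be scored consistently across centres), so
totals here are always "minus hearing".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence


class ValidationError(ValueError):
    """A visit or table violates the scale's scoring rules."""


class ConfigurationError(ValueError):
    """An analysis was configured with unknown domains or invalid options."""


class InsufficientDataError(ValueError):
    """A longitudinal operation was asked of too few visits or patients."""


MAJOR_DOMAINS: tuple[str, ...] = (
    "eye_movement",
    "ambulation",
    "memory",
    "speech",
    "swallowing",
    "fine_motor_skills",
    "cognition",
    "seizures",
)

MINOR_DOMAINS: tuple[str, ...] = (
    "cataplexy",
    "behavioural_changes",
    "narcolepsy",
    "psychiatric_symptoms",
    "hyperreflexia",
    "incontinence",
    "abr",
    "respiratory_signs",
)

ALL_DOMAINS: tuple[str, ...] = MAJOR_DOMAINS + MINOR_DOMAINS

MAJOR_MAX = 5
MINOR_MAX = 2

#: Per-domain maximum score.
DOMAIN_MAX: dict[str, int] = {
    **{d: MAJOR_MAX for d in MAJOR_DOMAINS},
    **{d: MINOR_MAX for d in MINOR_DOMAINS},
}

#: Theoretical maxima of the composite score.
MAX_MAJOR_TOTAL = sum(DOMAIN_MAX[d] for d in MAJOR_DOMAINS)  # 40
MAX_TOTAL = sum(DOMAIN_MAX.values())  # 56


@dataclass(frozen=True)
class DomainSpec:
    """One subdomain of the composite scale."""

    name: str
    tier: str  # "major" | "minor"
    max_score: int


DOMAIN_SPECS: tuple[DomainSpec, ...] = tuple(
    DomainSpec(d, "major", MAJOR_MAX) for d in MAJOR_DOMAINS
) + tuple(DomainSpec(d, "minor", MINOR_MAX) for d in MINOR_DOMAINS)


@dataclass(frozen=True)
class Violation:
    """A scoring-rule violation found by :func:`validate_visit`."""

    domain: str
    value: object
    allowed: tuple[int, int]

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        lo, hi = self.allowed
        return f"{self.domain}={self.value!r} outside allowed range [{lo}, {hi}]"


@dataclass
class VisitRecord:
    """One clinical assessment: patient identity, age and the 16 subdomain scores."""

    patient_id: str
    centre: str
    age: float
    scores: dict[str, int]
    seizure_observed: bool = False

    def __post_init__(self) -> None:
        if not self.age > 0:
            raise ValidationError(
                f"visit age must be strictly positive, got {self.age!r} "
                f"(ASIS is undefined at age 0)"
            )


@dataclass
class PatientSeries:
    """All visits of one patient, ordered by age, with cohort metadata.

    ``seizure_group`` is derived: true iff any visit recorded a seizure.
    """

    patient_id: str
    visits: list[VisitRecord]
    centre: str = ""
    treatment_start_age: Optional[float] = None
    subgroup: Optional[int] = None  # latent generating class, if synthetic

    def __post_init__(self) -> None:
        ages = [v.age for v in self.visits]
        if any(b <= a for a, b in zip(ages, ages[1:])):
            raise ValidationError(
                f"patient {self.patient_id}: visit ages must be strictly increasing, got {ages}"
            )

    @property
    def seizure_group(self) -> bool:
        return any(v.seizure_observed for v in self.visits)

    @property
    def first_visit(self) -> VisitRecord:
        return self.visits[0]

    @property
    def last_visit(self) -> VisitRecord:
        return self.visits[-1]

    @property
    def followup_years(self) -> float:
        """Total follow-up span, last visit age minus first visit age."""
        return self.visits[-1].age - self.visits[0].age


def _check_excluded(excluded: Iterable[str]) -> frozenset[str]:
    excluded = frozenset(excluded)
    unknown = excluded - set(ALL_DOMAINS)
    if unknown:
        raise ConfigurationError(f"unknown domain(s) in exclusion set: {sorted(unknown)}")
    return excluded


def validate_visit(visit: VisitRecord) -> list[Violation]:
    """Check a visit's scores against the scale; return violations (never raise).

    A violation is reported for any missing domain, non-integer score, or
    score outside [0, max] for its domain.
    """
    violations: list[Violation] = []
    for domain in ALL_DOMAINS:
        hi = DOMAIN_MAX[domain]
        if domain not in visit.scores:
            violations.append(Violation(domain, None, (0, hi)))
            continue
        value = visit.scores[domain]
        if isinstance(value, bool) or not isinstance(value, (int,)):
            violations.append(Violation(domain, value, (0, hi)))
            continue
        if not 0 <= value <= hi:
            violations.append(Violation(domain, value, (0, hi)))
    return violations


def total_severity(visit: VisitRecord, excluded: Iterable[str] = ()) -> int:
    """Total composite severity of a visit, optionally excluding domains.

    Parameters
    ----------
    visit:
        The assessment to score.
    excluded:
        Domain names whose scores are dropped from the sum (e.g. to compute
        a total "minus" a candidate panel).  Must be known domain names.

    Returns
    -------
    int
        Sum of the non-excluded subdomain scores; at most 56 minus the
        maxima of the excluded domains.
    """
    excluded = _check_excluded(excluded)
    violations = validate_visit(visit)
    if violations:
        raise ValidationError(
            f"visit {visit.patient_id}@{visit.age}: " + "; ".join(map(str, violations))
        )
    return sum(visit.scores[d] for d in ALL_DOMAINS if d not in excluded)


def max_total(excluded: Iterable[str] = ()) -> int:
    """Theoretical maximum total after excluding the given domains."""
    excluded = _check_excluded(excluded)
    return sum(hi for d, hi in DOMAIN_MAX.items() if d not in excluded)
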