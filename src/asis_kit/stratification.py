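"""Clinical-trial eligibility simulation: age bands versus ASIS bands.

Conventional NPC trial recruitment uses age windows plus a requirement
for neurological signs (severity > 0).  The alternative studied here is
an ASIS band that excludes both the very mild (slow-progressing) and
very severe (fast-progressing) extremes.  Eligibility is evaluated at
each patient's first recorded visit; reports give the percentage of the
cohort included overall and within the seizure / non-seizure groups, and
criteria can be cross-tabulated pairwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

from .metrics import asis
from .severity import InsufficientDataError, PatientSeries, total_severity


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding, used for report percentages."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class InclusionCriterion:
    """One inclusion rule: an age or ASIS band, optionally requiring neurological signs."""

    name: str
    kind: str  # "age_band" | "asis_band"
    lower: float  # inclusive
    upper: float  # inclusive; math.inf for open-ended
    require_neurological_signs: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("age_band", "asis_band"):
            raise ValueError(f"unknown criterion kind {self.kind!r}")
        if self.lower > self.upper:
            raise ValueError(f"criterion {self.name}: lower {self.lower} > upper {self.upper}")


@dataclass
class EligibilityReport:
    """Per-patient eligibility flags and cohort-level inclusion percentages."""

    criterion: InclusionCriterion
    eligible: dict[str, bool]
    percent_included: float
    percent_included_seizure: float
    percent_included_nonseizure: float

    @property
    def n_included(self) -> int:
        return sum(self.eligible.values())


def is_eligible(series: PatientSeries, criterion: InclusionCriterion) -> bool:
    """Eligibility of one patient, decided at the first recorded visit."""
    visit = series.first_visit
    severity = total_severity(visit)
    value = visit.age if criterion.kind == "age_band" else asis(visit).asis
    ok = criterion.lower <= value <= criterion.upper
    if criterion.require_neurological_signs:
        ok = ok and severity > 0
    return ok


def evaluate_criterion(
    cohort: Sequence[PatientSeries], criterion: InclusionCriterion
) -> EligibilityReport:
    """Evaluate a criterion over a cohort; percentages over the full cohort."""
    if not cohort:
        raise InsufficientDataError("eligibility evaluation on an empty cohort")
    flags = {s.patient_id: is_eligible(s, criterion) for s in cohort}

    def pct(series_subset: list[PatientSeries]) -> float:
        if not series_subset:
            return float("nan")
        inc = sum(flags[s.patient_id] for s in series_subset)
        return round_half_up(100.0 * inc / len(series_subset))

    seizure = [s for s in cohort if s.seizure_group]
    nonseizure = [s for s in cohort if not s.seizure_group]
    return EligibilityReport(
        criterion=criterion,
        eligible=flags,
        percent_included=pct(list(cohort)),
        percent_included_seizure=pct(seizure),
        percent_included_nonseizure=pct(nonseizure),
    )


def cross_tabulate(
    cohort: Sequence[PatientSeries],
    criterion_a: InclusionCriterion,
    criterion_b: InclusionCriterion,
) -> dict[str, float]:
    """Pairwise inclusion cross-tabulation as cohort percentages.

    Returns percentages of patients included by both criteria, excluded by
    both, and included by exactly one; they sum to 100 up to rounding.
    """
    if not cohort:
        raise InsufficientDataError("cross-tabulation on an empty cohort")
    n = len(cohort)
    both = only_a = only_b = neither = 0
    for s in cohort:
        a = is_eligible(s, criterion_a)
        b = is_eligible(s, criterion_b)
        both += a and b
        only_a += a and not b
        only_b += b and not a
        neither += not a and not b
    return {
        "pct_both_included": round_half_up(100.0 * both / n),
        "pct_both_excluded": round_half_up(100.0 * neither / n),
        "pct_a_only": round_half_up(100.0 * only_a / n),
        "pct_b_only": round_half_up(100.0 * only_b / n),
    }


#: Age criteria from real NPC trials (miglustat pivotal trial; arimoclomol;
#: intrathecal 2-hydroxypropyl-beta-cyclodextrin as modelled, ages 4-21).
AGE_CRITERIA: tuple[InclusionCriterion, ...] = (
    InclusionCriterion("age_over_12_miglustat", "age_band", 12.0, math.inf, True),
    InclusionCriterion("age_2_18_arimoclomol", "age_band", 2.0, 18.0, True),
    InclusionCriterion("age_4_21_cyclodextrin", "age_band", 4.0, 21.0, True),
)

#: ASIS bands excluding the mild and severe extremes; a positive lower bound
#: already implies neurological signs (severity > 0), so none is required.
ASIS_CRITERIA: tuple[InclusionCriterion, ...] = tuple(
    InclusionCriterion(f"asis_{lo}_{hi}", "asis_band", lo, hi, False)
    for lo, hi in [(0.5, 2.0), (0.75, 2.0), (1.0, 2.0), (0.5, 2.5), (0.75, 2.5), (1.0, 2.5)]
)

#: Registered-protocol variants of the age criteria (12-60 upper bound;
#: the cyclodextrin registration window 2-25); kept out of the 9-item catalog.
AGE_CRITERIA_VARIANTS: tuple[InclusionCriterion, ...] = (
    InclusionCriterion("age_12_60_miglustat_variant", "age_band", 12.0, 60.0, True),
    InclusionCriterion("age_2_25_cyclodextrin_variant", "age_band", 2.0, 25.0, True),
)


def criteria_catalog() -> list[InclusionCriterion]:
    """The nine built-in criteria: three age bands and six ASIS bands."""
    return list(AGE_CRITERIA) + list(ASIS_CRITERIA)
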