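import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from asis_kit import CohortConfig, generate_cohort
from asis_kit.severity import ALL_DOMAINS, PatientSeries, VisitRecord


def make_visit(patient_id="P1", age=10.0, seizure_observed=False, **scores):
    """VisitRecord with named scores and zeros elsewhere."""
    full = {d: 0 for d in ALL_DOMAINS}
    full.update(scores)
    return VisitRecord(
        patient_id=patient_id,
        centre="C1",
        age=age,
        scores=full,
        seizure_observed=seizure_observed,
    )


def make_total_visit(patient_id, age, total, seizure_observed=False):
    """VisitRecord with the given total severity, filled greedily across domains."""
    from asis_kit.severity import DOMAIN_MAX

    total = int(total)
    assert 0 <= total <= 56
    scores = {}
    remaining = total
    for d in ALL_DOMAINS:
        take = min(remaining, DOMAIN_MAX[d])
        scores[d] = take
        remaining -= take
    return make_visit(patient_id, age, seizure_observed=seizure_observed, **scores)


def make_series(patient_id, ages, severities, seizure=False):
    """Patient with prescribed total severity at each visit."""
    visits = [
        make_total_visit(patient_id, age, sev, seizure_observed=seizure)
        for age, sev in zip(ages, severities)
    ]
    return PatientSeries(patient_id=patient_id, visits=visits)


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort, shared across tests."""
    return generate_cohort(CohortConfig(seed=0))


@pytest.fixture()
def maxed_visit():
    from asis_kit.severity import DOMAIN_MAX

    return make_visit("PMAX", 20.0, **DOMAIN_MAX)
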