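import numpy as np
import pytest

from asis_kit.metrics import asis
from asis_kit.severity import ALL_DOMAINS, DOMAIN_MAX, MAX_TOTAL, total_severity
from asis_kit.simulate import (
    CohortConfig,
    TreatmentConfig,
    allocate_subdomains,
    generate_cohort,
    generate_treatment_series,
)


class TestCohortConfig:
    def test_defaults_match_study_design(self):
        cfg = CohortConfig()
        assert cfg.n_patients == 38 and cfg.n_centres == 2
        assert len(cfg.subgroup_slopes) == 6
        assert cfg.visits_min == 2 and cfg.visits_max == 9
        assert (cfg.followup_min, cfg.followup_max) == (0.94, 6.36)

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(subgroup_weights=(0.5, 0.1, 0.1, 0.1, 0.1, 0.2))
        with pytest.raises(ValueError):
            CohortConfig(subgroup_slopes=(1.0,), subgroup_weights=(0.5, 0.5))

    def test_infeasible_rate_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(subgroup_slopes=(60.0,), subgroup_weights=(1.0,))


class TestGenerateCohort:
    def test_seeded_determinism(self):
        a = generate_cohort(CohortConfig(seed=4))
        b = generate_cohort(CohortConfig(seed=4))
        for sa, sb in zip(a, b):
            assert sa.patient_id == sb.patient_id
            for va, vb in zip(sa.visits, sb.visits):
                assert va.age == vb.age and va.scores == vb.scores
        c = generate_cohort(CohortConfig(seed=5))
        assert any(
            va.scores != vb.scores
            for sa, sb in zip(a, c)
            for va, vb in zip(sa.visits, sb.visits)
        )

    def test_design_ranges_enforced(self, default_cohort):
        cfg = CohortConfig()
        assert len(default_cohort) == cfg.n_patients
        for s in default_cohort:
            assert cfg.visits_min <= len(s.visits) <= cfg.visits_max
            span = s.followup_years
            assert cfg.followup_min - 0.01 <= span <= cfg.followup_max + 0.01
            assert s.first_visit.age >= cfg.first_age_min

    def test_scale_respected_everywhere(self, default_cohort):
        for s in default_cohort:
            for v in s.visits:
                total = total_severity(v)
                assert 0 <= total <= MAX_TOTAL
                assert sum(v.scores.values()) == total
                assert all(0 <= v.scores[d] <= DOMAIN_MAX[d] for d in ALL_DOMAINS)

    def test_monotone_progression_by_default(self, default_cohort):
        for s in default_cohort:
            totals = [total_severity(v) for v in s.visits]
            assert totals == sorted(totals)

    def test_seizure_flag_coupled_to_score(self, default_cohort):
        for s in default_cohort:
            flags = [v.seizure_observed for v in s.visits]
            # onset-and-onward: flags are a suffix of the visit sequence
            assert flags == sorted(flags)
            for v in s.visits:
                if v.scores["seizures"] > 0:
                    assert v.seizure_observed
                if v.seizure_observed and total_severity(v) >= 1:
                    assert v.scores["seizures"] >= 1

    def test_noiseless_single_class_tracks_rate(self):
        """With no noise and one class, per-visit ASIS equals the rate up to
        the integer rounding of the severity scale."""
        cfg = CohortConfig(
            subgroup_slopes=(1.0,), subgroup_weights=(1.0,),
            severity_noise_sd=0.0, seizure_fraction=0.0, seed=0,
        )
        for s in generate_cohort(cfg):
            for v in s.visits:
                point = asis(v)
                assert abs(point.severity - v.age) <= 0.5
                assert point.asis == pytest.approx(1.0, abs=0.5 / v.age)

    def test_centres_assigned(self, default_cohort):
        assert {s.centre for s in default_cohort} <= {"C1", "C2"}


class TestAllocateSubdomains:
    def test_full_scale_forces_every_maximum(self):
        rng = np.random.default_rng(0)
        scores = allocate_subdomains(56, {d: 1.0 for d in ALL_DOMAINS}, rng)
        assert scores == DOMAIN_MAX

    def test_zero_total(self):
        rng = np.random.default_rng(0)
        assert set(allocate_subdomains(0, {}, rng).values()) == {0}

    def test_every_total_feasible(self):
        """Exhaustive check: all totals 0..56 allocate exactly under the caps."""
        rng = np.random.default_rng(1)
        weights = {d: float(DOMAIN_MAX[d]) for d in ALL_DOMAINS}
        for total in range(57):
            scores = allocate_subdomains(total, weights, rng)
            assert sum(scores.values()) == total
            assert all(0 <= scores[d] <= DOMAIN_MAX[d] for d in ALL_DOMAINS)

    def test_uniform_weights_respect_caps(self):
        rng = np.random.default_rng(2)
        scores = allocate_subdomains(20, {d: 1.0 for d in ALL_DOMAINS}, rng)
        assert sum(scores.values()) == 20
        assert all(scores[d] <= DOMAIN_MAX[d] for d in ALL_DOMAINS)

    def test_minima_and_tightened_maxima(self):
        rng = np.random.default_rng(3)
        scores = allocate_subdomains(
            10, {d: 1.0 for d in ALL_DOMAINS}, rng,
            minima={"seizures": 1}, maxima={"ambulation": 0},
        )
        assert scores["seizures"] >= 1 and scores["ambulation"] == 0
        assert sum(scores.values()) == 10

    def test_out_of_range_total_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            allocate_subdomains(57, {}, rng)


class TestTreatmentSeries:
    def test_times_within_duration_range(self):
        cfg = TreatmentConfig(seed=6)
        obs = generate_treatment_series(cfg)
        by_patient = {}
        for o in obs:
            by_patient.setdefault(o.patient_id, []).append(o.time_on_treatment)
        assert len(by_patient) == cfg.n_patients
        for times in by_patient.values():
            assert times[0] == 0.0
            assert cfg.visits_min + 1 <= len(times) <= cfg.visits_max + 1
            dur_years = max(times)
            assert (
                cfg.duration_months_min / 12 - 1e-6
                <= dur_years
                <= cfg.duration_months_max / 12 + 1e-6
            )

    def test_noiseless_series_lies_on_the_line(self):
        cfg = TreatmentConfig(seed=7, noise_sd=0.0)
        obs = generate_treatment_series(cfg)
        from asis_kit.treatment import fit_treatment_model

        fit = fit_treatment_model(obs)
        assert fit.fixed_slope == pytest.approx(cfg.treatment_slope, abs=1e-4)

    def test_determinism(self):
        a = generate_treatment_series(TreatmentConfig(seed=8))
        b = generate_treatment_series(TreatmentConfig(seed=8))
        assert a == b
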