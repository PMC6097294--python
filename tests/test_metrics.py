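import numpy as np
import pytest

from asis_kit.metrics import (
    asis,
    asis_slope,
    classify_stability,
    cohort_summary,
    density_estimate,
    location_dispersion_tests,
    silverman_bandwidth,
    tukey_fences,
)
from asis_kit.severity import InsufficientDataError, PatientSeries
from conftest import make_series, make_visit


class TestAsis:
    @pytest.mark.parametrize(
        "severity,age,expected",
        [(10, 10.0, 1.0), (0, 7.3, 0.0), (33, 16.5, 2.0)],
    )
    def test_ratio(self, severity, age, expected):
        point = asis(make_series("P1", [age], [severity]).first_visit)
        assert point.asis == pytest.approx(expected)
        assert point.severity == severity

    def test_exclusion_propagates(self):
        visit = make_visit(age=5.0, ambulation=4, memory=2)
        assert asis(visit, excluded={"memory"}).asis == pytest.approx(4 / 5)


class TestAsisSlope:
    def test_constant_asis_has_zero_slope(self):
        # severity exactly r * age keeps ASIS constant -> slope 0
        s = make_series("P1", [5.0, 10.0, 15.0], [5, 10, 15])
        traj = asis_slope(s)
        assert traj.slope == pytest.approx(0.0, abs=1e-12)
        assert all(p.asis == pytest.approx(1.0) for p in traj.points)

    def test_two_point_line(self):
        # ASIS 1.0 then 1.1 over five years -> slope (1.1 - 1.0) / 5 = 0.02
        s = make_series("P1", [5.0, 10.0], [5, 11])
        traj = asis_slope(s)
        assert traj.slope == pytest.approx(0.02, rel=1e-12)
        assert traj.intercept == pytest.approx(1.0, rel=1e-12)

    def test_noiseless_linear_asis(self):
        # ages chosen so ASIS = 0.8 + 0.05 t holds exactly on the integer scale:
        # severity (0.3 + 0.05 a) a at ages 10,14,20,24,30 -> 8,14,26,36,54
        ages = [10.0, 14.0, 20.0, 24.0, 30.0]
        severities = [8, 14, 26, 36, 54]
        traj = asis_slope(make_series("P1", ages, severities))
        assert [p.asis for p in traj.points] == pytest.approx(
            [0.8, 1.0, 1.3, 1.5, 1.8]
        )
        assert traj.slope == pytest.approx(0.05, abs=1e-12)
        assert traj.intercept == pytest.approx(0.8, abs=1e-12)

    def test_insufficient_visits(self):
        with pytest.raises(InsufficientDataError):
            asis_slope(PatientSeries("P1", [make_visit(age=3.0)]))

    def test_scale_consistency(self):
        """Doubling every severity doubles every ASIS value and the slope."""
        s1 = make_series("P1", [5.0, 7.0, 9.0], [3, 5, 6])
        s2 = make_series("P1", [5.0, 7.0, 9.0], [6, 10, 12])
        t1, t2 = asis_slope(s1), asis_slope(s2)
        assert t2.slope == pytest.approx(2 * t1.slope, rel=1e-12)
        for p1, p2 in zip(t1.points, t2.points):
            assert p2.asis == pytest.approx(2 * p1.asis, rel=1e-12)


class TestStability:
    def _trajectories(self, slopes):
        from asis_kit.metrics import AsisTrajectory

        return [
            AsisTrajectory(patient_id=f"P{i}", points=[], slope=s, intercept=1.0)
            for i, s in enumerate(slopes)
        ]

    def test_identical_slopes_all_stable(self):
        flagged = classify_stability(self._trajectories([0.02] * 6))
        assert all(t.stable for t in flagged)

    def test_single_outlier_flagged(self):
        slopes = [0.0] * 7 + [10.0]
        flagged = classify_stability(self._trajectories(slopes))
        # independent oracle: quartiles by sorting + linear interpolation
        srt = sorted(slopes)
        def quantile(q):
            pos = q * (len(srt) - 1)
            lo, frac = int(pos), pos - int(pos)
            return srt[lo] * (1 - frac) + srt[min(lo + 1, len(srt) - 1)] * frac
        q1, q3 = quantile(0.25), quantile(0.75)
        lo, hi = q1 - 1.5 * (q3 - q1), q3 + 1.5 * (q3 - q1)
        for t in flagged:
            assert t.stable == (lo <= t.slope <= hi)
        assert sum(not t.stable for t in flagged) == 1
        assert flagged[-1].stable is False

    def test_order_invariance(self):
        rng = np.random.default_rng(5)
        slopes = rng.normal(0, 0.05, size=20).tolist() + [2.0]
        a = classify_stability(self._trajectories(slopes))
        shuffled = self._trajectories(slopes)
        rng.shuffle(shuffled)
        b = classify_stability(shuffled)
        flags_a = {t.patient_id: t.stable for t in a}
        flags_b = {t.patient_id: t.stable for t in b}
        assert flags_a == flags_b

    def test_too_few_slopes(self):
        with pytest.raises(InsufficientDataError):
            classify_stability(self._trajectories([0.0, 0.1]))

    def test_near_constant_cohort_mostly_stable(self):
        """Patients with constant per-patient ASIS + small noise are >= 80% stable."""
        rng = np.random.default_rng(42)
        from asis_kit.metrics import AsisTrajectory

        trajs = [
            AsisTrajectory(f"P{i}", [], float(rng.normal(0, 0.01)), 1.0)
            for i in range(38)
        ]
        flagged = classify_stability(trajs)
        assert np.mean([t.stable for t in flagged]) >= 0.8


class TestSummaries:
    def test_three_values(self):
        assert cohort_summary([1, 2, 3]) == {"median": 2.0, "q1": 1.5, "q3": 2.5}

    def test_single_value(self):
        assert cohort_summary([4.2]) == {"median": 4.2, "q1": 4.2, "q3": 4.2}

    def test_symmetric_sample(self):
        assert cohort_summary([-3, -1, 0, 1, 3])["median"] == 0.0

    def test_empty_raises(self):
        with pytest.raises(InsufficientDataError):
            cohort_summary([])

    def test_tukey_fences_match_quartiles(self):
        lo, hi = tukey_fences([1, 2, 3, 4])
        q1, q3 = np.quantile([1, 2, 3, 4], [0.25, 0.75])
        assert (lo, hi) == (q1 - 1.5 * (q3 - q1), q3 + 1.5 * (q3 - q1))


class TestDensity:
    def test_silverman_formula(self):
        rng = np.random.default_rng(100)
        x = rng.normal(size=100)
        sd = np.std(x, ddof=1)
        q1, q3 = np.quantile(x, [0.25, 0.75])
        iqr = q3 - q1
        expected = 0.9 * min(sd, iqr / 1.34) * 100 ** (-0.2)
        assert silverman_bandwidth(x) == pytest.approx(expected, rel=1e-12)

    def test_density_integrates_to_one(self):
        rng = np.random.default_rng(7)
        grid, dens = density_estimate(rng.normal(size=200))
        assert np.trapezoid(dens, grid) == pytest.approx(1.0, abs=0.01)

    def test_symmetric_sample_symmetric_density(self):
        x = np.concatenate([np.linspace(-2, 2, 41)])
        grid, dens = density_estimate(x)
        assert dens[np.argmin(np.abs(grid + 1))] == pytest.approx(
            dens[np.argmin(np.abs(grid - 1))], rel=1e-6
        )

    def test_degenerate_sample_raises(self):
        with pytest.raises(InsufficientDataError):
            density_estimate([1.0, 1.0, 1.0])


class TestTwoSampleTests:
    def test_reports_statistics_and_pvalues(self):
        rng = np.random.default_rng(3)
        out = location_dispersion_tests(rng.normal(size=15), rng.normal(1, 2, size=12))
        assert set(out) == {
            "mannwhitney_stat", "mannwhitney_p", "ansari_stat", "ansari_p",
        }
        assert 0 <= out["mannwhitney_p"] <= 1 and 0 <= out["ansari_p"] <= 1
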