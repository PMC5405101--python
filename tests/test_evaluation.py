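"""DVH queries, plan-quality indices, acceptability and the dose ladder."""

import numpy as np
import pytest

import prioplan as pp
from prioplan.evaluation import EscalationTrail, dvh

from oracles import d_index_oracle, hi_oracle, r50_oracle, v_index_oracle


def flat_mask(n_true, n_total):
    m = np.zeros(n_total, bool)
    m[:n_true] = True
    return m


class TestDVH:
    def test_uniform_dose_is_step_function(self):
        mask = flat_mask(20, 20)
        h = dvh(np.full(20, 30.0), mask, bin_width_gy=0.5)
        assert h.v(0.0) == pytest.approx(1.0)
        assert h.v(29.0) == pytest.approx(1.0)
        assert h.v(31.0) == pytest.approx(0.0)

    def test_monotone_nonincreasing_and_endpoints(self):
        rng = np.random.default_rng(0)
        h = dvh(rng.uniform(0, 70, 500), flat_mask(500, 500))
        assert h.cumulative_volume_fraction[0] == 1.0
        assert np.all(np.diff(h.cumulative_volume_fraction) <= 1e-12)
        assert h.cumulative_volume_fraction[-1] == 0.0

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            dvh(np.ones(5), np.zeros(5, bool))


class TestIndices:
    def test_uniform_prescription_gives_full_v95(self):
        mask = flat_mask(40, 50)
        dose = np.zeros(50)
        dose[:40] = 66.0
        assert pp.v_index(dose, mask, 0.95 * 66.0) == 100.0

    def test_half_volume_at_double_threshold(self):
        mask = flat_mask(10, 10)
        dose = np.array([20.0] * 5 + [0.0] * 5)
        assert pp.v_index(dose, mask, 10.0) == 50.0

    def test_vd_indices_match_sort_oracles_on_random_vectors(self):
        rng = np.random.default_rng(42)
        for _ in range(30):
            n = int(rng.integers(20, 400))
            dose = rng.uniform(0, 80, n)
            mask = flat_mask(n, n)
            t = float(rng.uniform(0, 80))
            assert pp.v_index(dose, mask, t) == pytest.approx(
                v_index_oracle(dose, mask, t), abs=1e-12)
            x = float(rng.uniform(1, 100))
            assert pp.d_index(dose, mask, x) == pytest.approx(
                d_index_oracle(dose, mask, x), abs=1e-12)

    def test_d99_is_top_99_percent_order_statistic(self):
        rng = np.random.default_rng(7)
        dose = rng.uniform(0, 70, 100)
        mask = flat_mask(100, 100)
        assert pp.d_index(dose, mask, 99.0) == np.sort(dose)[::-1][98]

    def test_d_index_nonincreasing_in_percent(self):
        rng = np.random.default_rng(9)
        dose = rng.uniform(0, 70, 123)
        mask = flat_mask(123, 123)
        vals = [pp.d_index(dose, mask, x) for x in (2, 50, 95, 98, 99, 100)]
        assert np.all(np.diff(vals) <= 1e-12)

    def test_percent_bounds_rejected(self):
        with pytest.raises(ValueError):
            pp.d_index(np.ones(5), flat_mask(5, 5), 0.0)


class TestR50AndHI:
    def test_r50_arithmetic_example(self):
        patient = flat_mask(200, 200)
        ptv = flat_mask(50, 200)
        dose = np.full(200, 40.0)
        assert pp.r50(dose, ptv, patient, 66.0) == pytest.approx(4.0)

    def test_r50_counting_oracle_random(self):
        rng = np.random.default_rng(5)
        dose = rng.uniform(0, 70, 300)
        patient = rng.random(300) < 0.9
        ptv = patient & (rng.random(300) < 0.2)
        if not ptv.any():
            ptv[np.flatnonzero(patient)[0]] = True
        assert pp.r50(dose, ptv, patient, 66.0) == pytest.approx(
            r50_oracle(dose, ptv, patient, 66.0))

    def test_hi_formula_example(self):
        # D2=68, D98=62, D50=66 -> HI = 6/66
        dose = np.concatenate([np.full(2, 68.0), np.full(95, 66.0), np.full(3, 62.0)])
        mask = flat_mask(100, 100)
        assert pp.homogeneity_index(dose, mask) == pytest.approx(6.0 / 66.0)

    def test_hi_zero_for_uniform_dose_and_matches_oracle(self):
        mask = flat_mask(64, 64)
        assert pp.homogeneity_index(np.full(64, 50.0), mask) == 0.0
        rng = np.random.default_rng(11)
        dose = rng.uniform(40, 70, 64)
        assert pp.homogeneity_index(dose, mask) == pytest.approx(hi_oracle(dose, mask))


class TestAcceptability:
    def make_report(self, **overrides):
        base = dict(
            ptv_v95_pct=97.0, ptv_v90_pct=100.0, ptv_d99_gy=60.0, ctv_v95_pct=100.0,
            r50=4.0, hi=0.1, mean_lung_dose_gy=15.0, lungs_v5_pct=50.0,
            lungs_v20_pct=28.0, heart_mean_gy=10.0, esophagus_mean_gy=20.0,
            esophagus_v45_pct=20.0, cord_max_gy=40.0, plexus_max_gy=50.0,
        )
        base.update(overrides)
        return pp.MetricReport(**base)

    def test_all_thresholds_met_passes(self):
        acc = pp.check_acceptability(self.make_report(
            mean_lung_dose_gy=19.0, lungs_v20_pct=34.0), pp.ladder_prescription(66.0))
        assert acc.acceptable and not acc.advisory_flags

    def test_advisory_violation_flags_but_does_not_fail(self):
        acc = pp.check_acceptability(self.make_report(lungs_v5_pct=65.0),
                                     pp.ladder_prescription(66.0))
        assert acc.acceptable
        assert acc.advisory_flags == ["lungs_v5"]

    def test_coverage_below_binding_threshold_fails(self):
        acc = pp.check_acceptability(self.make_report(ptv_v95_pct=94.0),
                                     pp.ladder_prescription(66.0))
        assert not acc.acceptable
        assert not acc.rule("ptv_v95").passed

    def test_cord_tolerance_follows_fractionation(self):
        report = self.make_report(cord_max_gy=48.0)
        assert not pp.check_acceptability(report, pp.ladder_prescription(45.0)).acceptable
        assert pp.check_acceptability(report, pp.ladder_prescription(66.0)).acceptable


class TestEscalationLadder:
    @pytest.mark.parametrize("start,expected", [
        (30.0, 39.0), (39.0, 45.0), (45.0, 55.0), (55.0, 60.5),
        (60.0, 66.0), (60.5, 66.0),
    ])
    def test_upward_steps(self, start, expected):
        nxt = pp.escalation_step(pp.ladder_prescription(start), "up")
        assert nxt.total_dose_gy == expected

    def test_ladder_top_returns_none(self):
        assert pp.escalation_step(pp.ladder_prescription(66.0), "up") is None

    def test_downward_fork_depends_on_fractionation(self):
        top = pp.ladder_prescription(66.0)
        assert pp.escalation_step(top, "down").total_dose_gy == 60.0
        assert pp.escalation_step(top, "down", fractionation_gy=2.75).total_dose_gy == 60.5

    def test_off_ladder_rejected(self):
        with pytest.raises(ValueError):
            pp.escalation_step(pp.Prescription(50.0, 2.0, 25), "up")

    def test_bottom_returns_none(self):
        assert pp.escalation_step(pp.ladder_prescription(30.0), "down") is None


class TestAttemptEscalation:
    """Ladder-walking logic against scripted planner outcomes."""

    @staticmethod
    def scripted_planner(acceptable_doses):
        def plan_and_evaluate(rx):
            rules = [pp.evaluation.AcceptabilityRule(
                "ptv_v95", 0.0, 95.0, ">=", True,
                rx.total_dose_gy in acceptable_doses)]
            return f"plan@{rx.total_dose_gy}", pp.AcceptabilityResult(
                rules, rx.total_dose_gy in acceptable_doses)
        return plan_and_evaluate

    def test_escalates_to_highest_acceptable_level(self):
        plan, final, trail = pp.attempt_escalation(
            self.scripted_planner({60.0, 66.0}), pp.ladder_prescription(60.0))
        assert final.total_dose_gy == 66.0
        assert plan == "plan@66.0"
        assert [a.prescription_gy for a in trail.attempts] == [60.0, 66.0]

    def test_stops_at_first_failed_step(self):
        _, final, trail = pp.attempt_escalation(
            self.scripted_planner({45.0}), pp.ladder_prescription(45.0))
        assert final.total_dose_gy == 45.0
        assert [a.prescription_gy for a in trail.attempts] == [45.0, 55.0]
        assert not trail.attempts[-1].acceptable

    def test_deescalates_until_acceptable(self):
        _, final, trail = pp.attempt_escalation(
            self.scripted_planner({45.0, 39.0, 30.0}), pp.ladder_prescription(66.0))
        assert final.total_dose_gy == 45.0
        assert trail.direction == "down"
        assert [a.prescription_gy for a in trail.attempts] == [66.0, 60.0, 55.0, 45.0]
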