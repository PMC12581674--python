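"""KDIGO staging: rule application, run semantics, brute-force agreement,
monotonicity, risk score, and eligibility screening."""

import numpy as np
import pytest

from akirank.kdigo import (
    AkiRiskConfig,
    aki_risk_score,
    kdigo_stage,
    screen_eligibility,
    stage_from_scr,
    stage_from_uop,
)
from akirank.records import LabSeries, PatientRecord


def scr_series(*obs):
    t, v = zip(*obs)
    return LabSeries("scr", "mg/dL", np.array(t, float), np.array(v, float))


def uop_series(values, start_h=1.0):
    t = start_h + np.arange(len(values))
    return LabSeries("uop", "mL/kg/h", t.astype(float), np.array(values, float))


class TestScrStaging:
    def test_absolute_rise_within_48h_is_stage1(self):
        a = stage_from_scr(scr_series((0, 1.00), (36, 1.31)), at_time=36)
        assert (a.stage, a.trigger) == (1, "scr_abs_48h")

    def test_relative_doubling_within_7d_is_stage2(self):
        a = stage_from_scr(scr_series((0, 1.00), (144, 2.05)), at_time=144)
        assert (a.stage, a.trigger) == (2, "scr_rel_7d_100")

    def test_fifty_percent_rise_is_stage1(self):
        a = stage_from_scr(scr_series((0, 1.00), (120, 1.52)), at_time=120)
        assert (a.stage, a.trigger) == (1, "scr_rel_7d_50")

    def test_constant_series_stage0(self):
        a = stage_from_scr(scr_series((0, 1.1), (24, 1.1), (48, 1.1)), at_time=48)
        assert (a.stage, a.trigger) == (0, "none")

    def test_rise_outside_48h_window_not_absolute_trigger(self):
        # 0.35 mg/dL rise but spread over 72 h and below 50% relative
        a = stage_from_scr(scr_series((0, 1.00), (72, 1.35)), at_time=72)
        assert a.stage == 0

    def test_query_before_first_observation(self):
        a = stage_from_scr(scr_series((24, 1.0)), at_time=10)
        assert (a.stage, a.trigger) == (0, "none")

    def test_empty_series_rejected(self):
        empty = LabSeries("scr", "mg/dL", np.array([]), np.array([]))
        with pytest.raises(ValueError):
            stage_from_scr(empty, at_time=0)

    def test_stage2_implies_stage1_predicate(self):
        """A >=100% rise always satisfies the >=50% rule as well."""
        rng = np.random.default_rng(4)
        for _ in range(200):
            n = rng.integers(2, 10)
            t = np.sort(rng.uniform(0, 168, n))
            t += np.arange(n) * 1e-3
            v = rng.uniform(0.5, 4.0, n)
            s = LabSeries("scr", "mg/dL", t, v)
            at = float(t[-1])
            current = s.last_at_or_before(at)
            ref = s.window(at - 168, at).values.min()
            if current / ref >= 2.0:
                assert current / ref >= 1.5
                assert stage_from_scr(s, at).stage >= 2

    def test_monotone_adding_higher_value_never_lowers_stage(self):
        rng = np.random.default_rng(9)
        for _ in range(200):
            n = int(rng.integers(2, 8))
            t = np.sort(rng.uniform(0, 160, n)) + np.arange(n) * 1e-3
            v = rng.uniform(0.6, 3.0, n)
            s = LabSeries("scr", "mg/dL", t, v)
            at = float(t[-1]) + 1.0
            base_stage = stage_from_scr(s, at).stage
            # append a strictly higher terminal observation at the query time
            t2 = np.append(t, at)
            v2 = np.append(v, v.max() * 1.01)
            assert stage_from_scr(LabSeries("scr", "mg/dL", t2, v2), at).stage >= base_stage


class TestUopStaging:
    def test_seven_hour_run_stage1(self):
        a = stage_from_uop(uop_series([0.4] * 7), weight=80, at_time=24)
        assert (a.stage, a.trigger) == (1, "uop_6h")

    def test_thirteen_hour_run_stage2(self):
        a = stage_from_uop(uop_series([0.4] * 13), weight=80, at_time=24)
        assert (a.stage, a.trigger) == (2, "uop_12h")

    def test_broken_run_stage0(self):
        vals = [0.4] * 5 + [0.6] + [0.4] * 5
        a = stage_from_uop(uop_series(vals), weight=80, at_time=24)
        assert a.stage == 0

    def test_gap_breaks_run(self):
        # 3 hours, a 2-hour gap, then 4 hours: no 6-consecutive-hour run
        t = np.array([1, 2, 3, 6, 7, 8, 9], float)
        s = LabSeries("uop", "mL/kg/h", t, np.full(7, 0.4))
        assert stage_from_uop(s, weight=80, at_time=24).stage == 0

    def test_ml_per_hour_unit_uses_weight(self):
        s = LabSeries("uop", "mL/h", 1.0 + np.arange(7.0), np.full(7, 32.0))
        assert stage_from_uop(s, weight=80, at_time=24).stage == 1  # 0.4 mL/kg/h
        assert stage_from_uop(s, weight=40, at_time=24).stage == 0  # 0.8 mL/kg/h


class TestCombinedStage:
    def patient_labs(self):
        scr = scr_series((0, 1.0), (24, 1.0), (48, 1.0))
        uop = uop_series([1.0] * 24)
        return scr, uop

    def test_krt_forces_stage3(self):
        scr, uop = self.patient_labs()
        a = kdigo_stage(scr, uop, krt_start_day=1, weight=80, at_time=48)
        assert (a.stage, a.trigger) == (3, "krt")

    def test_max_of_components(self):
        scr = scr_series((0, 1.0), (48, 1.4))  # stage 1 absolute
        uop = uop_series([0.4] * 13)  # stage 2
        a = kdigo_stage(scr, uop, None, weight=80, at_time=24)
        assert a.stage == 2

    def test_all_normal_stage0(self):
        scr, uop = self.patient_labs()
        assert kdigo_stage(scr, uop, None, weight=80, at_time=48).stage == 0

    def test_requires_some_series(self):
        with pytest.raises(ValueError):
            kdigo_stage(None, None, None, weight=80, at_time=0)

    def test_matches_brute_force_window_scan(self):
        """Staging equals a brute-force scan over all (reference, current)
        pairs and oliguria windows on random series of <= 20 points."""
        rng = np.random.default_rng(21)

        def brute(scr, uop, at):
            stage = 0
            cur = scr.last_at_or_before(at)
            if cur is not None:
                for t0, v0 in zip(scr.times_h, scr.values):
                    if t0 > at:
                        continue
                    if at - 48 <= t0 and cur - v0 >= 0.3:
                        stage = max(stage, 1)
                    if at - 168 <= t0:
                        if cur / v0 >= 2.0:
                            stage = max(stage, 2)
                        elif cur / v0 >= 1.5:
                            stage = max(stage, 1)
            # oliguria: scan every consecutive run in the 24h lookback
            pts = [(t, v) for t, v in zip(uop.times_h, uop.values)
                   if at - 24 <= t <= at]
            run = 0
            prev = None
            best = 0
            for t, v in pts:
                if v < 0.5 and (prev is None or t - prev <= 1.0 + 1e-9) and run:
                    run += 1
                elif v < 0.5:
                    run = 1
                else:
                    run = 0
                best = max(best, run)
                prev = t
            if best >= 12:
                stage = max(stage, 2)
            elif best >= 6:
                stage = max(stage, 1)
            return stage

        for _ in range(300):
            n_scr = int(rng.integers(1, 10))
            t_scr = np.sort(rng.uniform(0, 200, n_scr)) + np.arange(n_scr) * 1e-3
            v_scr = rng.uniform(0.5, 3.0, n_scr)
            scr = LabSeries("scr", "mg/dL", t_scr, v_scr)
            n_uop = int(rng.integers(1, 20))
            start = float(rng.uniform(0, 10))
            step = rng.choice([1.0, 1.0, 2.0])
            t_uop = start + np.arange(n_uop) * step
            v_uop = rng.uniform(0.2, 1.2, n_uop)
            uop = LabSeries("uop", "mL/kg/h", t_uop, v_uop)
            at = float(rng.uniform(0, 200))
            got = kdigo_stage(scr, uop, None, weight=80, at_time=at).stage
            assert got == brute(scr, uop, at)


class TestRiskScoreAndScreening:
    def config(self):
        return AkiRiskConfig(factor_weights={"sepsis": 3, "vasopressors": 3,
                                             "diabetes": 2, "minor": 5},
                             threshold=6)

    def test_two_factors_meet_threshold(self):
        score, eligible = aki_risk_score({"sepsis", "vasopressors"}, self.config())
        assert (score, eligible) == (6, True)

    def test_empty_set_not_eligible(self):
        assert aki_risk_score(set(), self.config()) == (0, False)

    def test_single_factor_below_threshold(self):
        score, eligible = aki_risk_score({"minor"}, self.config())
        assert (score, eligible) == (5, False)

    def test_unknown_factor_named_in_error(self):
        with pytest.raises(KeyError, match="dialysis"):
            aki_risk_score({"dialysis"}, self.config())

    def screening_patient(self, ca=8.5, po4=4.0, egfr=60.0, aki=True, **kw):
        labs = {
            "calcium": LabSeries("calcium", "mg/dL", np.array([0.0]), np.array([ca])),
            "phosphate": LabSeries("phosphate", "mg/dL", np.array([0.0]), np.array([po4])),
            "scr": scr_series((0, 1.0)),
        }
        return PatientRecord(
            id="S1", arm="placebo", age=60, sex="F", icu_type="medical", apache2=20,
            septic_shock=True, aki_on_enrollment=aki, weight=70, baseline_scr=1.0,
            egfr=egfr, risk_factors=("sepsis", "vasopressors"), labs=labs, **kw,
        )

    def test_eligible_stage1_patient_included(self):
        d = screen_eligibility(self.screening_patient(), AkiRiskConfig())
        assert d.decision == "include"

    def test_high_calcium_excluded(self):
        d = screen_eligibility(self.screening_patient(ca=9.5), AkiRiskConfig())
        assert d.decision == "exclude" and "calcium" in d.reasons

    def test_high_phosphate_excluded(self):
        d = screen_eligibility(self.screening_patient(po4=6.5), AkiRiskConfig())
        assert d.decision == "exclude" and "phosphate" in d.reasons

    def test_stage2_excluded(self):
        d = screen_eligibility(self.screening_patient(), AkiRiskConfig(),
                               enrollment_stage=2)
        assert d.decision == "exclude" and "kdigo_ge2" in d.reasons

    def test_low_egfr_excluded(self):
        d = screen_eligibility(self.screening_patient(egfr=10.0), AkiRiskConfig())
        assert d.decision == "exclude" and "egfr_lt_15" in d.reasons

    def test_no_aki_no_risk_excluded(self):
        p = self.screening_patient(aki=False)
        p.risk_factors = ()
        d = screen_eligibility(p, AkiRiskConfig())
        assert d.decision == "exclude" and "no_aki_or_risk" in d.reasons

    def test_missing_lab_unscreenable(self):
        p = self.screening_patient()
        del p.labs["calcium"]
        d = screen_eligibility(p, AkiRiskConfig())
        assert d.decision == "unscreenable" and "calcium_missing" in d.reasons
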