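"""Secondary endpoints, safety flags, Fisher/chi-square contrasts, the
repeated-measures model, Rubin pooling, SOFA, and biomarker normalization."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from akirank.records import LabSeries, PatientRecord
from akirank.secondary import (
    compare_binary,
    free_days,
    krt_or_death,
    longitudinal_compare,
    mice_pool,
    new_or_progressive_aki,
    normalize_kim1,
    peak_scr,
    safety_flags,
    sofa_daily,
    vitamin_d_status,
)


def daily(analyte, unit, values):
    return LabSeries(analyte, unit, np.arange(len(values)) * 24.0,
                     np.asarray(values, float))


class TestFreeDays:
    def test_survivor_simple_difference(self):
        assert free_days(5, None) == 23

    def test_death_before_horizon_scores_zero(self):
        assert free_days(5, 10) == 0

    def test_long_stay_floors_at_zero(self):
        assert free_days(30, None) == 0

    def test_negative_stay_rejected(self):
        with pytest.raises(ValueError):
            free_days(-1, None)

    @given(st.integers(0, 60), st.one_of(st.none(), st.integers(0, 60)))
    def test_bounds_and_monotonicity(self, stay, death):
        fd = free_days(stay, death)
        assert 0 <= fd <= 28
        assert free_days(stay + 1, death) <= fd


class TestAkiProgressionEndpoints:
    def patient(self, scr_values, krt=None, death=None):
        labs = {"scr": daily("scr", "mg/dL", scr_values)}
        return PatientRecord(
            id="Q1", arm="placebo", age=55, sex="M", icu_type="medical",
            apache2=18, septic_shock=False, aki_on_enrollment=False, weight=80,
            baseline_scr=scr_values[0], krt_start_day=krt, death_day=death,
            labs=labs,
        )

    def test_new_stage1_counts(self):
        p = self.patient([1.0, 1.0, 1.0, 1.45, 1.45, 1.45, 1.45, 1.45])
        assert new_or_progressive_aki(p, enrollment_stage=0)

    def test_stable_stage_does_not_count(self):
        p = self.patient([1.0] * 8)
        assert not new_or_progressive_aki(p, enrollment_stage=1)

    def test_krt_is_progression_from_stage1(self):
        p = self.patient([1.0] * 8, krt=2)
        assert new_or_progressive_aki(p, enrollment_stage=1)

    def test_krt_or_death(self):
        assert krt_or_death(self.patient([1.0] * 8, death=6))
        assert not krt_or_death(self.patient([1.0] * 8))

    def test_peak_scr(self):
        p = self.patient([1.0, 2.4, 1.5, 1.0, 1.0, 1.0, 1.0, 1.0])
        assert peak_scr(p.lab("scr")) == pytest.approx(2.4)


class TestSafetyFlags:
    def test_hypercalcemia_peak_reported(self):
        ca = daily("calcium", "mg/dL", [9.0, 9.5, 10.0, 10.4, 10.9, 11.2, 11.4, 11.6])
        po4 = daily("phosphate", "mg/dL", [4.0] * 8)
        f = safety_flags(ca, po4)
        assert f.hypercalcemia
        assert f.peak_calcium == pytest.approx(11.6)
        assert f.peak_calcium_day == 7

    def test_boundary_values_do_not_flag(self):
        ca = daily("calcium", "mg/dL", [10.7] * 8)
        po4 = daily("phosphate", "mg/dL", [6.0] * 8)
        f = safety_flags(ca, po4)
        assert not f.hypercalcemia and not f.hyperphosphatemia

    def test_hyperphosphatemia_strictly_above(self):
        ca = daily("calcium", "mg/dL", [9.0] * 8)
        po4 = daily("phosphate", "mg/dL", [4.0, 6.01, 4.0, 4.0, 4.0, 4.0, 4.0, 4.0])
        assert safety_flags(ca, po4).hyperphosphatemia


class TestCompareBinary:
    def test_balanced_table_p_one(self):
        assert compare_binary(2, 4, 2, 4, "fisher") == pytest.approx(1.0)

    def test_disjoint_five_vs_five(self):
        # margins (5,5,5,5): only the two extreme tables have pmf <= observed
        assert compare_binary(0, 5, 5, 5, "fisher") == pytest.approx(2 / 252)

    def test_krt_counts_contrast(self):
        """1/51 vs 4/49 (the KRT comparison scale) matches the
        hypergeometric enumeration oracle."""
        def oracle(a, n1, b, n2):
            k, n = a + b, n1 + n2
            support = range(max(0, k - n2), min(k, n1) + 1)
            pmf = {x: math.comb(n1, x) * math.comb(n2, k - x) / math.comb(n, k)
                   for x in support}
            return min(1.0, sum(p for p in pmf.values() if p <= pmf[a] * (1 + 1e-7)))

        got = compare_binary(1, 51, 4, 49, "fisher")
        assert got == pytest.approx(oracle(1, 51, 4, 49))
        ref = stats.fisher_exact([[1, 50], [4, 45]]).pvalue
        assert got == pytest.approx(float(ref))

    def test_matches_scipy_on_random_tables(self, rng):
        for _ in range(50):
            n1, n2 = rng.integers(1, 30, size=2)
            a, b = rng.integers(0, n1 + 1), rng.integers(0, n2 + 1)
            ours = compare_binary(int(a), int(n1), int(b), int(n2), "fisher")
            ref = stats.fisher_exact([[a, n1 - a], [b, n2 - b]]).pvalue
            assert ours == pytest.approx(float(ref), abs=1e-10)

    def test_chi2_no_continuity_correction(self):
        ours = compare_binary(12, 40, 22, 40, "chi2")
        ref = stats.chi2_contingency([[12, 28], [22, 18]], correction=False)[1]
        assert ours == pytest.approx(float(ref))

    def test_zero_size_group_rejected(self):
        with pytest.raises(ValueError):
            compare_binary(0, 0, 1, 5)


def _long_frame(n_per_arm, offset, noise_sd, rng, times=(0, 1, 2, 3)):
    rows = []
    for arm, shift in (("active", offset), ("placebo", 0.0)):
        for i in range(n_per_arm):
            base = rng.normal(0, 1.0)
            for t in times:
                rows.append({
                    "patient_id": f"{arm}{i}", "arm": arm, "time": float(t),
                    "value": 10.0 + shift + base + rng.normal(0, noise_sd),
                })
    return pd.DataFrame(rows)


class TestLongitudinalCompare:
    def test_identical_trajectories_p_one(self):
        rows = []
        for arm in ("active", "placebo"):
            for i in range(10):
                for t in range(4):
                    rows.append({"patient_id": f"{arm}{i}", "arm": arm,
                                 "time": float(t), "value": 10.0 + t})
        res = longitudinal_compare(pd.DataFrame(rows))
        assert res.estimable and res.p_value == pytest.approx(1.0)

    def test_planted_offset_detected(self, rng):
        df = _long_frame(50, offset=3.0, noise_sd=0.3, rng=rng)
        res = longitudinal_compare(df)
        assert res.estimable and res.p_value < 0.001

    def test_null_rejection_rate_near_nominal(self, rng):
        """With permuted arm labels the group effect rejects at roughly the
        nominal rate."""
        hits = 0
        reps = 60
        for _ in range(reps):
            df = _long_frame(12, offset=0.0, noise_sd=1.0, rng=rng)
            ids = df.patient_id.unique()
            relab = dict(zip(ids, rng.permutation(
                [("active" if i < len(ids) // 2 else "placebo")
                 for i in range(len(ids))])))
            df["arm"] = df.patient_id.map(relab)
            res = longitudinal_compare(df)
            if res.estimable and res.p_value < 0.05:
                hits += 1
        # 95% binomial band around 0.05 at 60 reps: accept 0..8 rejections
        assert hits <= 8

    def test_single_arm_not_estimable(self):
        df = pd.DataFrame({"patient_id": ["a", "a"], "arm": ["x", "x"],
                           "time": [0.0, 1.0], "value": [1.0, 2.0]})
        assert not longitudinal_compare(df).estimable


class TestMicePool:
    def frame(self, rng, n=80, missing=0.0):
        x = rng.normal(0, 1, n)
        y = 2.0 + 1.5 * x + rng.normal(0, 0.5, n)
        df = pd.DataFrame({"x": x, "y": y})
        if missing:
            mask = rng.uniform(size=n) < missing
            df.loc[mask, "x"] = np.nan
        return df

    def test_no_missingness_is_identity(self, rng):
        import statsmodels.formula.api as smf

        df = self.frame(rng)
        pooled = mice_pool(df, "y ~ x", m=5, seed=1)
        fit = smf.ols("y ~ x", df).fit()
        assert pooled["estimate"].to_numpy() == pytest.approx(fit.params.to_numpy())
        assert pooled["se"].to_numpy() == pytest.approx(fit.bse.to_numpy())

    def test_single_imputation_se_has_no_between_component(self, rng):
        df = self.frame(rng, missing=0.2)
        pooled = mice_pool(df, "y ~ x", m=1, seed=2)
        assert np.all(np.isfinite(pooled["se"]))
        assert np.all(np.isinf(pooled["df"]))  # B = 0 when m = 1

    def test_mcar_recovery_of_slope(self, rng):
        """Pooled slope CI covers the generating slope in most replicates
        under 20% MCAR missingness."""
        cover = 0
        reps = 20
        for i in range(reps):
            df = self.frame(rng, n=120, missing=0.2)
            pooled = mice_pool(df, "y ~ x", m=5, seed=100 + i)
            est, se = pooled.loc["x", "estimate"], pooled.loc["x", "se"]
            if abs(est - 1.5) <= 1.96 * se:
                cover += 1
        assert cover >= int(0.9 * reps) - 2

    def test_all_missing_column_rejected(self):
        df = pd.DataFrame({"x": [np.nan, np.nan], "y": [1.0, 2.0]})
        with pytest.raises(ValueError):
            mice_pool(df, "y ~ x")


class TestSofa:
    def test_all_normal_zero(self):
        inputs = dict(respiration_pf=450, coagulation_platelets=250,
                      liver_bilirubin=0.5, cardiovascular_map=80,
                      cns_gcs=15, renal_creatinine=0.9)
        assert sofa_daily(inputs) == (0, ())

    def test_all_worst_twenty_four(self):
        inputs = dict(respiration_pf=60, coagulation_platelets=10,
                      liver_bilirubin=15.0, cardiovascular_category=4,
                      cns_gcs=3, renal_creatinine=6.0)
        score, missing = sofa_daily(inputs)
        assert score == 24 and missing == ()

    def test_single_organ_failure(self):
        inputs = dict(respiration_pf=450, coagulation_platelets=250,
                      liver_bilirubin=0.5, cardiovascular_map=80,
                      cns_gcs=15, renal_creatinine=6.0)
        assert sofa_daily(inputs)[0] == 4

    def test_missing_organ_scores_zero_and_flags(self):
        inputs = dict(respiration_pf=450, coagulation_platelets=250,
                      liver_bilirubin=0.5, cardiovascular_map=80,
                      cns_gcs=15)
        score, missing = sofa_daily(inputs)
        assert score == 0 and missing == ("renal_creatinine",)


class TestKim1AndVitdStatus:
    def test_normalization_ratio(self):
        assert normalize_kim1(1000.0, 100.0) == pytest.approx(10.0)

    def test_zero_creatinine_rejected(self):
        with pytest.raises(ValueError):
            normalize_kim1(1000.0, 0.0)

    @given(st.floats(1e-3, 1e6), st.floats(1e-3, 1e6), st.floats(0.1, 10))
    def test_scale_invariance(self, kim1, cr, k):
        assert normalize_kim1(kim1 * k, cr * k) == pytest.approx(
            normalize_kim1(kim1, cr)
        )

    def test_status_percentages_round_to_one_decimal(self):
        levels = [5.0] * 37 + [15.0] * 51 + [25.0] * 42 + [35.0] * 19
        s = vitamin_d_status(levels)
        assert s["n"] == 149
        assert s["insufficient_lt30_count"] == 130
        assert s["insufficient_lt30_pct"] == 87.2
        assert s["deficient_lt20_count"] == 88
        assert s["deficient_lt20_pct"] == 59.1
        assert s["severe_lt10_count"] == 37
        assert s["severe_lt10_pct"] == 24.8
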