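import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vitdmr.phenotypes import (
    MissingFieldError,
    abnormal_bp,
    average_repeated,
    bmi,
    classify_ms,
    classify_t2d,
    homa_ir,
    insulin_pmol_to_uiu,
    phenotype_cohort,
    vitd_category,
    vitd_quintiles,
    whr,
)


class TestAverageRepeated:
    def test_two_close_readings_are_averaged(self):
        assert average_repeated((80.0, 80.5), 1.0) == pytest.approx(80.25)

    def test_three_readings_use_closest_pair(self):
        assert average_repeated((80.0, 82.0, 80.6), 1.0) == pytest.approx(80.3)

    def test_blood_pressure_closest_pair(self):
        assert average_repeated((120, 132, 124), 10.0) == pytest.approx(122.0)

    def test_two_discrepant_readings_require_a_third(self):
        with pytest.raises(ValueError, match="third"):
            average_repeated((80.0, 82.0), 1.0)

    def test_fewer_than_two_readings_rejected(self):
        with pytest.raises(ValueError):
            average_repeated((80.0,), 1.0)

    def test_equidistant_third_averages_with_earlier_reading(self):
        # third reading 81 is 3 away from both 78 and 84: tie-break pairs it
        # with the earlier reading -> (78 + 81) / 2
        assert average_repeated((78.0, 84.0, 81.0), 1.0) == pytest.approx(79.5)


class TestIndices:
    @pytest.mark.parametrize(
        "fbg, ins, expected", [(4.5, 10, 2.0), (22.5, 1, 1.0), (5.6, 12, 67.2 / 22.5)]
    )
    def test_homa_ir(self, fbg, ins, expected):
        assert homa_ir(fbg, ins) == pytest.approx(expected, abs=1e-9)

    def test_homa_ir_rejects_non_positive(self):
        with pytest.raises(ValueError):
            homa_ir(0.0, 10)

    @pytest.mark.parametrize("w, h, expected", [(81, 1.8, 25.0), (60, 1.5, 60 / 2.25)])
    def test_bmi(self, w, h, expected):
        assert bmi(w, h) == pytest.approx(expected, abs=1e-9)

    def test_whr(self):
        assert whr(90, 100) == pytest.approx(0.9)

    def test_zero_height_rejected(self):
        with pytest.raises(ValueError):
            bmi(70, 0.0)

    def test_insulin_unit_conversion(self):
        assert insulin_pmol_to_uiu(6.945) == pytest.approx(1.0)


def _ms_record(flags, sex="male"):
    """Construct a record realizing exactly the requested component flags."""
    obesity, tg, hdl, bp, glucose = flags
    wc_cut = 85.0 if sex == "male" else 80.0
    hdl_cut = 1.0 if sex == "male" else 1.3
    return {
        "sex": sex,
        "wc_cm": wc_cut + 5 if obesity else wc_cut - 10,
        "tg_mmol_l": 1.8 if tg else 1.0,
        "hdl_mmol_l": hdl_cut - 0.2 if hdl else hdl_cut + 0.3,
        "sbp_mmhg": 135.0 if bp else 120.0,
        "dbp_mmhg": 70.0,
        "fbg_mmol_l": 5.8 if glucose else 4.8,
        "med_tg_lowering": False,
        "med_hdl_raising": False,
        "med_antihypertensive": False,
        "med_antidiabetic": False,
    }


class TestClassifyMs:
    def test_truth_table_all_32_component_combinations(self):
        """MS is diagnosed exactly when >= 3 of the 5 components are abnormal."""
        for flags in itertools.product([False, True], repeat=5):
            result = classify_ms(_ms_record(flags))
            assert (
                result.central_obesity,
                result.high_tg,
                result.low_hdl,
                result.high_bp,
                result.high_glucose,
            ) == flags
            assert result.n_abnormal == sum(flags)
            assert result.ms_case == (sum(flags) >= 3)

    def test_three_flags_make_a_case(self):
        rec = _ms_record((True, True, True, False, False))
        rec.update(wc_cm=90.0, tg_mmol_l=1.8, hdl_mmol_l=0.9, sbp_mmhg=120.0, fbg_mmol_l=5.0)
        result = classify_ms(rec)
        assert result.n_abnormal == 3 and result.ms_case

    def test_boundary_values_honor_inclusive_exclusive_conventions(self):
        # WC 85 (inclusive) and TG 1.7 (inclusive) abnormal; HDL 1.0 is NOT
        # < 1.0; BP 129/84 below both cutoffs; FBG 5.5 below 5.6.
        rec = dict(
            sex="male", wc_cm=85.0, tg_mmol_l=1.7, hdl_mmol_l=1.0,
            sbp_mmhg=129.0, dbp_mmhg=84.0, fbg_mmol_l=5.5,
            med_tg_lowering=False, med_hdl_raising=False,
            med_antihypertensive=False, med_antidiabetic=False,
        )
        result = classify_ms(rec)
        assert result.central_obesity and result.high_tg
        assert not (result.low_hdl or result.high_bp or result.high_glucose)
        assert not result.ms_case

    def test_female_cutoffs(self):
        rec = _ms_record((False,) * 5, sex="female")
        rec.update(wc_cm=80.0, hdl_mmol_l=1.29)
        result = classify_ms(rec)
        assert result.central_obesity and result.low_hdl

    def test_medication_implies_component_abnormal(self):
        rec = _ms_record((False,) * 5)
        rec.update(med_tg_lowering=True, med_antihypertensive=True, med_antidiabetic=True)
        result = classify_ms(rec)
        assert result.high_tg and result.high_bp and result.high_glucose
        assert result.ms_case

    def test_missing_field_flags_record_unclassifiable(self):
        rec = _ms_record((False,) * 5)
        rec["tg_mmol_l"] = None
        with pytest.raises(MissingFieldError, match="tg_mmol_l"):
            classify_ms(rec)


class TestClassifyT2d:
    @pytest.mark.parametrize(
        "fbg, ogtt, med, prior, expected",
        [
            (7.0, np.nan, False, False, True),   # FBG threshold inclusive
            (6.0, 11.1, False, False, True),     # OGTT threshold inclusive
            (5.0, np.nan, False, False, False),
            (5.0, np.nan, True, False, True),
            (5.0, np.nan, False, True, True),
            (6.9, 11.0, False, False, False),
        ],
    )
    def test_diagnostic_rules(self, fbg, ogtt, med, prior, expected):
        rec = {
            "fbg_mmol_l": fbg, "ogtt_2h_mmol_l": ogtt,
            "med_antidiabetic": med, "prior_t2d_diagnosis": prior,
        }
        assert classify_t2d(rec) is expected

    @given(
        fbg=st.floats(min_value=3.0, max_value=12.0),
        bump=st.floats(min_value=0.0, max_value=5.0),
    )
    @settings(deadline=None, max_examples=50)
    def test_monotone_in_fbg(self, fbg, bump):
        """Raising fasting glucose can never undo a diabetes diagnosis."""
        base = {"fbg_mmol_l": fbg, "med_antidiabetic": False, "prior_t2d_diagnosis": False}
        higher = dict(base, fbg_mmol_l=fbg + bump)
        assert classify_t2d(higher) >= classify_t2d(base)


class TestVitdCategory:
    @pytest.mark.parametrize(
        "vitd, label",
        [
            (24.9, "severe_deficiency"),
            (25.0, "deficiency"),
            (49.99, "deficiency"),
            (50.0, "insufficiency"),
            (75.0, "sufficiency"),
            (200.0, "sufficiency"),
        ],
    )
    def test_half_open_boundaries(self, vitd, label):
        assert vitd_category(vitd) == label

    def test_non_positive_rejected(self):
        with pytest.raises(ValueError):
            vitd_category(0.0)

    @given(vitd=st.floats(min_value=1e-6, max_value=500.0))
    @settings(deadline=None, max_examples=100)
    def test_partition_of_positive_axis(self, vitd):
        """Every positive concentration falls in exactly one category."""
        label = vitd_category(vitd)
        bounds = {
            "severe_deficiency": (0, 25), "deficiency": (25, 50),
            "insufficiency": (50, 75), "sufficiency": (75, np.inf),
        }[label]
        assert bounds[0] <= vitd < bounds[1]


class TestVitdQuintiles:
    def test_highest_concentration_is_q1(self):
        values = pd.Series(np.arange(1.0, 101.0))
        q = vitd_quintiles(values)
        assert q.iloc[-1] == "Q1" and q.iloc[0] == "Q5"
        assert (q.value_counts() == 20).all()

    def test_boundary_tie_goes_to_lower_concentration_group(self):
        values = pd.Series([10.0, 20.0, 30.0, 40.0, 50.0])
        q = vitd_quintiles(values)
        # 20th percentile is ~13.2; the exact boundary membership convention:
        # a value equal to a cutpoint stays in the lower-concentration group
        cuts = np.quantile(values, [0.2, 0.4, 0.6, 0.8])
        tied = vitd_quintiles(pd.Series([cuts[0]] * 2 + [100.0] * 3))
        assert tied.iloc[0] == "Q5"

    def test_missing_values_rejected(self):
        with pytest.raises(ValueError):
            vitd_quintiles(pd.Series([10.0, np.nan]))


class TestAbnormalBp:
    @pytest.mark.parametrize(
        "sbp, dbp, med, expected",
        [
            (130, 80, False, (True, False)),
            (120, 85, False, (False, True)),
            (110, 70, True, (True, True)),  # medication clause applies to both
        ],
    )
    def test_include_medication_rule(self, sbp, dbp, med, expected):
        rec = {"sbp_mmhg": sbp, "dbp_mmhg": dbp, "med_antihypertensive": med}
        assert abnormal_bp(rec, med_rule="include") == expected

    def test_exclude_medication_rule_is_threshold_only(self):
        rec = {"sbp_mmhg": 110, "dbp_mmhg": 70, "med_antihypertensive": True}
        assert abnormal_bp(rec, med_rule="exclude") == (False, False)


class TestPhenotypeCohort:
    def test_derived_columns_and_consistency(self, default_cohort):
        pheno = phenotype_cohort(default_cohort)
        for col in ("bmi", "whr", "homa_ir", "ms_case", "t2d_case",
                    "abnormal_sbp", "abnormal_dbp", "vitd_category", "vitd_quintile"):
            assert col in pheno.columns
        np.testing.assert_allclose(
            pheno["homa_ir"], pheno["fbg_mmol_l"] * pheno["insulin_uiu_ml"] / 22.5
        )
        # the BP component of MS and the abnormal-BP outcomes share cutoffs
        high_bp_rows = (pheno["sbp_mmhg"] >= 130) | (pheno["dbp_mmhg"] >= 85) | (
            pheno["med_antihypertensive"] == 1
        )
        assert (pheno["abnormal_sbp"] | pheno["abnormal_dbp"]).equals(
            pd.Series(high_bp_rows, name=None).astype("boolean")
        )

    def test_missing_field_marks_row_not_drops_it(self, default_cohort):
        broken = default_cohort.copy()
        broken.loc[broken.index[3], "tg_mmol_l"] = np.nan
        pheno = phenotype_cohort(broken)
        assert len(pheno) == len(broken)
        assert pd.isna(pheno.loc[pheno.index[3], "ms_case"])
        assert broken.index[3] in pheno.attrs["unclassifiable_rows"]
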