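import warnings

import numpy as np
import pandas as pd
import pytest

from urinorm.io import CreatinineAssay, PeakTable, SampleSheet
from urinorm.normalise import (NormalisationError, find_creatinine_feature,
                               normalise_area_percent, normalise_assay_creatinine,
                               normalise_ms_creatinine, normalise_pooled_creatinine)


def _one_subject_table(values_row):
    n = len(values_row)
    cols = [f"s{i}" for i in range(n)]
    labels = ["P1", "P2", "PT1", "PT2", "PT3", "PT4", "PT5", "PT6", "PT7", "PT8"][:n]
    peaks = PeakTable(pd.DataFrame([values_row], index=["m1"], columns=cols),
                      pd.DataFrame({"name": ["m1"]}, index=["m1"]))
    sheet = SampleSheet(pd.DataFrame(
        {"subject_id": ["S1"] * n, "timepoint_label": labels},
        index=pd.Index(cols, name="sample_id")))
    return peaks, sheet


class TestAreaPercent:
    @pytest.mark.parametrize("row,expected", [
        ([5.0, 5.0, 5.0, 5.0], [25.0, 25.0, 25.0, 25.0]),
        ([1.0, 3.0], [25.0, 75.0]),
    ])
    def test_forced_arithmetic(self, row, expected):
        peaks, sheet = _one_subject_table(row)
        out = normalise_area_percent(peaks, sheet)
        assert np.allclose(out.values.loc["m1"], expected)

    def test_zero_sum_becomes_missing_with_warning(self):
        peaks, sheet = _one_subject_table([0.0, 0.0, 0.0])
        with pytest.warns(UserWarning, match="zero within-subject sum"):
            out = normalise_area_percent(peaks, sheet)
        assert out.values.loc["m1"].isna().all()

    def test_single_sample_subject_rejected(self):
        peaks, sheet = _one_subject_table([4.0])
        with pytest.raises(NormalisationError, match="at least 2"):
            normalise_area_percent(peaks, sheet)

    def test_rows_sum_to_100_per_subject(self, tiny_peaks, tiny_sheet):
        out = normalise_area_percent(tiny_peaks, tiny_sheet)
        for subject in tiny_sheet.subjects:
            sums = out.values[tiny_sheet.samples_of(subject)].sum(axis=1)
            assert np.allclose(sums, 100.0, rtol=1e-9)

    def test_invariant_under_per_metabolite_subject_rescaling(self, tiny_peaks, tiny_sheet):
        out0 = normalise_area_percent(tiny_peaks, tiny_sheet)
        scaled = tiny_peaks.copy()
        scaled.values.loc["m_var", tiny_sheet.samples_of("A")] *= 7.0
        out1 = normalise_area_percent(scaled, tiny_sheet)
        pd.testing.assert_frame_equal(out0.values, out1.values)

    def test_not_invariant_under_per_sample_rescaling(self, tiny_peaks, tiny_sheet):
        out0 = normalise_area_percent(tiny_peaks, tiny_sheet)
        scaled = tiny_peaks.copy()
        scaled.values["A_P1"] *= 3.0
        out1 = normalise_area_percent(scaled, tiny_sheet)
        assert not np.allclose(out0.values, out1.values)

    def test_missing_policy_propagate_poisons_block(self, tiny_peaks, tiny_sheet):
        tiny_peaks.values.loc["m_var", "A_P1"] = np.nan
        as_zero = normalise_area_percent(tiny_peaks, tiny_sheet, "as_zero")
        # remaining sample carries 100% of the observed output
        assert as_zero.values.loc["m_var", "A_PT1"] == pytest.approx(100.0)
        prop = normalise_area_percent(tiny_peaks, tiny_sheet, "propagate")
        assert prop.values.loc["m_var", tiny_sheet.samples_of("A")].isna().all()
        # other subject untouched either way
        assert prop.values.loc["m_var", "B_P1"] == pytest.approx(25.0)


class TestCreatinineStrategies:
    def test_ms_creatinine_forced_arithmetic(self, tiny_peaks):
        out = normalise_ms_creatinine(tiny_peaks)
        assert out.values.loc["m_flat", "A_P1"] == pytest.approx(0.5)  # 5 / 10
        assert np.allclose(out.values.loc["creat"], 1.0)  # self-division

    def test_ms_creatinine_invariant_under_per_sample_rescaling(self, tiny_peaks):
        out0 = normalise_ms_creatinine(tiny_peaks)
        scaled = tiny_peaks.copy()
        scaled.values["B_PT1"] *= 11.0
        out1 = normalise_ms_creatinine(scaled)
        pd.testing.assert_frame_equal(out0.values, out1.values)

    def test_ms_creatinine_zero_divisor_rejected(self, tiny_peaks):
        tiny_peaks.values.loc["creat", "A_PT1"] = 0.0
        with pytest.raises(NormalisationError, match="A_PT1"):
            normalise_ms_creatinine(tiny_peaks)

    def test_pooled_forced_arithmetic_and_between_subject_ratio(self, tiny_peaks, tiny_sheet):
        out = normalise_pooled_creatinine(tiny_peaks, tiny_sheet, {"A": 2.0, "B": 4.0})
        assert out.values.loc["m_flat", "A_P1"] == pytest.approx(2.5)
        # within-subject ratios unchanged; between-subject ratio halves
        raw = tiny_peaks.values.loc["m_var"]
        assert (out.values.loc["m_var", "A_PT1"] / out.values.loc["m_var", "A_P1"]
                == pytest.approx(raw["A_PT1"] / raw["A_P1"]))
        assert (out.values.loc["m_flat", "B_P1"] / out.values.loc["m_flat", "A_P1"]
                == pytest.approx(2.0 / 4.0))

    def test_pooled_missing_subject_rejected(self, tiny_peaks, tiny_sheet):
        with pytest.raises(NormalisationError, match="B"):
            normalise_pooled_creatinine(tiny_peaks, tiny_sheet, {"A": 2.0})

    def test_assay_forced_arithmetic(self, tiny_peaks, tiny_assay):
        out = normalise_assay_creatinine(tiny_peaks, tiny_assay)
        assert out.values.loc["m_var", "B_PT1"] == pytest.approx(3.0)  # 6 / 2

    def test_assay_dilution_invariance_when_assay_tracks_dilution(self, tiny_peaks, tiny_assay):
        """Scaling a sample AND its assay value by the same dilution factor
        leaves the output unchanged (the invariance the divisor is for)."""
        out0 = normalise_assay_creatinine(tiny_peaks, tiny_assay)
        scaled = tiny_peaks.copy()
        scaled.values["A_P1"] *= 5.0
        assay2 = CreatinineAssay(tiny_assay.concentrations * pd.Series(
            {"A_P1": 5.0, "A_PT1": 1.0, "B_P1": 1.0, "B_PT1": 1.0}))
        out1 = normalise_assay_creatinine(scaled, assay2)
        pd.testing.assert_frame_equal(out0.values, out1.values)

    def test_creatinine_strategies_not_invariant_under_block_rescaling(
            self, tiny_peaks, tiny_sheet, tiny_assay):
        """Counterexample: per-(metabolite, subject) rescaling changes the
        output of every creatinine strategy (it only cancels in area%)."""
        scaled = tiny_peaks.copy()
        scaled.values.loc["m_var", tiny_sheet.samples_of("A")] *= 7.0
        for out0, out1 in [
            (normalise_ms_creatinine(tiny_peaks), normalise_ms_creatinine(scaled)),
            (normalise_assay_creatinine(tiny_peaks, tiny_assay),
             normalise_assay_creatinine(scaled, tiny_assay)),
            (normalise_pooled_creatinine(tiny_peaks, tiny_sheet, {"A": 1.0, "B": 1.0}),
             normalise_pooled_creatinine(scaled, tiny_sheet, {"A": 1.0, "B": 1.0})),
        ]:
            assert not np.allclose(out0.values, out1.values, equal_nan=True)


class TestCreatinineFeatureDetection:
    def test_name_match(self, tiny_peaks):
        assert find_creatinine_feature(tiny_peaks) == "creat"

    def test_explicit_override(self, tiny_peaks):
        assert find_creatinine_feature(tiny_peaks, "m_flat") == "m_flat"

    def test_no_candidate_rejected(self, tiny_peaks):
        peaks = tiny_peaks.copy()
        peaks.annotations["name"] = ["x", "y", "z"]
        with pytest.raises(NormalisationError, match="creatinine"):
            find_creatinine_feature(peaks)

    def test_mass_arbitrates_between_candidates(self, tiny_peaks):
        peaks = tiny_peaks.copy()
        peaks.annotations.loc["m_flat", "name"] = "creatinine isomer"
        peaks.annotations.loc["m_flat", "mass"] = 150.0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert find_creatinine_feature(peaks) == "creat"


def test_strategies_are_order_equivariant(tiny_peaks, tiny_sheet, tiny_assay):
    """Permuting sample columns permutes every strategy's output identically."""
    perm = ["B_PT1", "A_P1", "B_P1", "A_PT1"]
    permuted = PeakTable(tiny_peaks.values[perm], tiny_peaks.annotations)
    for fn in [
        lambda p: normalise_area_percent(p, tiny_sheet),
        normalise_ms_creatinine,
        lambda p: normalise_assay_creatinine(p, tiny_assay),
    ]:
        out0 = fn(tiny_peaks)
        out1 = fn(permuted)
        pd.testing.assert_frame_equal(out0.values[perm], out1.values)
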