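"""Reference tables: validation, I/O round trip, interpolation, centiles."""

import numpy as np
import pytest
from scipy import stats as sps

import growthref as gr
from growthref.references import centile_curve_reference_from_lms


def write_ref(tmp_path, rows, header="sex,age,L,M,S"):
    path = tmp_path / "ref.csv"
    path.write_text(header + "\n" + "\n".join(rows) + "\n")
    return path


class TestReading:
    def test_reads_two_row_reference(self, tmp_path):
        path = write_ref(tmp_path, ["M,1.0,1,10,0.1", "M,2.0,1,12,0.1"])
        (ref,) = gr.read_lms_reference(path, measure="weight")
        assert ref.sex == "male" and len(ref.ages) == 2
        assert ref.age_span == (1.0, 2.0)
        assert ref.M.tolist() == [10.0, 12.0]

    def test_both_sexes_in_one_file_with_filter(self, tmp_path):
        path = write_ref(tmp_path, ["F,1,1,10,0.1", "F,2,1,12,0.1",
                                    "M,1,1,11,0.1", "M,2,1,13,0.1"])
        refs = gr.read_lms_reference(path, measure="weight")
        assert {r.sex for r in refs} == {"female", "male"}
        (only_f,) = gr.read_lms_reference(path, measure="weight", sex="F")
        assert only_f.M.tolist() == [10.0, 12.0]

    def test_age_in_months_flag(self, tmp_path):
        path = write_ref(tmp_path, ["M,12,1,10,0.1", "M,24,1,12,0.1"])
        (ref,) = gr.read_lms_reference(path, measure="weight",
                                       age_in_months=True)
        assert ref.ages.tolist() == [1.0, 2.0]

    def test_tab_delimited_and_column_map(self, tmp_path):
        path = tmp_path / "ref.tsv"
        path.write_text("sex\tagemos\tL\tM\tS\nM\t1\t1\t10\t0.1\nM\t2\t1\t12\t0.1\n")
        (ref,) = gr.read_lms_reference(path, measure="weight",
                                       column_map={"age": "agemos"})
        assert ref.M.tolist() == [10.0, 12.0]

    @pytest.mark.parametrize("rows, match", [
        (["M,2.0,1,10,0.1", "M,1.0,1,12,0.1", "M,0.5,1,9,0.1"],
         "non-increasing age"),      # unsorted input is sorted, dup check below
        (["M,1.0,1,10,0.1", "M,1.0,1,12,0.1"], "non-increasing age"),
        (["M,1.0,1,10,0.0", "M,2.0,1,12,0.1"], "non-positive S at row 0"),
        (["M,1.0,1,-5,0.1", "M,2.0,1,12,0.1"], "non-positive M at row 0"),
        (["M,1.0,1,ten,0.1", "M,2.0,1,12,0.1"], "non-numeric"),
    ])
    def test_validation_errors_name_the_problem(self, tmp_path, rows, match):
        path = write_ref(tmp_path, rows)
        if match == "non-increasing age" and rows[0].startswith("M,2.0"):
            # distinct ages in any order are simply sorted
            refs = gr.read_lms_reference(path, measure="weight")
            assert np.all(np.diff(refs[0].ages) > 0)
            return
        with pytest.raises(gr.ReferenceValidationError, match=match):
            gr.read_lms_reference(path, measure="weight")

    def test_missing_column_is_fatal(self, tmp_path):
        path = write_ref(tmp_path, ["M,1.0,1,10", "M,2.0,1,12"],
                         header="sex,age,L,M")
        with pytest.raises(gr.ReferenceValidationError, match="missing column"):
            gr.read_lms_reference(path, measure="weight")

    def test_write_read_round_trip(self, tmp_path, toy_reference):
        path = tmp_path / "out.csv"
        gr.write_lms_reference(path, [toy_reference])
        (back,) = gr.read_lms_reference(path, measure="weight", label="toy")
        for col in ("ages", "L", "M", "S"):
            np.testing.assert_array_equal(getattr(back, col),
                                          getattr(toy_reference, col))


class TestInterpolation:
    def test_linear_midpoint_and_knot_exactness(self, toy_reference):
        assert toy_reference.interpolate(1.5) == pytest.approx((1.0, 11.0, 0.1))
        assert toy_reference.interpolate(1.0) == (1.0, 10.0, 0.1)
        assert toy_reference.interpolate(2.0) == (1.0, 12.0, 0.1)

    def test_no_extrapolation(self, toy_reference):
        with pytest.raises(gr.AgeOutOfRangeError):
            toy_reference.interpolate(2.5)
        with pytest.raises(gr.AgeOutOfRangeError):
            toy_reference.interpolate(0.5)

    def test_interpolated_m_s_stay_positive_on_dense_grid(self):
        ref = gr.make_base_reference("weight", "female")
        ages = np.linspace(*ref.age_span, 997)
        _, M, S = ref.interpolate(ages)
        assert np.all(M > 0) and np.all(S > 0)


class TestCentileCurves:
    def test_median_curve_equals_m_column(self, toy_reference):
        curve = gr.centile_curve_from_lms(toy_reference, 50)
        np.testing.assert_allclose(curve["value"], toy_reference.M)

    def test_third_centile_hand_value(self, toy_reference):
        # 10 * (1 + 0.1 * z_0.03) with an independent quantile evaluation
        curve = gr.centile_curve_from_lms(toy_reference, 3)
        expected = 10 * (1 + 0.1 * sps.norm.ppf(0.03))
        assert curve["value"][0] == pytest.approx(expected, abs=1e-9)
        assert curve["value"][0] == pytest.approx(8.119, abs=5e-4)

    @pytest.mark.parametrize("p", [0, 100])
    def test_rejects_degenerate_centile(self, toy_reference, p):
        with pytest.raises(ValueError):
            gr.centile_curve_from_lms(toy_reference, p)

    def test_monotone_in_centile_at_fixed_age(self, toy_reference):
        ps = [1, 3, 10, 25, 50, 75, 90, 97, 99]
        values = np.array([gr.centile_curve_from_lms(toy_reference, p)["value"]
                           for p in ps])
        assert np.all(np.diff(values, axis=0) > 0)

    def test_reduced_reference_invariants(self, toy_reference):
        red = centile_curve_reference_from_lms(toy_reference)
        assert np.all(red.P3 < red.P50)
        p3, p50 = red.interpolate(1.5)
        assert p50 == pytest.approx(11.0)
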