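"""Data model, CSV round trips, protocol validation and the enrollment filter."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ifsigtt.cohort import (
    Cohort,
    ProtocolSpec,
    SubjectSeries,
    apply_enrollment_filter,
    convert_supplementary,
    read_cohort_csv,
    validate_protocol,
    write_cohort_csv,
)
from ifsigtt.errors import IntegrityError, ParseError, SchemaError, ValidationError

from .conftest import make_series


def _write(tmp_path, text, name="cohort.csv"):
    p = tmp_path / name
    p.write_text(text)
    return p


HEADER = "subject_id,group,age_hours,time_min,glucose_mg_dl,insulin_uIU_ml\n"


class TestProtocolSpec:
    def test_default_schedule_has_20_times_and_two_baselines(self, protocol):
        assert len(protocol.sample_times_min) == 20
        assert sum(t <= 0 for t in protocol.sample_times_min) == 2
        assert protocol.insulin_time_min > protocol.dextrose_time_min

    def test_non_increasing_times_rejected(self):
        with pytest.raises(ValidationError):
            ProtocolSpec(sample_times_min=(-60.0, 0.0, 5.0, 5.0, 10.0))

    def test_single_baseline_rejected(self):
        with pytest.raises(ValidationError):
            ProtocolSpec(sample_times_min=(0.0, 2.0, 5.0))


class TestSubjectSeries:
    def test_negative_glucose_rejected(self):
        with pytest.raises(ValidationError):
            make_series([0, 5], [100, -1], [8, 8])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            make_series([0, 5, 10], [100, 100], [8, 8, 8])

    def test_unknown_group_rejected(self):
        with pytest.raises(ValidationError):
            make_series([0, 5], [100, 100], [8, 8], group="pony")

    def test_missing_values_flagged_not_imputed(self):
        s = make_series([0, 5, 10], [100, np.nan, 90], [8, 8, 8])
        assert np.isnan(s.glucose[1])


class TestReadCohortCsv:
    def test_empty_file_is_schema_error(self, tmp_path):
        with pytest.raises(SchemaError):
            read_cohort_csv(_write(tmp_path, ""))

    def test_missing_column_is_schema_error(self, tmp_path):
        p = _write(tmp_path, "subject_id,group,time_min,glucose_mg_dl\na,foal,0,100\n")
        with pytest.raises(SchemaError):
            read_cohort_csv(p)

    def test_three_row_single_subject_fixture(self, tmp_path):
        p = _write(tmp_path, HEADER + "a,foal,30,0,166,8.3\na,foal,30,2,300,40\na,foal,30,5,280,30\n")
        cohort = read_cohort_csv(p)
        assert len(cohort) == 1
        s = cohort.subjects[0]
        assert s.times.tolist() == [0.0, 2.0, 5.0]
        assert s.glucose.tolist() == [166.0, 300.0, 280.0]
        assert s.age == 30.0

    def test_duplicate_time_is_integrity_error(self, tmp_path):
        p = _write(tmp_path, HEADER + "a,foal,,0,166,8\na,foal,,0,170,9\n")
        with pytest.raises(IntegrityError):
            read_cohort_csv(p)

    def test_non_numeric_cell_names_row(self, tmp_path):
        p = _write(tmp_path, HEADER + "a,foal,,0,166,8\na,foal,,2,oops,9\n")
        with pytest.raises(ParseError, match="row 1"):
            read_cohort_csv(p)

    def test_rows_sorted_by_time_and_missing_cells_reported(self, tmp_path):
        p = _write(tmp_path, HEADER + "a,foal,,5,,30\na,foal,,0,166,8.3\n")
        cohort = read_cohort_csv(p)
        assert cohort.subjects[0].times.tolist() == [0.0, 5.0]
        assert cohort.parse_report.missing_cells == [("a", 5.0, "glucose_mg_dl")]


class TestRoundTrip:
    @given(st.lists(
        st.tuples(
            st.floats(min_value=20, max_value=500),
            st.floats(min_value=0, max_value=300),
        ),
        min_size=2, max_size=8,
    ))
    @settings(deadline=None, max_examples=30, derandomize=True)
    def test_write_read_identity_to_full_precision(self, rows):
        import tempfile
        times = np.arange(len(rows), dtype=float)
        g = np.array([r[0] for r in rows])
        i = np.array([r[1] for r in rows])
        cohort = Cohort(subjects=[make_series(times, g, i)])
        with tempfile.NamedTemporaryFile(suffix=".csv", mode="w", delete=False) as fh:
            path = fh.name
        write_cohort_csv(cohort, path)
        back = read_cohort_csv(path)
        s = back.subjects[0]
        np.testing.assert_array_equal(s.glucose, g)
        np.testing.assert_array_equal(s.insulin, i)
        np.testing.assert_array_equal(s.times, times)


class TestEnrollmentFilter:
    def _cohort(self, insulins):
        subs = [make_series([-60, 0, 5], [100, 100, 200], [i, i, i],
                            subject_id=f"s{k}") for k, i in enumerate(insulins)]
        return Cohort(subjects=subs)

    def test_above_cutoff_excluded(self):
        kept, excluded = apply_enrollment_filter(self._cohort([25.0]))
        assert excluded == ["s0"] and len(kept) == 0

    def test_exactly_at_cutoff_retained(self):
        kept, excluded = apply_enrollment_filter(self._cohort([20.0]))
        assert excluded == [] and len(kept) == 1

    def test_enumerated_cohort_splits_three_two(self):
        kept, excluded = apply_enrollment_filter(self._cohort([4, 8, 20, 21, 30]))
        assert len(kept) == 3
        assert excluded == ["s3", "s4"]

    def test_missing_time0_insulin_is_validation_error(self):
        subs = [make_series([-60, 0], [100, 100], [8, np.nan])]
        with pytest.raises(ValidationError):
            apply_enrollment_filter(Cohort(subjects=subs))

    def test_filter_is_idempotent(self):
        cohort = self._cohort([4, 8, 20, 21, 30])
        once, _ = apply_enrollment_filter(cohort)
        twice, excluded2 = apply_enrollment_filter(once)
        assert excluded2 == []
        assert [s.subject_id for s in twice.subjects] == [s.subject_id for s in once.subjects]


class TestValidateProtocol:
    def _full_series(self, protocol, drop=None, extra=None):
        times = [t for t in protocol.sample_times_min if t != drop]
        if extra is not None:
            times = sorted(times + [extra])
        n = len(times)
        return make_series(times, [100.0] * n, [8.0] * n)

    def test_complete_series_has_no_issues(self, protocol):
        assert validate_protocol(self._full_series(protocol), protocol) == []

    def test_missing_scheduled_time_reported(self, protocol):
        issues = validate_protocol(self._full_series(protocol, drop=150.0), protocol)
        assert [(i.kind, i.time_min) for i in issues] == [("missing_time", 150.0)]

    def test_unscheduled_time_reported(self, protocol):
        issues = validate_protocol(self._full_series(protocol, extra=45.0), protocol)
        assert [(i.kind, i.time_min) for i in issues] == [("unscheduled_time", 45.0)]

    def test_missing_measurement_reported(self, protocol):
        s = self._full_series(protocol)
        s.glucose[3] = np.nan
        issues = validate_protocol(s, protocol)
        assert [(i.kind, i.channel) for i in issues] == [("missing_measurement", "glucose")]


class TestConvertSupplementary:
    def test_wide_workbooks_round_trip(self, tmp_path):
        import pandas as pd
        times = [-60, 0, 2, 5]
        glu = pd.DataFrame(
            {"subject": ["f1", "h1"], **{t: [100.0 + t, 200.0 + t] for t in times}})
        ins = pd.DataFrame(
            {"subject": ["f1", "h1"], **{t: [8.0, 9.0] for t in times}})
        info = pd.DataFrame({"subject_id": ["f1", "h1"], "group": ["foal", "horse"],
                             "age_hours": [30.0, None]})
        paths = {}
        for name, df in (("s1", glu), ("s2", ins), ("s5", info)):
            paths[name] = tmp_path / f"{name}.xlsx"
            df.to_excel(paths[name], index=False)
        out = tmp_path / "cohort.csv"
        protocol = ProtocolSpec(sample_times_min=(-60.0, 0.0, 2.0, 5.0))
        cohort = convert_supplementary(paths["s1"], paths["s2"], paths["s5"], out, protocol)
        assert len(cohort) == 2
        f1 = cohort.subjects[0]
        assert f1.subject_id == "f1" and f1.age == 30.0
        np.testing.assert_allclose(f1.glucose, [40.0, 100.0, 102.0, 105.0])
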