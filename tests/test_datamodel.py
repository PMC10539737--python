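"""Cohort tables, factor specs and complete-case dataset construction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cohortdbn import (
    CohortTable,
    FactorSpec,
    build_initial_dataset,
    build_transition_dataset,
    collapse_to_binary,
    load_factor_specs,
    validate_cohort,
)
from cohortdbn.datamodel import (
    EmptyDatasetError,
    SchemaError,
    save_factor_specs,
)

from conftest import BINARY, binary_spec, diagnosis_spec


def make_table(records, factors=("a", "b")):
    """records: list of (subject, t, {factor: value-or-None})"""
    rows = []
    for subj, t, vals in records:
        row = {"subject_id": subj, "timepoint": t}
        for f in factors:
            row[f] = vals.get(f)
        rows.append(row)
    return CohortTable(pd.DataFrame(rows), factors)


class TestFactorSpec:
    def test_rejects_bad_level_counts_and_truthy(self):
        with pytest.raises(SchemaError):
            FactorSpec("x", ("only",), "syndrome", ("only",))
        with pytest.raises(SchemaError):
            FactorSpec("x", ("a", "b", "c", "d"), "syndrome", ("a",))
        with pytest.raises(SchemaError):  # truthy must be strict subset
            FactorSpec("x", BINARY, "syndrome", BINARY)
        with pytest.raises(SchemaError):  # duplicate levels
            FactorSpec("x", ("a", "a"), "syndrome", ("a",))

    @pytest.mark.parametrize(
        "value,expected",
        [("full-threshold", True), ("subthreshold", True), ("none", False)],
    )
    def test_diagnosis_collapse(self, value, expected):
        # sub- and full-threshold both count as the condition being present
        assert collapse_to_binary(value, diagnosis_spec("dep")) is expected

    def test_collapse_rejects_unknown_level(self):
        with pytest.raises(SchemaError):
            collapse_to_binary("maybe", binary_spec("a"))


class TestValidation:
    def test_unknown_level_label_names_factor(self):
        table = make_table([("s1", 0, {"a": "maybe", "b": "true"})])
        with pytest.raises(SchemaError, match="'a'.*'maybe'"):
            validate_cohort(table, [binary_spec("a"), binary_spec("b")])

    def test_empty_table_reports_zero_subjects(self):
        table = CohortTable(
            pd.DataFrame(columns=["subject_id", "timepoint", "a"]), ("a",)
        )
        report = validate_cohort(table, [binary_spec("a")])
        assert report.n_subjects == 0 and report.n_records == 0

    def test_counts(self, tiny_cohort):
        table, specs = tiny_cohort
        report = validate_cohort(table, specs)
        assert (report.n_subjects, report.n_records, report.n_missing) == (3, 6, 0)

    def test_duplicate_record_rejected(self):
        table = make_table(
            [("s1", 0, {"a": "true", "b": "true"}), ("s1", 0, {"a": "false", "b": "true"})]
        )
        with pytest.raises(SchemaError, match="duplicate"):
            validate_cohort(table, [binary_spec("a"), binary_spec("b")])


class TestInitialDataset:
    specs = [binary_spec("a"), binary_spec("b")]

    def test_only_t0_completeness_matters(self):
        table = make_table(
            [
                ("s1", 0, {"a": "true", "b": "true"}),
                ("s1", 1, {"a": None, "b": "true"}),
            ]
        )
        ds = build_initial_dataset(table, self.specs)
        assert len(ds) == 1

    def test_incomplete_t0_excluded(self):
        table = make_table(
            [
                ("s1", 0, {"a": "true", "b": None}),
                ("s2", 0, {"a": "true", "b": "false"}),
            ]
        )
        ds = build_initial_dataset(table, self.specs)
        assert ds.rows["subject_id"].tolist() == ["s2"]

    def test_count_on_mixed_fixture(self):
        # 10 subjects, exactly 4 with complete t=0 records
        records = []
        for i in range(10):
            vals = {"a": "true", "b": "true"} if i < 4 else {"a": None, "b": "true"}
            records.append((f"s{i}", 0, vals))
        assert len(build_initial_dataset(make_table(records), self.specs)) == 4

    def test_zero_rows_raises(self):
        table = make_table([("s1", 0, {"a": None, "b": "true"})])
        with pytest.raises(EmptyDatasetError, match="factor subset"):
            build_initial_dataset(table, self.specs)


class TestTransitionDataset:
    specs = [binary_spec("a"), binary_spec("b")]

    def complete(self, subj, t):
        return (subj, t, {"a": "true", "b": "false"})

    def test_three_complete_timepoints_give_two_pairs(self):
        table = make_table([self.complete("s1", t) for t in (0, 1, 2)])
        ds = build_transition_dataset(table, self.specs)
        assert len(ds) == 2
        assert ds.rows["timepoint"].tolist() == [0, 1]

    def test_gap_breaks_pairing(self):
        # complete at 0 and 2 only: not consecutive, contributes nothing
        table = make_table(
            [self.complete("s1", 0), self.complete("s1", 2), self.complete("s2", 0), self.complete("s2", 1)]
        )
        ds = build_transition_dataset(table, self.specs)
        assert ds.rows["subject_id"].tolist() == ["s2"]

    def test_pairs_resume_after_missed_visit(self):
        table = make_table(
            [self.complete("s1", 0), self.complete("s1", 2), self.complete("s1", 3)]
        )
        ds = build_transition_dataset(table, self.specs)
        assert len(ds) == 1 and ds.rows["timepoint"].tolist() == [2]

    def test_zero_pairs_raises(self):
        table = make_table([self.complete("s1", 0)])
        with pytest.raises(EmptyDatasetError):
            build_transition_dataset(table, self.specs)

    @settings(max_examples=40, deadline=None)
    @given(st.data())
    def test_row_count_matches_brute_force_scan(self, data):
        """Transition rows = complete consecutive pairs found by direct scan."""
        n_subjects = data.draw(st.integers(1, 5))
        records, expected = [], 0
        for i in range(n_subjects):
            tps = data.draw(
                st.lists(st.integers(0, 6), unique=True, min_size=1, max_size=5)
            )
            complete_tps = set()
            for t in tps:
                is_complete = data.draw(st.booleans())
                vals = (
                    {"a": "true", "b": "false"}
                    if is_complete
                    else {"a": None, "b": "false"}
                )
                records.append((f"s{i}", t, vals))
                if is_complete:
                    complete_tps.add(t)
            expected += sum(1 for t in complete_tps if t + 1 in complete_tps)
        table = make_table(records)
        if expected == 0:
            with pytest.raises(EmptyDatasetError):
                build_transition_dataset(table, self.specs)
        else:
            ds = build_transition_dataset(table, self.specs)
            assert len(ds) == expected
            assert not ds.rows.isna().any().any()

    def test_subject_relabelling_leaves_rows_unchanged(self):
        records = [self.complete("s1", t) for t in (0, 1)] + [
            self.complete("s2", t) for t in (1, 2)
        ]
        ds1 = build_transition_dataset(make_table(records), self.specs)
        relabelled = [(("zz" if s == "s1" else "aa"), t, v) for s, t, v in records]
        ds2 = build_transition_dataset(make_table(relabelled), self.specs)
        cols = [c for c in ds1.rows.columns if c != "subject_id"]
        left = ds1.rows[cols].sort_values(cols).reset_index(drop=True)
        right = ds2.rows[cols].sort_values(cols).reset_index(drop=True)
        pd.testing.assert_frame_equal(left, right)


class TestIO:
    def test_csv_round_trip_with_binarization(self, tmp_path):
        specs = [
            FactorSpec(
                "sofas_good",
                BINARY,
                "function",
                ("true",),
                binarize={"source_column": "sofas", "threshold": 70, "direction": "greater"},
            ),
            binary_spec("b"),
        ]
        csv = tmp_path / "cohort.csv"
        csv.write_text(
            "subject_id,timepoint,sofas,b\n"
            "s1,0,85,true\n"
            "s2,0,70,false\n"  # not strictly greater: poor functioning
            "s3,0,,true\n"
        )
        table = CohortTable.from_csv(csv, specs)
        col = table.data.set_index("subject_id")["sofas_good"]
        assert col["s1"] == "true" and col["s2"] == "false" and col["s3"] is None

    def test_spec_yaml_round_trip(self, tmp_path):
        specs = [diagnosis_spec("depression"), binary_spec("b", "function")]
        path = tmp_path / "specs.yaml"
        save_factor_specs(specs, path)
        loaded = load_factor_specs(path)
        assert loaded == specs

    def test_negative_timepoint_rejected(self):
        with pytest.raises(SchemaError):
            make_table([("s1", -1, {"a": "true", "b": "true"})])
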