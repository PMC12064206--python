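"""Diary ingestion, filtering, SWB grouping and incidence construction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_diary_frame
from leisurenet import (
    apply_inclusion_filters, assign_swb_group, build_incidence, classify_swb,
    default_config, generate_diaries, read_diary, write_diary,
)
from leisurenet.diary_io import EXCLUDED, HIGH, LOW, SchemaError


class TestReadDiary:
    def test_canonical_rows_parse(self, toy_diaries, tmp_path):
        path = tmp_path / "d.csv"
        write_diary(toy_diaries, path)
        records, rejects = read_diary(path)
        assert len(records) == 3 and len(rejects) == 0
        assert records["minutes"].tolist() == [400, 60, 380]

    def test_non_numeric_minutes_lands_in_rejects(self, toy_diaries, tmp_path):
        bad = toy_diaries.copy()
        bad.loc[1, "minutes"] = "abc"
        path = tmp_path / "d.csv"
        bad.to_csv(path, index=False)
        records, rejects = read_diary(path)
        assert len(records) == 2
        assert rejects["reject_reason"].tolist() == ["non-numeric minutes"]

    def test_missing_column_names_it(self, toy_diaries, tmp_path):
        path = tmp_path / "d.csv"
        toy_diaries.drop(columns=["day_type"]).to_csv(path, index=False)
        with pytest.raises(SchemaError, match="day_type"):
            read_diary(path)

    def test_synthetic_output_round_trips(self, default_diaries, tmp_path):
        path = tmp_path / "synth.csv"
        write_diary(default_diaries, path)
        records, rejects = read_diary(path)
        assert len(rejects) == 0
        recovered = records.astype(default_diaries.dtypes.to_dict())
        pd.testing.assert_frame_equal(recovered, default_diaries)


class TestSwbGrouping:
    @pytest.mark.parametrize("swb,health,expected", [
        (1, 1, HIGH), (4, 2, HIGH),          # joint high-SWB stratum
        (7, 5, LOW), (5, 3, LOW),            # joint low-SWB stratum
        (2, 4, EXCLUDED), (6, 1, EXCLUDED),  # crossed combinations drop out
        (4, 3, EXCLUDED), (5, 2, EXCLUDED),
        (None, 1, EXCLUDED), (3, None, EXCLUDED),
    ])
    def test_joint_score_rules(self, swb, health, expected):
        assert classify_swb(swb, health) == expected

    @given(swb=st.integers(1, 7), health=st.integers(1, 5))
    @settings(max_examples=35, deadline=None)
    def test_partition_is_total_and_consistent(self, swb, health):
        """Every score combination maps to exactly one group, and the
        vectorised path agrees with the scalar rule."""
        label = classify_swb(swb, health)
        assert label in (HIGH, LOW, EXCLUDED)
        frame = make_diary_frame([{"swb_score": swb, "health_score": health}])
        assert assign_swb_group(frame).iloc[0] == label


class TestInclusionFilters:
    def test_age_rule(self):
        df = make_diary_frame([
            {"person_id": f"P{i}", "age": age}
            for i, age in enumerate([9, 10, 19, 20])
        ])
        kept, report = apply_inclusion_filters(df)
        assert report.removed_age == 2
        assert kept["age"].tolist() == [10, 19]

    def test_duplicate_rows_keep_first(self):
        df = make_diary_frame([
            {"person_id": "A", "activity_code": "Sleeping", "minutes": 100},
            {"person_id": "A", "activity_code": "Sleeping", "minutes": 200},
            {"person_id": "A", "activity_code": "Sleeping", "day_type": "weekend"},
        ])
        kept, report = apply_inclusion_filters(df)
        assert report.removed_duplicate == 1
        assert len(kept) == 2
        assert kept["minutes"].iloc[0] == 100  # first survives

    def test_missing_mandatory_fields(self):
        df = make_diary_frame([{}, {"swb_score": np.nan}, {"person_id": ""}])
        kept, report = apply_inclusion_filters(df)
        assert report.removed_missing == 2 and len(kept) == 1

    def test_clean_synthetic_set_reports_all_zeros(self, default_diaries):
        kept, report = apply_inclusion_filters(default_diaries)
        assert (report.removed_age, report.removed_duplicate,
                report.removed_missing) == (0, 0, 0)
        assert report.n_output == report.n_input == len(kept)

    def test_removal_counts_sum_to_difference(self, default_diaries):
        from leisurenet import inject_pathologies

        dirty = inject_pathologies(default_diaries, "duplicates", 0.05, seed=3)
        dirty = inject_pathologies(dirty, "out_of_age_range", 0.02, seed=4)
        kept, report = apply_inclusion_filters(dirty)
        assert report.n_removed == len(dirty) - len(kept)


class TestBuildIncidence:
    def test_toy_binary_column_sums(self, toy_diaries):
        df = toy_diaries.assign(swb_group=assign_swb_group(toy_diaries))
        inc = build_incidence(df, HIGH, "weekday")
        assert inc.persons == ["A", "B"]
        assert inc.activities == ["Sleeping", "Watching live TV"]
        np.testing.assert_array_equal(inc.binary.sum(axis=0), [2, 1])

    def test_minutes_summed_per_cell(self):
        df = make_diary_frame([
            {"person_id": "A", "activity_code": "PC games", "minutes": 30},
            {"person_id": "A", "activity_code": "PC games", "minutes": 30},
        ])
        inc = build_incidence(df, HIGH, "weekday")
        assert inc.weights[0, 0] == 60
        assert inc.binary[0, 0] == 1

    def test_binary_iff_positive_weight_invariant(self, default_diaries):
        inc = build_incidence(default_diaries, HIGH, "weekday")
        np.testing.assert_array_equal(inc.binary, (inc.weights > 0))
        assert (inc.weights.sum(axis=1) > 0).all()   # no all-zero person rows
        assert (inc.binary.sum(axis=0) >= 1).all()   # no empty activity columns

    def test_record_order_does_not_matter(self, default_diaries):
        shuffled = default_diaries.sample(frac=1.0, random_state=9)
        a = build_incidence(default_diaries, LOW, "weekend")
        b = build_incidence(shuffled, LOW, "weekend")
        assert a.persons == b.persons and a.activities == b.activities
        np.testing.assert_array_equal(a.weights, b.weights)

    def test_empty_selection_flagged(self, toy_diaries):
        inc = build_incidence(toy_diaries, LOW, "weekend")
        assert inc.empty and inc.shape == (0, 0)
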