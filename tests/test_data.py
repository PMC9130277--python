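"""Ingestion, twin identification, selection filters and derived tables."""

import numpy as np
import pandas as pd
import pytest

import twinfert as tf
from twinfert.data import DataError, FormatError, write_children


def _children(rows):
    base = {"population_id": "A", "maternal_id": "m1",
            "maternal_birth_year": 1760, "maternal_birth_month": 6,
            "followup_to_45": True}
    return pd.DataFrame([dict(base, **r) for r in rows])


class TestReadChildren:
    def test_identity_parse(self, toy_children, tmp_path):
        path = tmp_path / "c.csv"
        toy_children.to_csv(path, index=False)
        out = tf.read_children(path)
        assert len(out) == len(toy_children)
        assert out["month_known"].all()

    def test_missing_month_retained_and_flagged(self, toy_children):
        toy = toy_children.copy()
        toy.loc[0, "child_birth_month"] = np.nan
        out = tf.read_children(toy)
        assert len(out) == len(toy)
        assert (~out["month_known"]).sum() == 1

    def test_missing_mandatory_column(self, toy_children):
        with pytest.raises(FormatError, match="maternal_id"):
            tf.read_children(toy_children.drop(columns=["maternal_id"]))

    def test_unparseable_date_names_row(self, toy_children):
        toy = toy_children.astype({"child_birth_year": object})
        toy.loc[2, "child_birth_year"] = "May"
        with pytest.raises(DataError, match="child_birth_year"):
            tf.read_children(toy)

    def test_column_map(self, toy_children):
        renamed = toy_children.rename(columns={"maternal_id": "mother"})
        out = tf.read_children(renamed, column_map={"maternal_id": "mother"})
        assert set(out["maternal_id"]) == {"m1", "m2", "m3"}

    def test_round_trip_write_read(self, tmp_path):
        truth = tf.make_truth("paper_like")
        children, _ = tf.generate_dataset(truth, 40, seed=11)
        first = tf.read_children(children)
        path = tmp_path / "rt.csv"
        write_children(first, path)
        second = tf.read_children(path)
        pd.testing.assert_frame_equal(first, second)


class TestTwinIdentification:
    @pytest.mark.parametrize("day2,expected_events", [(4, 1), (5, 2)])
    def test_one_day_apart_merges_two_days_does_not(self, day2, expected_events):
        ch = _children([
            {"child_birth_year": 1800, "child_birth_month": 5, "child_birth_day": 3},
            {"child_birth_year": 1800, "child_birth_month": 5, "child_birth_day": day2},
        ])
        ev = tf.identify_twin_births(tf.read_children(ch))
        assert len(ev) == expected_events
        if expected_events == 1:
            assert ev["n_offspring"].iloc[0] == 2 and ev["twin"].iloc[0]

    def test_same_year_month_no_day_merges(self):
        ch = _children([
            {"child_birth_year": 1800, "child_birth_month": 5},
            {"child_birth_year": 1800, "child_birth_month": 5},
        ])
        ev = tf.identify_twin_births(tf.read_children(ch))
        assert len(ev) == 1 and ev["n_offspring"].iloc[0] == 2

    def test_year_boundary_adjacent_days_merge(self):
        ch = _children([
            {"child_birth_year": 1800, "child_birth_month": 12, "child_birth_day": 31},
            {"child_birth_year": 1801, "child_birth_month": 1, "child_birth_day": 1},
        ])
        ev = tf.identify_twin_births(tf.read_children(ch))
        assert len(ev) == 1

    def test_triplets_allowed_quadruplets_rejected(self):
        rows = [{"child_birth_year": 1800, "child_birth_month": 5,
                 "child_birth_day": 3}] * 3
        ev = tf.identify_twin_births(tf.read_children(_children(rows)))
        assert len(ev) == 1 and ev["n_offspring"].iloc[0] == 3
        with pytest.raises(DataError, match="more than 3"):
            tf.identify_twin_births(tf.read_children(_children(rows * 2)))

    def test_order_invariance(self):
        truth = tf.make_truth("paper_like")
        children, _ = tf.generate_dataset(truth, 60, seed=12)
        ev1 = tf.identify_twin_births(tf.read_children(children))
        shuffled = children.sample(frac=1, random_state=0)
        ev2 = tf.identify_twin_births(tf.read_children(shuffled))
        pd.testing.assert_frame_equal(ev1.reset_index(drop=True),
                                      ev2.reset_index(drop=True))


class TestSelectionFilters:
    def _events(self, children):
        return tf.identify_twin_births(tf.read_children(children))

    def test_eight_month_gap_excludes_family(self):
        ch = _children([
            {"child_birth_year": 1800, "child_birth_month": 1, "child_birth_day": 1},
            {"child_birth_year": 1800, "child_birth_month": 9, "child_birth_day": 1},
        ])
        kept, log = tf.apply_selection_filters(self._events(ch))
        assert len(kept) == 0
        assert log["reason"].iloc[0] == "interbirth_gap_below_9_months"

    def test_nine_month_gap_retained(self):
        ch = _children([
            {"child_birth_year": 1800, "child_birth_month": 1, "child_birth_day": 1},
            {"child_birth_year": 1800, "child_birth_month": 10, "child_birth_day": 1},
        ])
        kept, log = tf.apply_selection_filters(self._events(ch))
        assert len(kept) == 2 and len(log) == 0

    def test_not_traced_to_45_excluded(self):
        ch = _children([{"child_birth_year": 1800, "child_birth_month": 5,
                         "followup_to_45": False}])
        kept, log = tf.apply_selection_filters(self._events(ch))
        assert len(kept) == 0 and log["reason"].iloc[0] == "not_traced_to_45"

    def test_missing_child_month_excluded(self):
        ch = _children([{"child_birth_year": 1800},
                        {"child_birth_year": 1803, "child_birth_month": 2}])
        kept, log = tf.apply_selection_filters(self._events(ch))
        assert len(kept) == 0
        assert log["reason"].iloc[0] == "child_birth_month_unknown"

    def test_filtering_idempotent(self):
        truth = tf.make_truth("paper_like")
        children, _ = tf.generate_dataset(truth, 60, seed=13)
        corrupted, _ = tf.inject_defects(children, {"month_missing": 0.2}, seed=1)
        ev = self._events(corrupted)
        kept1, _ = tf.apply_selection_filters(ev)
        kept2, log2 = tf.apply_selection_filters(kept1)
        assert len(log2) == 0
        pd.testing.assert_frame_equal(kept1, kept2)


class TestDerivedTables:
    def test_invariants_on_synthetic_data(self):
        truth = tf.make_truth("paper_like")
        children, gt = tf.generate_dataset(truth, 120, seed=14)
        ds = tf.load_and_prepare(children)
        assert ds.check_invariants()
        # conservation: children count equals total offspring
        assert ds.births["n_offspring"].sum() == len(children)
        # one terminal birth per mother
        assert ds.births["IBI_months"].notna().sum() == \
            len(ds.births) - len(ds.mothers)
        assert (ds.births.groupby("maternal_id")["PP"].min() == 0).all()

    def test_parity_has_no_gaps(self):
        truth = tf.make_truth("paper_like")
        children, _ = tf.generate_dataset(truth, 50, seed=15)
        ds = tf.load_and_prepare(children)
        for _, g in ds.births.groupby("maternal_id"):
            assert sorted(g["parity"]) == list(range(1, len(g) + 1))


class TestPopulationSummary:
    def test_toy_rates(self):
        ch = _children([
            {"child_birth_year": 1800, "child_birth_month": 1, "child_birth_day": 1},
            {"child_birth_year": 1800, "child_birth_month": 1, "child_birth_day": 1},
            {"child_birth_year": 1802, "child_birth_month": 1, "child_birth_day": 1},
        ])
        ds = tf.load_and_prepare(ch)
        summ = tf.summarize_populations(ds)
        pooled = summ[summ["population_id"] == "all"].iloc[0]
        assert pooled["twinning_rate_permille"] == 500.0
        assert pooled["twinner_rate_permille"] == 1000.0
        assert pooled["n_births"] == 2 and pooled["n_mothers"] == 1

    def test_rates_match_counts(self, dataset):
        summ = tf.summarize_populations(dataset)
        pooled = summ[summ["population_id"] == "all"].iloc[0]
        assert pooled["twinning_rate_permille"] == pytest.approx(
            1000 * pooled["n_twin_births"] / pooled["n_births"], abs=0.005)
        assert pooled["n_mothers"] == len(dataset.mothers)
        # one row per population plus the pooled row
        assert len(summ) == dataset.mothers["population_id"].nunique() + 1
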