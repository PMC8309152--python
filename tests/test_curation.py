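"""Unit conversion, replicate aggregation and curation accounting."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from solqspr.curation import (ConversionError, ValidationError,
                              aggregate_replicates, curate,
                              drop_incomplete_descriptors, records_to_log_molar,
                              remove_test_overlap, replicate_summary,
                              to_log_molar)
from solqspr.synth import TABLE_REPLICATE_HISTOGRAM


def _log_records(values_per_compound):
    rows = [{"compound_id": cid, "log_s0": v}
            for cid, vals in values_per_compound.items() for v in vals]
    return pd.DataFrame(rows)


class TestToLogMolar:
    @pytest.mark.parametrize("value,unit,mw,expected", [
        (1.0, "molar", None, 0.0),
        (2.0, "ug_per_mL", 200.0, -5.0),       # 2 ug/mL = 1e-5 M
        (-3.52, "log_molar", None, -3.52),      # identity pass-through
        (1.0, "mg_per_mL", 100.0, -2.0),        # 1 mg/mL = 1 g/L = 0.01 M
        (0.5, "g_per_L", 50.0, -2.0),
    ])
    def test_examples(self, value, unit, mw, expected):
        assert to_log_molar(value, unit, mw) == pytest.approx(expected, abs=1e-12)

    def test_missing_molecular_weight_names_record(self):
        with pytest.raises(ConversionError, match="RX-17"):
            to_log_molar(2.0, "ug_per_mL", None, record_id="RX-17")

    @pytest.mark.parametrize("value", [0.0, -1.0])
    def test_non_positive_value_rejected(self, value):
        with pytest.raises(ValidationError):
            to_log_molar(value, "molar")

    def test_unknown_unit_rejected(self):
        with pytest.raises(ValidationError, match="unknown unit"):
            to_log_molar(1.0, "parts_per_million")

    @given(value=st.floats(1e-6, 1e6), mw=st.floats(50.0, 1000.0))
    @settings(max_examples=100, deadline=None)
    def test_mass_conversion_round_trip(self, value, mw):
        """10^logS * MW * 1e3 recovers the ug/mL input to 1e-9 relative."""
        log_m = to_log_molar(value, "ug_per_mL", mw)
        back = 10.0 ** log_m * mw * 1e3
        assert back == pytest.approx(value, rel=1e-9)


class TestAggregateReplicates:
    @pytest.mark.parametrize("values,strategy,expected", [
        ([-3.0], "mean", -3.0),
        ([-2.0, -4.0], "mean", -3.0),
        ([-2.0, -4.0], "median", -3.0),
        ([-1.0, -2.0, -6.0], "mean", -3.0),
        ([-1.0, -2.0, -6.0], "median", -2.0),
    ])
    def test_examples(self, values, strategy, expected):
        out = aggregate_replicates(_log_records({"A": values}), strategy=strategy)
        assert out.loc[0, "logS0"] == pytest.approx(expected)
        assert out.loc[0, "n_replicates"] == len(values)

    def test_all_strategy_keeps_every_replicate(self):
        out = aggregate_replicates(_log_records({"A": [-2, -4], "B": [-1]}),
                                   strategy="all")
        assert len(out) == 3
        assert set(out["compound_id"]) == {"A", "B"}
        assert out.loc[out["compound_id"] == "A", "n_replicates"].tolist() == [2, 2]

    def test_manual_override(self):
        out = aggregate_replicates(_log_records({"A": [-2, -4], "B": [-1]}),
                                   strategy="manual", overrides={"A": -3.7})
        a = out.set_index("compound_id")
        assert a.loc["A", "logS0"] == -3.7
        assert a.loc["B", "logS0"] == -1.0

    def test_manual_unknown_compound_rejected(self):
        with pytest.raises(ValidationError):
            aggregate_replicates(_log_records({"A": [-2]}), strategy="manual",
                                 overrides={"Z": -1.0})

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            aggregate_replicates(_log_records({}))

    @given(st.lists(st.floats(-10, 2), min_size=1, max_size=7))
    @settings(max_examples=60, deadline=None)
    def test_mean_median_agree_on_symmetric_sets(self, vals):
        """Symmetrising any replicate set around its mean equalises mean/median."""
        c = float(np.mean(vals))
        sym = vals + [2 * c - v for v in vals]
        recs = _log_records({"A": sym})
        mean = aggregate_replicates(recs, "mean").loc[0, "logS0"]
        med = aggregate_replicates(recs, "median").loc[0, "logS0"]
        assert mean == pytest.approx(med, abs=1e-9)


class TestOverlapAndDescriptors:
    def test_overlap_removed_and_counted(self):
        train = pd.DataFrame({"compound_id": list("ABCDE")})
        out, removed = remove_test_overlap(train, {"B", "D", "Z"})
        assert list(out["compound_id"]) == ["A", "C", "E"]
        assert removed == ["B", "D"]

    def test_disjoint_unchanged_and_idempotent(self):
        train = pd.DataFrame({"compound_id": list("ABC")})
        once, removed = remove_test_overlap(train, {"X"})
        assert removed == []
        twice, _ = remove_test_overlap(once, {"X"})
        pd.testing.assert_frame_equal(once, twice)

    def test_training_subset_of_test_warns_empty(self):
        train = pd.DataFrame({"compound_id": ["A", "B"]})
        with pytest.warns(UserWarning, match="empty training set"):
            out, removed = remove_test_overlap(train, {"A", "B"})
        assert out.empty and removed == ["A", "B"]

    def test_one_missing_descriptor_removes_molecule(self):
        df = pd.DataFrame({"compound_id": ["A", "B"], "logS0": [-1, -2],
                           "d1": [1.0, 2.0], "d2": [np.nan, 3.0]})
        out, removed = drop_incomplete_descriptors(df)
        assert removed == ["A"] and list(out["compound_id"]) == ["B"]

    def test_all_removed_is_error(self):
        df = pd.DataFrame({"compound_id": ["A"], "logS0": [-1], "d1": [np.nan]})
        with pytest.raises(ValidationError):
            drop_incomplete_descriptors(df)


class TestReplicateSummary:
    def test_study_histogram_accounting(self):
        """The replicate histogram implies 270 molecules and 412 values."""
        rows = []
        i = 0
        for count, n_mol in TABLE_REPLICATE_HISTOGRAM.items():
            for _ in range(n_mol):
                rows.append({f"M{i}": [-3.0 + 0.1 * j for j in range(count)]})
                i += 1
        recs = _log_records({k: v for d in rows for k, v in d.items()})
        s = replicate_summary(recs)
        assert s.histogram == TABLE_REPLICATE_HISTOGRAM
        assert s.n_molecules == 270
        assert s.n_values == 412

    def test_all_singletons_no_interlab_sd(self):
        s = replicate_summary(_log_records({"A": [-1], "B": [-2]}))
        assert s.mean_interlab_sd is None
        assert s.histogram == {1: 2}

    def test_two_point_sd(self):
        """Sample SD of {-2, -4} is |delta|/sqrt(2) = 1.414."""
        s = replicate_summary(_log_records({"A": [-2.0, -4.0]}))
        assert s.mean_interlab_sd == pytest.approx(2 / math.sqrt(2), abs=1e-9)

    @given(st.dictionaries(st.integers(1, 6), st.integers(1, 20),
                           min_size=1, max_size=5))
    @settings(max_examples=40, deadline=None)
    def test_histogram_totals_identity(self, hist):
        """sum(count x molecules) always equals the number of input values."""
        values = {}
        i = 0
        for count, n_mol in hist.items():
            for _ in range(n_mol):
                values[f"M{i}"] = list(np.linspace(-5, -4, count))
                i += 1
        s = replicate_summary(_log_records(values))
        assert s.n_values == sum(c * m for c, m in hist.items())
        assert s.n_molecules == sum(hist.values())
        assert sum(c * m for c, m in s.histogram.items()) == s.n_values


class TestRecordValidation:
    def test_identical_duplicates_rejected(self):
        recs = pd.DataFrame({
            "compound_id": ["A", "A"], "cas": ["50-00-0"] * 2,
            "source_id": ["src1", "src1"], "value": [-3.0, -3.0],
            "unit": ["log_molar"] * 2, "mw": [np.nan] * 2, "polymorph": ["", ""]})
        with pytest.raises(ValidationError, match="duplicate"):
            records_to_log_molar(recs)

    def test_polymorphs_are_replicates(self):
        recs = pd.DataFrame({
            "compound_id": ["A", "A"], "cas": ["x"] * 2, "source_id": ["s1", "s1"],
            "value": [-3.0, -3.4], "unit": ["log_molar"] * 2,
            "mw": [np.nan] * 2, "polymorph": ["form-I", "form-II"]})
        agg = aggregate_replicates(records_to_log_molar(recs))
        assert agg.loc[0, "n_replicates"] == 2
        assert agg.loc[0, "logS0"] == pytest.approx(-3.2)


def test_curate_end_to_end_counts(study):
    """Full chain on the default synthetic study: 270 molecules, 412 values."""
    ds = curate(study.records, study.descriptors, strategy="mean")
    assert ds.summary.n_molecules == 270
    assert ds.summary.n_values == 412
    assert len(ds.table) == 270
    assert not ds.X.isna().any().any()
    assert ds.log["n_input_records"] == 412
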