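import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ampliclean import (
    FeatureTable,
    NormalizationConfig,
    SampleMetadata,
    filter_singletons,
    read_feature_table,
    subsample_to_depth,
)
from ampliclean.errors import (
    FormatError,
    IdentifierError,
    MetadataError,
    ValidationError,
)


class TestReadWrite:
    def test_round_trip_preserves_counts_and_ids(self, small_table, tmp_path):
        path = tmp_path / "table.tsv"
        small_table.to_tsv(path)
        back = read_feature_table(path)
        assert back == small_table

    def test_samples_as_rows_orientation(self, small_table, tmp_path):
        path = tmp_path / "t.tsv"
        small_table.df.T.rename_axis("sample_id").to_csv(path, sep="\t")
        assert read_feature_table(path, "samples_as_rows") == small_table

    @pytest.mark.parametrize("body,err", [
        ("feature\ts1\ts2\nf1\t2.5\t1\nf2\t1\t1\n", ValidationError),
        ("feature\ts1\ts2\nf1\t-1\t1\nf2\t1\t1\n", ValidationError),
        ("feature\ts1\ts2\nf1\t1\t0\nf1\t2\t1\n", IdentifierError),
        ("feature\ts1\ts2\nf1\tx\t1\nf2\t1\t1\n", ValidationError),
        ("feature\n", FormatError),
    ])
    def test_invalid_tables_rejected(self, tmp_path, body, err):
        path = tmp_path / "bad.tsv"
        path.write_text(body)
        with pytest.raises(err):
            read_feature_table(path)

    def test_duplicate_sample_ids_rejected(self):
        df = pd.DataFrame([[1, 2], [3, 4]], index=["f1", "f2"], columns=["s", "s"])
        with pytest.raises(IdentifierError):
            FeatureTable(df)

    def test_all_zero_sample_dropped_by_default(self):
        df = pd.DataFrame({"s1": [2, 1], "s2": [0, 0]}, index=["f1", "f2"])
        assert FeatureTable(df).sample_ids == ["s1"]
        kept = FeatureTable(df, drop_empty_samples=False)
        assert kept.sample_ids == ["s1", "s2"]

    def test_biom_round_trip(self, small_table, tmp_path):
        biom = pytest.importorskip("biom")
        from ampliclean.table_ops import read_biom_table
        bt = biom.Table(small_table.df.to_numpy(),
                        small_table.feature_ids, small_table.sample_ids)
        path = tmp_path / "t.biom"
        path.write_text(bt.to_json("test"))
        assert read_biom_table(path) == small_table


class TestFilterSingletons:
    def test_total_count_one_removed_two_retained(self):
        df = pd.DataFrame({"s1": [1, 1, 0], "s2": [0, 1, 0], "s3": [0, 0, 4]},
                          index=["single", "doubleton", "other"])
        out = filter_singletons(FeatureTable(df))
        assert out.feature_ids == ["doubleton", "other"]
        pd.testing.assert_frame_equal(out.df, df.loc[["doubleton", "other"]])

    def test_identity_when_no_singletons(self, small_table):
        assert filter_singletons(small_table) == small_table

    def test_idempotent(self):
        df = pd.DataFrame({"s1": [1, 2], "s2": [0, 0]}, index=["a", "b"])
        once = filter_singletons(FeatureTable(df, drop_empty_samples=False))
        assert filter_singletons(once) == once

    def test_all_singletons_is_an_error(self):
        df = pd.DataFrame({"s1": [1, 0], "s2": [0, 1]}, index=["a", "b"])
        with pytest.raises(ValidationError):
            filter_singletons(FeatureTable(df))


class TestSubsample:
    def test_sample_at_depth_unchanged(self):
        df = pd.DataFrame({"s1": [3, 2]}, index=["a", "b"])
        out = subsample_to_depth(FeatureTable(df), NormalizationConfig(depth=5))
        pd.testing.assert_frame_equal(out.df, df)

    def test_single_nonzero_feature(self):
        df = pd.DataFrame({"s1": [10, 0]}, index=["a", "b"])
        out = subsample_to_depth(FeatureTable(df, drop_empty_samples=False),
                                 NormalizationConfig(depth=5))
        assert out.df["s1"].tolist() == [5, 0]

    def test_deterministic_given_seed(self, mosquito_like):
        table, _ = mosquito_like
        cfg = NormalizationConfig(depth=1000, seed=7)
        a = subsample_to_depth(table, cfg)
        b = subsample_to_depth(table, cfg)
        assert a == b

    def test_column_sums_and_cellwise_bound(self, mosquito_like):
        table, _ = mosquito_like
        out = subsample_to_depth(table, NormalizationConfig(depth=1000, seed=0))
        assert (out.sample_totals() == 1000).all()
        assert (out.df <= table.df[out.sample_ids]).all().all()

    def test_below_depth_dropped_or_kept(self):
        df = pd.DataFrame({"deep": [80, 20], "shallow": [3, 1]}, index=["a", "b"])
        cfg = NormalizationConfig(depth=50, seed=0)
        out = subsample_to_depth(FeatureTable(df), cfg)
        assert out.sample_ids == ["deep"]
        kept = subsample_to_depth(
            FeatureTable(df), NormalizationConfig(depth=50, seed=0,
                                                  drop_below_depth=False))
        assert kept.df["shallow"].tolist() == [3, 1]

    def test_all_samples_below_depth_is_an_error(self, small_table):
        with pytest.raises(ValidationError):
            subsample_to_depth(small_table, NormalizationConfig(depth=10**6))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 50), min_size=2, max_size=12).filter(
        lambda c: sum(c) >= 10), st.integers(0, 2**31 - 1))
    def test_rarefied_column_is_sub_multiset(self, counts, seed):
        df = pd.DataFrame({"s1": counts},
                          index=[f"f{i}" for i in range(len(counts))])
        out = subsample_to_depth(FeatureTable(df, drop_empty_samples=False),
                                 NormalizationConfig(depth=10, seed=seed))
        assert out.df["s1"].sum() == 10
        assert (out.df["s1"] <= df["s1"]).all()


class TestSampleMetadata:
    def test_required_columns_and_roles(self):
        with pytest.raises(MetadataError):
            SampleMetadata(pd.DataFrame({"role": ["control"]}, index=["s1"]))
        with pytest.raises(MetadataError):
            SampleMetadata(pd.DataFrame(
                {"role": ["blank"], "dataset": ["d"], "tissue": ["gut"]},
                index=["s1"]))

    def test_validate_against_catches_missing_rows_and_roles(self, small_table):
        meta = SampleMetadata(pd.DataFrame(
            {"role": ["control"], "dataset": ["d"], "tissue": ["gut"]},
            index=["s1"]))
        with pytest.raises(MetadataError, match="without metadata"):
            meta.validate_against(small_table)
        meta2 = SampleMetadata(pd.DataFrame(
            {"role": ["control", "control"], "dataset": "d", "tissue": "gut"},
            index=["s1", "s2"]))
        with pytest.raises(MetadataError, match="lacks a"):
            meta2.validate_against(small_table)

    def test_tsv_round_trip_and_selectors(self, tmp_path, mosquito_like):
        _, meta = mosquito_like
        path = tmp_path / "meta.tsv"
        meta.to_tsv(path)
        back = SampleMetadata.from_tsv(path)
        assert back.controls("ds1") == meta.controls("ds1")
        assert back.experimental("ds1", tissue="gut") == meta.experimental("ds1")
        assert back.datasets == ["ds1"]
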