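import numpy as np
import pandas as pd
import pytest

from ampliclean import (
    AbundanceProfile,
    FeatureTable,
    SampleMetadata,
    TreatmentSpec,
    classify_threshold,
    pooled_relative_abundance,
    printed_abundance_blocks,
    screening_report,
    shared_contaminant_summary,
)
from ampliclean.errors import UndefinedProfileError
from ampliclean.screening import round_half_up

from conftest import random_count_table


class TestPooledRelativeAbundance:
    def test_single_sample_fractions(self):
        table = FeatureTable(pd.DataFrame({"s1": [40, 60]}, index=["A", "B"]))
        prof = pooled_relative_abundance(table, ["s1"])
        assert prof.abundances["A"] == pytest.approx(0.40)
        assert prof.abundances["B"] == pytest.approx(0.60)

    def test_pooling_sums_counts_not_proportions(self):
        table = FeatureTable(pd.DataFrame(
            {"s1": [10, 90], "s2": [30, 70]}, index=["A", "B"]))
        prof = pooled_relative_abundance(table, ["s1", "s2"])
        assert prof.abundances["A"] == pytest.approx(40 / 200)
        assert prof.total_counts == 200

    def test_absent_feature_has_zero_abundance_and_profile_sums_to_one(self):
        table = FeatureTable(pd.DataFrame(
            {"s1": [5, 0], "s2": [0, 3]}, index=["A", "B"]))
        prof = pooled_relative_abundance(table, ["s1"])
        assert prof.abundances["B"] == 0
        assert prof.abundances.sum() == pytest.approx(1.0, abs=1e-9)

    def test_all_zero_subset_is_undefined(self):
        table = FeatureTable(pd.DataFrame(
            {"s1": [5, 1], "s2": [0, 0]}, index=["A", "B"]),
            drop_empty_samples=False)
        with pytest.raises(UndefinedProfileError):
            pooled_relative_abundance(table, ["s2"])

    def test_empty_subset_rejected(self, small_table):
        with pytest.raises(ValueError):
            pooled_relative_abundance(small_table, [])


class TestClassifyThreshold:
    @pytest.fixture
    def aedes_control(self):
        return printed_abundance_blocks()["Aedes"]["control"]

    @pytest.mark.parametrize("tau,n_expected", [(1, 4), (5, 3), (10, 2), (200, 0)])
    def test_candidate_counts_on_worked_example(self, aedes_control, tau, n_expected):
        assert len(classify_threshold(aedes_control, tau)) == n_expected

    def test_comparison_is_inclusive(self):
        prof = AbundanceProfile.from_percentages({"A": 5.0, "B": 4.999})
        assert classify_threshold(prof, 5) == {"A"}

    def test_tau_must_be_positive(self, aedes_control):
        with pytest.raises(ValueError):
            classify_threshold(aedes_control, 0)

    def test_nestedness_over_random_tables(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            table = FeatureTable(random_count_table(rng),
                                 drop_empty_samples=False)
            prof = pooled_relative_abundance(table, table.sample_ids[:3])
            c10 = classify_threshold(prof, 10)
            c5 = classify_threshold(prof, 5)
            c1 = classify_threshold(prof, 1)
            assert c10 <= c5 <= c1 <= prof.features_detected()


class TestSharedSummary:
    def test_worked_example_aedes_gut(self):
        blocks = printed_abundance_blocks()["Aedes"]
        cand = classify_threshold(blocks["control"], 1)
        summ = shared_contaminant_summary(cand, blocks["tissues"]["gut"])
        assert (summ.n_candidates, summ.n_shared) == (4, 3)
        assert summ.pct_tissue_rounded == 49.10

    def test_candidates_absent_from_tissue(self):
        blocks = printed_abundance_blocks()["Aegypti"]
        cand = classify_threshold(blocks["control"], 1)
        summ = shared_contaminant_summary(cand, blocks["tissues"]["gut"])
        assert (summ.n_candidates, summ.n_shared, summ.pct_tissue) == (16, 0, 0)

    def test_empty_candidate_set(self):
        prof = AbundanceProfile.from_percentages({"A": 10.0})
        summ = shared_contaminant_summary(set(), prof)
        assert (summ.n_candidates, summ.n_shared, summ.pct_tissue) == (0, 0, 0)

    def test_pct_additive_over_disjoint_candidate_sets(self):
        blocks = printed_abundance_blocks()["Anopheles1"]
        tissue = blocks["tissues"]["gut"]
        all_cand = classify_threshold(blocks["control"], 1)
        high = classify_threshold(blocks["control"], 5)
        low = all_cand - high
        total = shared_contaminant_summary(all_cand, tissue).pct_tissue
        parts = (shared_contaminant_summary(high, tissue).pct_tissue
                 + shared_contaminant_summary(low, tissue).pct_tissue)
        assert total == pytest.approx(parts)
        assert total <= 100


class TestScreeningReport:
    def test_single_control_single_feature(self):
        table = FeatureTable(pd.DataFrame({"c": [7], "e": [3]}, index=["A"]))
        meta = SampleMetadata(pd.DataFrame(
            {"role": ["control", "experimental"], "dataset": "d",
             "tissue": ["na", "gut"]}, index=["c", "e"]))
        contaminants, shared = screening_report(table, meta)
        assert len(contaminants) == 1
        assert contaminants.iloc[0]["control_pct"] == 100.0
        full = shared[(shared.treatment == "full") & (shared.tissue == "gut")]
        assert full.iloc[0]["pct_tissue"] == 100.0

    def test_dataset_without_controls_skipped_with_warning(self, caplog):
        table = FeatureTable(pd.DataFrame({"e1": [5], "e2": [3]}, index=["A"]))
        meta = SampleMetadata(pd.DataFrame(
            {"role": "experimental", "dataset": "d", "tissue": "gut"},
            index=["e1", "e2"]))
        with caplog.at_level("WARNING"):
            contaminants, shared = screening_report(table, meta)
        assert contaminants.empty and shared.empty
        assert "no control samples" in caplog.text

    def test_counts_version_of_worked_example(self, aedes_counts):
        table, meta = aedes_counts
        _, shared = screening_report(table, meta, taus=(1, 5, 10))
        gut = shared[shared.tissue == "gut"].set_index("treatment")
        assert gut.loc["t1", ["n_candidates", "n_shared"]].tolist() == [4, 3]
        assert gut.loc["t1", "pct_tissue"] == pytest.approx(49.10, abs=0.005)
        assert gut.loc["t5", ["n_candidates", "n_shared"]].tolist() == [3, 3]
        assert gut.loc["t10", "pct_tissue"] == pytest.approx(38.94, abs=0.005)


class TestTreatmentSpec:
    @pytest.mark.parametrize("label,kind,tau", [
        ("none", "none", None), ("full", "full_removal", None),
        ("t1", "threshold", 1.0), ("t5", "threshold", 5.0),
        ("t2.5", "threshold", 2.5),
    ])
    def test_label_round_trip(self, label, kind, tau):
        spec = TreatmentSpec.from_label(label)
        assert (spec.kind, spec.tau) == (kind, tau)
        assert spec.label == label

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            TreatmentSpec("threshold")
        with pytest.raises(ValueError):
            TreatmentSpec("nope")
        with pytest.raises(ValueError):
            TreatmentSpec("none", tau=1.0)


def test_round_half_up_ties_away_from_zero():
    assert round_half_up(49.105, 2) == 49.11
    assert round_half_up(2.675, 2) == 2.68  # plain round() would give 2.67
    assert round_half_up(0.0, 2) == 0.0
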