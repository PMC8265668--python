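import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ampliclean import (
    GeneratorConfig,
    TreatmentSpec,
    alpha_diversity,
    apply_all_treatments,
    compare_treatments,
    generate,
    letter_groups,
    paired_compare,
)
from ampliclean.comparison import PairedTestResult, significance_band
from ampliclean.errors import InsufficientDataError
from ampliclean.table_ops import filter_singletons


class TestPairedCompare:
    def test_identical_vectors_degenerate(self):
        x = np.arange(10.0)
        res = paired_compare(x, x)
        assert res.test_used == "degenerate"
        assert res.p_value == 1.0
        assert not res.significant

    def test_normal_shift_uses_t_test_with_closed_form_p(self):
        rng = np.random.default_rng(12)
        y = rng.normal(10, 1, size=15)
        x = y + 0.8 + rng.normal(0, 0.3, size=15)
        res = paired_compare(x, y)
        assert res.test_used == "paired_t"
        d = x - y
        t = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        expected = 2 * stats.t.sf(abs(t), df=len(d) - 1)
        assert res.p_value == pytest.approx(expected, rel=1e-9)
        assert res.significant

    def test_heavy_tailed_differences_take_wilcoxon_branch(self):
        rng = np.random.default_rng(3)
        y = np.zeros(30)
        x = stats.cauchy.rvs(size=30, random_state=rng) * 10
        assert stats.shapiro(x - y).pvalue < 0.05  # premise of the fixture
        res = paired_compare(x, y)
        assert res.test_used == "wilcoxon_signed_rank"

    def test_constant_nonzero_shift_falls_back_to_sign_test(self):
        x = np.arange(10.0)
        res = paired_compare(x + 3.0, x)
        assert res.test_used == "wilcoxon_signed_rank"
        assert res.p_value == pytest.approx(2 * 0.5**10)

    def test_missing_pairs_dropped_and_minimum_enforced(self):
        x = np.array([1.0, np.nan, 2.0, 3.0])
        y = np.array([1.0, 5.0, np.nan, 3.0])
        with pytest.raises(InsufficientDataError):
            paired_compare(x, y)

    def test_pair_order_does_not_change_p_value(self):
        rng = np.random.default_rng(8)
        x = rng.normal(5, 1, 20)
        y = x + rng.normal(0.5, 0.5, 20)
        res1 = paired_compare(x, y)
        perm = rng.permutation(20)
        res2 = paired_compare(x[perm], y[perm])
        assert res1.p_value == pytest.approx(res2.p_value)
        assert res1.test_used == res2.test_used


class TestLetterGroups:
    @staticmethod
    def result(a, b, p):
        return PairedTestResult(a, b, 10, "paired_t", p)

    def test_non_different_treatments_share_a_letter(self):
        res = [self.result("none", "t1", 0.9)]
        letters = letter_groups(["none", "t1"], res).letters
        assert set(letters["none"]) & set(letters["t1"])

    def test_outlier_treatment_gets_unique_letter(self):
        res = [self.result("none", "t1", 0.8),
               self.result("none", "full", 0.001),
               self.result("t1", "full", 0.002)]
        letters = letter_groups(["none", "full", "t1"], res).letters
        assert letters["none"] == letters["t1"]
        assert not set(letters["full"]) & set(letters["none"])

    def test_share_letter_iff_not_significant(self):
        rng = np.random.default_rng(0)
        treatments = ["none", "full", "t1", "t5", "t10"]
        for _ in range(25):
            res = []
            for i in range(len(treatments)):
                for j in range(i + 1, len(treatments)):
                    res.append(self.result(treatments[i], treatments[j],
                                           float(rng.choice([0.001, 0.9]))))
            letters = letter_groups(treatments, res).letters
            for r in res:
                shares = bool(set(letters[r.treatment_a]) & set(letters[r.treatment_b]))
                assert shares == (not r.significant)


class TestCompareTreatments:
    def test_detects_threshold_dependent_contaminant(self):
        # pool members each sit between 1% and 10% control abundance, so the
        # tau=1 treatment strips them while tau=10 removes nothing
        cfg = GeneratorConfig(n_contam_features=40, dominant_share=0.0,
                              contam_alpha=5.0, bleed_mean=0.3,
                              depth_min=5000, depth_max=5000, seed=21)
        table, meta, truth = generate(cfg)
        table = filter_singletons(table)
        outcomes = apply_all_treatments(table, meta, [
            TreatmentSpec("none"),
            TreatmentSpec("threshold", tau=1.0),
            TreatmentSpec("threshold", tau=10.0),
        ])
        assert truth.contaminants_at(10.0) == set()  # premise
        values = {lbl: alpha_diversity(o.table_out)["richness_S"]
                  for lbl, o in outcomes.items()}
        results, letters = compare_treatments(values)
        assert letters.letters["none"] == letters.letters["t10"]
        assert not set(letters.letters["t1"]) & set(letters.letters["none"])

    def test_holm_adjustment_never_lowers_p(self):
        rng = np.random.default_rng(9)
        base = pd.Series(rng.normal(10, 1, 12), index=[f"s{i}" for i in range(12)])
        values = {"none": base,
                  "t1": base + rng.normal(0.2, 0.3, 12),
                  "full": base - rng.normal(1.0, 0.3, 12)}
        raw, _ = compare_treatments(values, holm=False)
        adj, _ = compare_treatments(values, holm=True)
        for r, a in zip(raw, adj):
            assert a.p_value >= r.p_value - 1e-12

    def test_requires_two_treatments_and_shared_keys(self):
        base = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        with pytest.raises(InsufficientDataError):
            compare_treatments({"none": base})
        other = pd.Series([1.0, 2.0], index=list("xy"))
        with pytest.raises(InsufficientDataError):
            compare_treatments({"none": base, "t1": other})


def test_significance_bands_match_reporting_convention():
    assert significance_band(0.03) == "*"
    assert significance_band(0.004) == "**"
    assert significance_band(1e-5) == "***"
    assert significance_band(0.2) == ""
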