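import numpy as np
import pandas as pd
import pytest

from ampliclean import FeatureTable, SampleMetadata


@pytest.fixture
def small_table() -> FeatureTable:
    counts = pd.DataFrame(
        {"s1": [3, 1, 0], "s2": [0, 2, 5]},
        index=["f1", "f2", "f3"],
    )
    return FeatureTable(counts)


@pytest.fixture
def mosquito_like() -> tuple[FeatureTable, SampleMetadata]:
    """One data set with a control-dominant contaminant block (c*) bleeding
    into tissue samples and a tissue-only resident block (r*)."""
    rng = np.random.default_rng(42)
    features = [f"c{i}" for i in range(5)] + [f"r{i}" for i in range(10)]
    pool = np.array([0.5, 0.25, 0.15, 0.07, 0.03])
    true = rng.dirichlet(np.ones(10))
    cols = {}
    roles = {}
    for i in range(2):
        comp = np.concatenate([pool * 0.98, true * 0.02])
        cols[f"ctrl{i}"] = rng.multinomial(5000, comp / comp.sum())
        roles[f"ctrl{i}"] = "control"
    for i in range(8):
        comp = np.concatenate([pool * 0.3, true * 0.7])
        cols[f"exp{i}"] = rng.multinomial(5000, comp / comp.sum())
        roles[f"exp{i}"] = "experimental"
    table = FeatureTable(pd.DataFrame(cols, index=features))
    meta = SampleMetadata(pd.DataFrame({
        "role": pd.Series(roles), "dataset": "ds1", "tissue": "gut"}))
    return table, meta


@pytest.fixture
def aedes_counts() -> tuple[FeatureTable, SampleMetadata]:
    """Integer counts whose pooled profiles realize the Aedes worked-example
    block exactly (percent x 100 reads; the remainder is spread over filler
    features that all stay below the 1% threshold)."""
    control = {"Enterobacter_1": 4006, "Enterobacter_2": 1964,
               "Serratia_1": 569, "Cutibacterium_1": 111}
    gut = {"Enterobacter_1": 2589, "Enterobacter_2": 1305,
           "Serratia_1": 1016, "Cutibacterium_1": 0}
    for i in range(67):  # 67 x 50 = 3350 control remainder, each 0.50%
        control[f"filler_{i:02d}"] = 50
        gut[f"filler_{i:02d}"] = 76 if i < 66 else 74  # 5090 gut remainder
    counts = pd.DataFrame({"ctrl": control, "gut1": gut}).fillna(0).astype(int)
    assert counts.sum().tolist() == [10_000, 10_000]
    table = FeatureTable(counts)
    meta = SampleMetadata(pd.DataFrame(
        {"role": ["control", "experimental"], "dataset": "Aedes",
         "tissue": ["na", "gut"]}, index=["ctrl", "gut1"]))
    return table, meta


def random_count_table(rng: np.random.Generator, n_features: int = 30,
                       n_samples: int = 8) -> pd.DataFrame:
    lam = rng.uniform(0, 20, size=(n_features, 1))
    counts = rng.poisson(lam, size=(n_features, n_samples))
    counts[rng.integers(0, n_features), :] += 1  # avoid all-zero tables
    return pd.DataFrame(
        counts,
        index=[f"f{i}" for i in range(n_features)],
        columns=[f"s{j}" for j in range(n_samples)],
    )
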