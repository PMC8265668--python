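#!/usr/bin/env python
"""Paired comparison of diversity between removal treatments.

Reads the per-treatment alpha/beta tables from results/diversity/ and tests
every treatment pair per metric (Shapiro-gated paired t / Wilcoxon
signed-rank), pairing samples (alpha) or unordered sample pairs (beta).
Writes comparisons.tsv and letters.tsv under results/comparison/.
"""

from pathlib import Path

import pandas as pd

from ampliclean import compare_treatments
from ampliclean.comparison import DEFAULT_TREATMENT_ORDER, comparison_table
from ampliclean.diversity import METRICS

divdir = Path("results/diversity")
outdir = Path("results/comparison")
outdir.mkdir(parents=True, exist_ok=True)

ALPHA_METRICS = ("richness_S", "shannon_H", "pielou_J")


def condensed(frame: pd.DataFrame) -> pd.Series:
    ids = list(frame.index)
    out = {}
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            a, b = sorted((ids[i], ids[j]))
            out[f"{a}|{b}"] = frame.loc[ids[i], ids[j]]
    return pd.Series(out)


tables = []
letters_rows = []
for metric in ALPHA_METRICS:
    values = {t: pd.read_csv(divdir / f"alpha_{t}.tsv", sep="\t", index_col=0)[metric]
              for t in DEFAULT_TREATMENT_ORDER}
    results, letters = compare_treatments(values)
    tables.append(comparison_table(results, metric=metric, dataset="sim"))
    letters_rows += [{"metric": metric, "treatment": t, "letters": l}
                     for t, l in letters.letters.items()]
for metric in METRICS:
    values = {t: condensed(pd.read_csv(divdir / f"beta_{metric}_{t}.tsv",
                                       sep="\t", index_col=0))
              for t in DEFAULT_TREATMENT_ORDER}
    results, letters = compare_treatments(values)
    tables.append(comparison_table(results, metric=metric, dataset="sim"))
    letters_rows += [{"metric": metric, "treatment": t, "letters": l}
                     for t, l in letters.letters.items()]

comparisons = pd.concat(tables, ignore_index=True)
comparisons.to_csv(outdir / "comparisons.tsv", sep="\t", index=False)
letters_df = pd.DataFrame(letters_rows)
letters_df.to_csv(outdir / "letters.tsv", sep="\t", index=False)

vs_none = comparisons[(comparisons.treatment_a == "none")]
print(vs_none.to_string(index=False))
print("\nLetter displays (shared letter = no significant difference):")
print(letters_df.pivot(index="treatment", columns="metric",
                       values="letters").to_string())
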