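#!/usr/bin/env python
"""Screen the simulated data set: abundance thresholds vs the prevalence test.

Reads results/sim/ (run 02_simulate.py first), classifies candidate
contaminants both ways, and scores each call set against the generator's
ground truth. Writes contaminants.tsv, shared_summary.tsv, prevalence.tsv and
recovery.tsv under results/screen/.
"""

from pathlib import Path

import pandas as pd

from ampliclean import (
    SampleMetadata,
    classify_prevalence,
    classify_threshold,
    pooled_relative_abundance,
    prevalence_results,
    read_feature_table,
    recovery_metrics,
    screening_report,
)
from ampliclean.prevalence import prevalence_table
from ampliclean.synthetic import SyntheticTruth
from ampliclean.table_ops import filter_singletons

simdir = Path("results/sim")
table = read_feature_table(simdir / "table.tsv")
metadata = SampleMetadata.from_tsv(simdir / "metadata.tsv")
truth_df = pd.read_csv(simdir / "truth.tsv", sep="\t", index_col=0)
truth = SyntheticTruth(labels=truth_df["label"].to_dict(),
                       pooled_control_abundance=truth_df["pooled_control_pct"] / 100)

table = filter_singletons(table)
outdir = Path("results/screen")
outdir.mkdir(parents=True, exist_ok=True)

contaminants, shared = screening_report(table, metadata)
contaminants.to_csv(outdir / "contaminants.tsv", sep="\t", index=False)
shared.to_csv(outdir / "shared_summary.tsv", sep="\t", index=False)

results = prevalence_results(table, metadata)
prevalence_table(results).to_csv(outdir / "prevalence.tsv", sep="\t")

ctrl_profile = pooled_relative_abundance(table, metadata.controls())
rows = []
call_sets = {f"threshold_t{tau:g}": classify_threshold(ctrl_profile, tau)
             for tau in (1, 5, 10)}
call_sets["full_removal"] = ctrl_profile.features_detected()
for p_star in (0.1, 0.5):
    call_sets[f"prevalence_p{p_star:g}"] = classify_prevalence(results, p_star)
for method, called in call_sets.items():
    called = {f for f in called if f in truth.labels}
    precision, recall = recovery_metrics(truth, called)
    rows.append({"method": method, "n_called": len(called),
                 "precision": round(precision, 4), "recall": round(recall, 4)})
recovery = pd.DataFrame(rows)
recovery.to_csv(outdir / "recovery.tsv", sep="\t", index=False)
print(recovery.to_string(index=False))
print("\nAt ~30% bleed-through the contaminants are detected in every tissue "
      "sample, so the prevalence test has little signal; abundance "
      "thresholding of the controls still isolates the pool (precision 1.0 "
      "when cross-contamination stays below the lowest threshold).")
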