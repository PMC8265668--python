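#!/usr/bin/env python
"""Reproduce the worked example: classify contaminants in the packaged
per-ASV abundance blocks and summarize their shared burden in tissues.

For each of the five mosquito data sets, ASVs at >=1/5/10% pooled control
abundance are classified as candidate contaminants and their summed relative
abundance in each tissue subset is reported. Writes
results/worked_example/shared_summary.tsv.
"""

from importlib import resources

from ampliclean.pipeline import RunConfig, run

blocks = resources.files("ampliclean").joinpath("data/printed_blocks.tsv")
with resources.as_file(blocks) as path:
    out = run(RunConfig.from_mapping({
        "abundance_blocks": str(path),
        "outdir": "results/worked_example",
    }))

shared = out["shared"]
print(shared.to_string(index=False))
burden = shared[shared.treatment == "t1"].groupby("dataset")["pct_tissue"].max()
print("\nLargest >=1% contaminant burden per data set (% of tissue reads):")
print(burden.to_string())
print("\nNote the Aegypti case: 16 control ASVs >=1%, none detected in gut "
      "tissue, so abundance-based removal costs no tissue reads there.")
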