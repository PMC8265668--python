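"""Worked-example abundance blocks.

Packaged per-ASV overall relative abundances (percent) in negative controls
and tissue subsets for five mosquito 16S data sets (Aedes, Aegypti,
Albopictus, Anopheles1, Anopheles2). Only ASVs at >= 1% control abundance are
listed, so the profiles are partial (``complete=False``); they exercise the
screening and shared-burden computations without any count data.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .screening import AbundanceProfile

_TISSUE_COLUMNS = ("gut", "urt", "lrt")


def printed_blocks_frame() -> pd.DataFrame:
    """Raw fixture rows: dataset, feature_id, control %, tissue %s (NaN where
    a data set has no such tissue)."""
    path = resources.files("ampliclean").joinpath("data/printed_blocks.tsv")
    with resources.as_file(path) as p:
        return pd.read_csv(p, sep="\t")


def printed_abundance_blocks() -> dict[str, dict]:
    """Fixture profiles per data set.

    Returns ``{dataset: {"control": AbundanceProfile,
    "tissues": {tissue: AbundanceProfile}}}`` with percent inputs converted
    to fractional profiles.
    """
    df = printed_blocks_frame()
    out: dict[str, dict] = {}
    for ds, grp in df.groupby("dataset", sort=False):
        grp = grp.set_index("feature_id")
        block = {
            "control": AbundanceProfile.from_percentages(
                grp["control"], subset_label=f"{ds}:control"),
            "tissues": {},
        }
        for tissue in _TISSUE_COLUMNS:
            col = grp[tissue]
            if col.isna().all():
                continue
            block["tissues"][tissue] = AbundanceProfile.from_percentages(
                col, subset_label=f"{ds}:{tissue}")
        out[ds] = block
    return out
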