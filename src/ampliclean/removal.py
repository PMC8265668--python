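"""Apply a removal treatment to a feature table.

A treatment produces the experimental-samples-only analysis subset: either
untouched ("none"), with every control-detected feature dropped
("full_removal"), or with the features at/above a control-abundance threshold
tau dropped ("threshold"). Removal is feature-global within a data set: a
classified feature is removed from every experimental sample. Counts are not
re-normalized after removal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import MetadataError, SpecError
from .screening import (
    AbundanceProfile,
    TreatmentSpec,
    classify_threshold,
    pooled_relative_abundance,
)
from .table_ops import FeatureTable, SampleMetadata


@dataclass
class RemovalOutcome:
    treatment: TreatmentSpec
    removed_features: set[str]
    table_out: FeatureTable  # experimental samples only
    removed_fraction_per_sample: pd.Series  # fraction of reads removed

    def __post_init__(self):
        overlap = self.removed_features & set(self.table_out.feature_ids)
        if overlap:
            raise ValueError(f"removed features still present: {sorted(overlap)[:5]}")
        fr = self.removed_fraction_per_sample
        if ((fr < -1e-12) | (fr > 1 + 1e-12)).any():
            raise ValueError("removed fractions must lie in [0, 1]")


def candidate_features(table: FeatureTable, metadata: SampleMetadata,
                       spec: TreatmentSpec, dataset: str | None = None) -> set[str]:
    """The feature set a treatment removes (empty for kind='none')."""
    if spec.kind == "none":
        return set()
    ctrl = metadata.controls(dataset)
    ctrl = [s for s in ctrl if s in table.sample_ids]
    if not ctrl:
        raise MetadataError("no control samples available to derive candidates")
    profile = pooled_relative_abundance(table, ctrl)
    if spec.kind == "full_removal":
        return profile.features_detected()
    if spec.kind == "threshold":
        return classify_threshold(profile, spec.tau)
    raise SpecError(f"unknown treatment kind {spec.kind!r}")


def apply_treatment(table: FeatureTable, metadata: SampleMetadata,
                    spec: TreatmentSpec, dataset: str | None = None) -> RemovalOutcome:
    """Produce the analysis subset for one treatment within one data set.

    If ``dataset`` is None the metadata must describe a single data set.
    """
    if dataset is None:
        datasets = metadata.df.loc[
            [s for s in table.sample_ids if s in metadata.sample_ids], "dataset"
        ].unique()
        if len(datasets) != 1:
            raise MetadataError(
                "apply_treatment works per data set; pass dataset= when the "
                f"table spans several ({sorted(datasets)})"
            )
        dataset = datasets[0]

    removed = candidate_features(table, metadata, spec, dataset)
    exp = [s for s in metadata.experimental(dataset) if s in table.sample_ids]
    if not exp:
        raise MetadataError(f"dataset {dataset!r} has no experimental samples")
    exp_table = table.select_samples(exp)

    totals_in = exp_table.sample_totals()
    present_removed = [f for f in removed if f in exp_table.df.index]
    removed_reads = (exp_table.df.loc[present_removed].sum(axis=0)
                     if present_removed else pd.Series(0, index=exp))
    out = exp_table.drop_features(removed) if removed else exp_table

    frac = (removed_reads / totals_in.replace(0, pd.NA)).astype(float).fillna(0.0)
    return RemovalOutcome(
        treatment=spec,
        removed_features=set(removed),
        table_out=out,
        removed_fraction_per_sample=frac,
    )


def apply_all_treatments(table: FeatureTable, metadata: SampleMetadata,
                         specs, dataset: str | None = None) -> dict[str, RemovalOutcome]:
    """Apply each treatment; keys are treatment labels (none, full, t1, ...)."""
    return {spec.label: apply_treatment(table, metadata, spec, dataset) for spec in specs}
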