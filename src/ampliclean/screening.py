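"""Abundance-based contaminant screening.

The screening rule is deliberately simple: pool all reads of a sample subset,
compute each feature's *overall* relative abundance (summed counts over the
subset divided by the subset's total reads — not the mean of per-sample
proportions), and call any feature at or above a percent threshold tau in the
negative controls a candidate contaminant. Shared-burden summaries then ask
how many candidates are also detected in tissue samples and what fraction of
the tissue reads they carry.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .errors import UndefinedProfileError
from .table_ops import FeatureTable, SampleMetadata, ROLE_CONTROL, ROLE_EXPERIMENTAL

logger = logging.getLogger(__name__)

FULL_REMOVAL_LABEL = "full"


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero (report formatting; 2-decimal percent)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class AbundanceProfile:
    """Per-feature relative abundance (fractions) over one sample subset.

    ``complete`` marks profiles built from a full count table, which must sum
    to 1; profiles entered directly from printed percent tables may list only
    the abundant features and are marked incomplete.
    """

    abundances: pd.Series  # fraction in [0, 1], indexed by feature_id
    subset_label: str = ""
    total_counts: int = 0
    complete: bool = True

    def __post_init__(self):
        if (self.abundances < -1e-12).any():
            raise ValueError("negative abundance")
        if self.complete and self.total_counts > 0:
            s = float(self.abundances.sum())
            if abs(s - 1.0) > 1e-9:
                raise ValueError(f"complete profile sums to {s}, expected 1")

    @classmethod
    def from_percentages(cls, percents: dict | pd.Series, subset_label: str = "") -> "AbundanceProfile":
        """Build a (possibly partial) profile from percent values, e.g. a
        printed abundance table."""
        ser = pd.Series(percents, dtype=float) / 100.0
        return cls(ser, subset_label=subset_label, total_counts=0, complete=False)

    def percent(self, feature_id: str) -> float:
        return float(self.abundances.get(feature_id, 0.0)) * 100.0

    def percent_series(self) -> pd.Series:
        return self.abundances * 100.0

    def features_detected(self) -> set[str]:
        return set(self.abundances.index[self.abundances > 0])


def pooled_relative_abundance(table: FeatureTable, sample_ids) -> AbundanceProfile:
    """Overall relative abundance of every feature over ``sample_ids``."""
    sample_ids = list(sample_ids)
    if not sample_ids:
        raise ValueError("sample_ids must be nonempty")
    sub = table.select_samples(sample_ids)
    totals = sub.feature_totals()
    grand = int(totals.sum())
    if grand == 0:
        raise UndefinedProfileError(
            f"subset {sample_ids} has zero total counts; profile undefined"
        )
    return AbundanceProfile(totals / grand, subset_label=",".join(sample_ids),
                            total_counts=grand, complete=True)


def classify_threshold(control_profile: AbundanceProfile, tau: float) -> set[str]:
    """Features whose control relative abundance is >= ``tau`` percent."""
    if tau <= 0:
        raise ValueError("tau must be > 0 (use full_removal for tau -> 0)")
    pct = control_profile.percent_series()
    return set(pct.index[pct >= tau])


@dataclass
class TreatmentSpec:
    """One of the removal treatments: none, full removal of control-detected
    features, or removal at a control-abundance threshold of tau percent."""

    kind: str  # none | full_removal | threshold
    tau: float | None = None

    def __post_init__(self):
        if self.kind not in ("none", "full_removal", "threshold"):
            raise ValueError(f"unknown treatment kind {self.kind!r}")
        if self.kind == "threshold":
            if self.tau is None or self.tau <= 0:
                raise ValueError("threshold treatment requires tau > 0")
        elif self.tau is not None:
            raise ValueError(f"tau is only meaningful for threshold treatments")

    @property
    def label(self) -> str:
        if self.kind == "none":
            return "none"
        if self.kind == "full_removal":
            return FULL_REMOVAL_LABEL
        return f"t{self.tau:g}"

    @classmethod
    def from_label(cls, label: str) -> "TreatmentSpec":
        if label == "none":
            return cls("none")
        if label in (FULL_REMOVAL_LABEL, "full_removal"):
            return cls("full_removal")
        if label.startswith("t"):
            return cls("threshold", tau=float(label[1:]))
        raise ValueError(f"cannot parse treatment label {label!r}")


DEFAULT_TREATMENTS = (
    TreatmentSpec("none"),
    TreatmentSpec("full_removal"),
    TreatmentSpec("threshold", tau=1.0),
    TreatmentSpec("threshold", tau=5.0),
    TreatmentSpec("threshold", tau=10.0),
)


@dataclass
class SharedSummary:
    """Shared-contaminant burden of one candidate set in one tissue subset."""

    n_candidates: int
    n_shared: int
    pct_tissue: float  # summed tissue relative abundance of shared candidates, %

    def __post_init__(self):
        if not (0 <= self.n_shared <= self.n_candidates):
            raise ValueError("n_shared must lie in [0, n_candidates]")
        if not (-1e-9 <= self.pct_tissue <= 100 + 1e-9):
            raise ValueError("pct_tissue must lie in [0, 100]")

    @property
    def pct_tissue_rounded(self) -> float:
        return round_half_up(self.pct_tissue, 2)


def shared_contaminant_summary(candidates: set[str],
                               tissue_profile: AbundanceProfile) -> SharedSummary:
    """Count candidates detected (> 0) in the tissue subset and sum their
    tissue relative abundance (percent; unrounded internally)."""
    pct = tissue_profile.percent_series()
    shared = [f for f in candidates if float(pct.get(f, 0.0)) > 0]
    return SharedSummary(
        n_candidates=len(candidates),
        n_shared=len(shared),
        pct_tissue=float(pct.reindex(shared).sum()) if shared else 0.0,
    )


def screening_report(table: FeatureTable, metadata: SampleMetadata,
                     taus=(1.0, 5.0, 10.0)) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assemble the per-feature abundance report and shared-burden summary.

    Returns ``(contaminants, shared)``:

    * ``contaminants`` — one row per (dataset, feature) for every feature at
      or above min(taus) in that dataset's pooled controls, with its control
      abundance and its abundance in each tissue subset (percent, 2 dp).
    * ``shared`` — one row per (dataset, tissue, treatment) for each tau and
      for the full-removal set (every control-detected feature), holding the
      candidate count, shared count and shared tissue burden.
    """
    taus = sorted(float(t) for t in taus)
    contaminant_rows = []
    shared_rows = []
    for ds in metadata.datasets:
        ctrl = metadata.controls(ds)
        if not ctrl:
            logger.warning("dataset %s has no control samples; skipped", ds)
            continue
        exp_all = metadata.experimental(ds)
        if not exp_all:
            logger.warning("dataset %s has no experimental samples; skipped", ds)
            continue
        ctrl_profile = pooled_relative_abundance(table, ctrl)
        tissues = sorted(metadata.df.loc[exp_all, "tissue"].unique())
        tissue_profiles = {
            t: pooled_relative_abundance(table, metadata.experimental(ds, tissue=t))
            for t in tissues
        }

        report_features = sorted(
            classify_threshold(ctrl_profile, taus[0]),
            key=lambda f: -ctrl_profile.percent(f),
        )
        for f in report_features:
            row = {
                "dataset": ds,
                "feature_id": f,
                "control_pct": round_half_up(ctrl_profile.percent(f), 2),
            }
            for t in tissues:
                row[f"{t}_pct"] = round_half_up(tissue_profiles[t].percent(f), 2)
            contaminant_rows.append(row)

        candidate_sets = {f"t{tau:g}": classify_threshold(ctrl_profile, tau) for tau in taus}
        candidate_sets[FULL_REMOVAL_LABEL] = ctrl_profile.features_detected()
        for t in tissues:
            for label, cand in candidate_sets.items():
                summ = shared_contaminant_summary(cand, tissue_profiles[t])
                shared_rows.append({
                    "dataset": ds,
                    "tissue": t,
                    "treatment": label,
                    "n_candidates": summ.n_candidates,
                    "n_shared": summ.n_shared,
                    "pct_tissue": summ.pct_tissue_rounded,
                })

    contaminants = pd.DataFrame(
        contaminant_rows, columns=["dataset", "feature_id", "control_pct"]
        if not contaminant_rows else None)
    shared = pd.DataFrame(
        shared_rows, columns=["dataset", "tissue", "treatment",
                              "n_candidates", "n_shared", "pct_tissue"]
        if not shared_rows else None)
    return contaminants, shared
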