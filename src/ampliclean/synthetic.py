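"""Synthetic low-biomass amplicon data with known contamination structure.

The generator emulates the two phenomena that make negative-control-based
decontamination hard in low-microbial-biomass samples:

* a reagent/laboratory contaminant pool (the "kitome") that dominates the
  negative controls and bleeds into every tissue sample, with the bleed-in
  fraction varying between samples (a proxy for biomass differences); and
* cross-contamination of true resident taxa from tissue samples into the
  negative controls (well-to-well leakage / index switching), which is what
  breaks the naive "remove everything seen in a control" rule.

Compositions are mixed on disjoint feature blocks (true residents vs pool)
and counts are drawn multinomially at a per-sample depth, so column totals
are exact and ground truth is a clean partition. Per-sample overdispersion of
the true community enters through a log-normal perturbation of a log-normal
base profile. Singleton features (total count 1) are injected by swapping one
read, preserving column totals, to exercise singleton filtering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .table_ops import FeatureTable, SampleMetadata

LABEL_CONTAMINANT = "contaminant"
LABEL_TRUE = "true_resident"


@dataclass
class GeneratorConfig:
    """Study conditions for one simulated data set.

    Defaults mirror a typical lab-reared mosquito tissue study: 23 tissue
    samples against 6 negative controls sequenced at 25,000 reads; a
    contaminant pool with one dominant member at ~20% plus a diverse tail;
    roughly a third of tissue reads of contaminant origin on average; and ~1%
    of control reads leaked from the true community.
    """

    n_experimental: int = 23
    n_controls: int = 6
    n_true_features: int = 80
    n_contam_features: int = 60
    true_sigma: float = 1.5        # log-normal sd of the base true profile
    sample_sigma: float = 0.5      # per-sample log-normal dispersion
    contam_alpha: float = 1.0      # Dirichlet concentration of the pool tail
    dominant_share: float = 0.20   # pool share of the single dominant contaminant
    bleed_mean: float = 0.30       # mean contaminant fraction in tissue samples
    bleed_conc: float = 10.0       # Beta concentration of per-sample bleed
    cross_fraction: float = 0.01   # true-community fraction in controls
    depth_min: int = 25_000
    depth_max: int = 25_000
    singleton_rate: float = 0.02   # injected singletons per feature
    endosymbiont_share: float = 0.0  # optional fixed share of one true feature
    dataset: str = "sim"
    tissue: str = "gut"
    seed: int = 0

    def __post_init__(self):
        for name in ("bleed_mean", "cross_fraction", "dominant_share",
                     "endosymbiont_share", "singleton_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.n_true_features < 1:
            raise ValueError("need at least one true feature")
        if self.n_experimental < 1 or self.n_controls < 1:
            raise ValueError("need at least one experimental and one control sample")
        if not (1 <= self.depth_min <= self.depth_max):
            raise ValueError("require 1 <= depth_min <= depth_max")


@dataclass
class SyntheticTruth:
    """Ground-truth labels plus each feature's realized pooled control abundance."""

    labels: dict[str, str]  # feature_id -> contaminant | true_resident
    pooled_control_abundance: pd.Series  # fraction of control reads per feature

    def contaminant_ids(self) -> set[str]:
        return {f for f, lab in self.labels.items() if lab == LABEL_CONTAMINANT}

    def contaminants_at(self, tau_percent: float) -> set[str]:
        """Contaminant-pool features whose realized pooled control abundance
        is at/above ``tau_percent``."""
        pct = self.pooled_control_abundance * 100.0
        return {f for f in self.contaminant_ids() if pct.get(f, 0.0) >= tau_percent}


def _pool_weights(cfg: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    n = cfg.n_contam_features
    if n == 0:
        return np.zeros(0)
    if n == 1:
        return np.ones(1)
    if cfg.dominant_share > 0:
        tail = rng.dirichlet(np.full(n - 1, cfg.contam_alpha))
        return np.concatenate([[cfg.dominant_share], tail * (1 - cfg.dominant_share)])
    return rng.dirichlet(np.full(n, cfg.contam_alpha))


def _base_true_weights(cfg: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    w = np.exp(cfg.true_sigma * rng.standard_normal(cfg.n_true_features))
    w /= w.sum()
    if cfg.endosymbiont_share > 0 and cfg.n_true_features > 1:
        w = w * (1 - cfg.endosymbiont_share) / (1 - w[0]) if w[0] < 1 else w
        w[0] = cfg.endosymbiont_share
        w /= w.sum()
    return w


def generate(config: GeneratorConfig) -> tuple[FeatureTable, SampleMetadata, SyntheticTruth]:
    """Draw one feature table with metadata and ground truth; deterministic
    given ``config.seed``."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    true_ids = [f"true_{i:04d}" for i in range(cfg.n_true_features)]
    contam_ids = [f"contam_{i:04d}" for i in range(cfg.n_contam_features)]
    feature_ids = true_ids + contam_ids
    n_feat = len(feature_ids)

    pool = _pool_weights(cfg, rng)
    base_true = _base_true_weights(cfg, rng)

    pool_full = np.zeros(n_feat)
    if cfg.n_contam_features:
        pool_full[cfg.n_true_features:] = pool
    true_full_base = np.zeros(n_feat)
    true_full_base[: cfg.n_true_features] = base_true

    columns = {}
    roles = {}

    # negative controls: contaminant pool plus cross-contaminated true taxa
    if cfg.n_contam_features:
        ctrl_comp = (1 - cfg.cross_fraction) * pool_full + cfg.cross_fraction * true_full_base
    else:
        ctrl_comp = true_full_base  # no pool: controls see only leaked true taxa
    ctrl_comp = ctrl_comp / ctrl_comp.sum()
    for i in range(cfg.n_controls):
        depth = int(rng.integers(cfg.depth_min, cfg.depth_max + 1))
        sid = f"ctrl_{i:02d}"
        columns[sid] = rng.multinomial(depth, ctrl_comp)
        roles[sid] = "control"

    # tissue samples: per-sample true profile plus bleed-in from the pool
    for i in range(cfg.n_experimental):
        w = base_true * np.exp(cfg.sample_sigma * rng.standard_normal(cfg.n_true_features))
        w /= w.sum()
        if cfg.n_contam_features and cfg.bleed_mean > 0:
            if cfg.bleed_conc > 0 and 0 < cfg.bleed_mean < 1:
                eps = rng.beta(cfg.bleed_mean * cfg.bleed_conc,
                               (1 - cfg.bleed_mean) * cfg.bleed_conc)
            else:
                eps = cfg.bleed_mean
        else:
            eps = 0.0
        comp = np.zeros(n_feat)
        comp[: cfg.n_true_features] = (1 - eps) * w
        comp += eps * pool_full
        comp /= comp.sum()
        depth = int(rng.integers(cfg.depth_min, cfg.depth_max + 1))
        sid = f"exp_{i:02d}"
        columns[sid] = rng.multinomial(depth, comp)
        roles[sid] = "experimental"

    counts = pd.DataFrame(columns, index=feature_ids)
    labels = {f: LABEL_TRUE for f in true_ids}
    labels.update({f: LABEL_CONTAMINANT for f in contam_ids})

    # singleton injection: swap one read so column totals stay exact
    n_singletons = int(round(cfg.singleton_rate * n_feat))
    sample_ids = list(counts.columns)
    for i in range(n_singletons):
        sid = sample_ids[int(rng.integers(len(sample_ids)))]
        col = counts[sid]
        donors = col.index[col >= 2]
        if len(donors) == 0:
            continue
        donor = donors[int(rng.integers(len(donors)))]
        new_id = f"singleton_{i:04d}"
        counts.loc[donor, sid] -= 1
        counts.loc[new_id, :] = 0
        counts.loc[new_id, sid] = 1
        labels[new_id] = LABEL_TRUE

    table = FeatureTable(counts.fillna(0).astype(np.int64), drop_empty_samples=False)
    meta = SampleMetadata(pd.DataFrame({
        "role": pd.Series(roles),
        "dataset": cfg.dataset,
        "tissue": cfg.tissue,
    }))

    ctrl_cols = [s for s, r in roles.items() if r == "control"]
    ctrl_totals = table.df[ctrl_cols].sum(axis=1)
    pooled = ctrl_totals / ctrl_totals.sum()
    truth = SyntheticTruth(labels=labels, pooled_control_abundance=pooled)
    return table, meta, truth


def recovery_metrics(truth: SyntheticTruth, called: set[str]) -> tuple[float, float]:
    """Precision and recall of a contaminant call set against ground truth.

    Precision is NaN when nothing was called; recall is NaN when the truth
    contains no contaminants.
    """
    universe = set(truth.labels)
    unknown = set(called) - universe
    if unknown:
        raise ValueError(f"called features outside the universe: {sorted(unknown)[:5]}")
    contam = truth.contaminant_ids()
    tp = len(called & contam)
    precision = tp / len(called) if called else float("nan")
    recall = tp / len(contam) if contam else float("nan")
    return precision, recall
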