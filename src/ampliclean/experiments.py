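"""Simulation studies: recovery, impact and calibration of the screening
pipeline on generated data.

Each study runs the full library path (generate -> screen/classify -> remove
-> diversity -> compare) over many seeded replicates and returns tidy frames.
Child seeds are spawned deterministically from one master seed.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .comparison import paired_compare
from .diversity import alpha_diversity
from .prevalence import classify_prevalence, prevalence_results
from .removal import apply_treatment
from .screening import TreatmentSpec, classify_threshold, pooled_relative_abundance
from .synthetic import GeneratorConfig, generate
from .table_ops import NormalizationConfig, filter_singletons, subsample_to_depth


def _child_seeds(seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def threshold_recovery_study(n_seeds: int = 20, taus=(1.0, 5.0, 10.0),
                             config: GeneratorConfig | None = None,
                             seed: int = 0) -> pd.DataFrame:
    """Exact recovery of the contaminant pool by abundance thresholding.

    With no cross-contamination the negative controls contain only pool
    features, so thresholding their pooled abundance must return *exactly*
    the pool features whose realized control abundance is at/above tau.
    """
    base = config or GeneratorConfig()
    rows = []
    for s in _child_seeds(seed, n_seeds):
        cfg = replace(base, cross_fraction=0.0, seed=s)
        table, meta, truth = generate(cfg)
        profile = pooled_relative_abundance(table, meta.controls())
        for tau in taus:
            called = classify_threshold(profile, tau)
            expected = truth.contaminants_at(tau)
            rows.append({
                "seed": s, "tau": tau,
                "n_called": len(called), "n_expected": len(expected),
                "exact_match": called == expected,
            })
    return pd.DataFrame(rows)


# The prevalence study runs in the low-bleed regime where the score is
# informative: at higher bleed-through the contaminants are detected in
# essentially every tissue sample, the presence margins degenerate, and the
# test is uninformative by design (the cross-contamination caveat).
PREVALENCE_STUDY_CONFIG = GeneratorConfig(
    n_experimental=40,
    n_controls=6,
    bleed_mean=5e-4,
    bleed_conc=0.0,  # constant bleed per sample
    cross_fraction=0.0,
    depth_min=2_000,
    depth_max=2_000,
)


def prevalence_recovery_study(n_seeds: int = 20, p_star: float = 0.5,
                              min_control_pct: float = 1.0,
                              config: GeneratorConfig | None = None,
                              seed: int = 0) -> pd.DataFrame:
    """Recall/precision of the prevalence test for pool features at/above a
    control-abundance floor, pooled over seeds by summing counts."""
    base = config or PREVALENCE_STUDY_CONFIG
    rows = []
    for s in _child_seeds(seed, n_seeds):
        cfg = replace(base, seed=s)
        table, meta, truth = generate(cfg)
        results = prevalence_results(table, meta)
        called = classify_prevalence(results, p_star)
        qualifying = truth.contaminants_at(min_control_pct)
        tp = len(called & qualifying)
        rows.append({
            "seed": s,
            "n_qualifying": len(qualifying),
            "n_called": len(called),
            "tp": tp,
            "recall": tp / len(qualifying) if qualifying else float("nan"),
        })
    return pd.DataFrame(rows)


def pooled_recall(study: pd.DataFrame) -> float:
    return float(study["tp"].sum() / study["n_qualifying"].sum())


def removal_impact_study(n_seeds: int = 50, alpha: float = 0.05,
                         config: GeneratorConfig | None = None,
                         seed: int = 0) -> pd.DataFrame:
    """Effect of full removal on per-sample richness and Shannon diversity.

    For each replicate: generate, drop singletons, apply the non-removal and
    full-removal treatments, and compare alpha diversity with the paired
    test. Also records whether the removal decreased (or left unchanged)
    every sample's value.
    """
    base = config or GeneratorConfig()
    rows = []
    for s in _child_seeds(seed, n_seeds):
        cfg = replace(base, seed=s)
        table, meta, truth = generate(cfg)
        table = filter_singletons(table)
        none_out = apply_treatment(table, meta, TreatmentSpec("none"))
        full_out = apply_treatment(table, meta, TreatmentSpec("full_removal"))
        a_none = alpha_diversity(none_out.table_out)
        a_full = alpha_diversity(full_out.table_out)
        dom_pct = float(truth.pooled_control_abundance.max()) * 100.0
        row = {"seed": s, "dominant_control_pct": dom_pct}
        for metric in ("richness_S", "shannon_H"):
            x = a_none[metric]
            y = a_full[metric].reindex(x.index)
            res = paired_compare(x, y, alpha=alpha,
                                 treatment_a="none", treatment_b="full")
            row[f"direction_ok_{metric}"] = bool((y <= x + 1e-12).all())
            row[f"p_{metric}"] = res.p_value
            row[f"significant_{metric}"] = res.significant
        rows.append(row)
    return pd.DataFrame(rows)


def type1_study(n_sims: int = 200, alpha: float = 0.05,
                rarefy_depth: int = 1_000,
                config: GeneratorConfig | None = None,
                seed: int = 0) -> pd.DataFrame:
    """Type-I error of the treatment comparison under zero contamination.

    With no bleed-through and no cross-contamination the tau = 1% candidates
    are absent from every tissue sample, so the treatment removes nothing:
    the null of "no diversity difference" is exactly true. Each treatment
    subset is rarefied independently, which is the stochastic channel the
    comparison sees in practice; the paired test on per-sample Shannon values
    should then reject at its nominal rate.
    """
    base = config or GeneratorConfig(bleed_mean=0.0, cross_fraction=0.0,
                                     depth_min=2_000, depth_max=2_000)
    rows = []
    for s in _child_seeds(seed, n_sims):
        cfg = replace(base, bleed_mean=0.0, cross_fraction=0.0, seed=s)
        table, meta, _ = generate(cfg)
        table = filter_singletons(table)
        none_out = apply_treatment(table, meta, TreatmentSpec("none"))
        t1_out = apply_treatment(table, meta, TreatmentSpec("threshold", tau=1.0))
        rare_none = subsample_to_depth(
            none_out.table_out, NormalizationConfig(depth=rarefy_depth, seed=2 * s))
        rare_t1 = subsample_to_depth(
            t1_out.table_out, NormalizationConfig(depth=rarefy_depth, seed=2 * s + 1))
        h_none = alpha_diversity(rare_none)["shannon_H"]
        h_t1 = alpha_diversity(rare_t1)["shannon_H"].reindex(h_none.index)
        res = paired_compare(h_none, h_t1, alpha=alpha,
                             treatment_a="none", treatment_b="t1")
        rows.append({"seed": s, "test": res.test_used,
                     "p_value": res.p_value, "significant": res.significant})
    return pd.DataFrame(rows)


def rejection_rate(study: pd.DataFrame) -> float:
    return float(study["significant"].mean())
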