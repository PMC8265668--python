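"""Prevalence-based contaminant classification.

For each feature, presence/absence is tabulated in negative controls versus
experimental samples and a one-sided score P asks whether the feature is
*more prevalent in controls*. Small P means contaminant-like. The score is a
chi-square test on the 2x2 presence table (no continuity correction), halved
and directed by the sign of the prevalence difference; whenever any expected
cell is below 5 the one-sided Fisher exact test (hypergeometric tail) is used
instead. Features more prevalent in experimental samples are never classified
(their score is clamped to at least 0.5), and degenerate margins (present in
all samples, or none) score 1. A feature is called a contaminant when
P < P* for a user-chosen threshold P* (conventional choices: 0.1 and 0.5).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import MetadataError
from .table_ops import FeatureTable, SampleMetadata, ROLE_CONTROL, ROLE_EXPERIMENTAL


@dataclass
class PrevalenceResult:
    feature_id: str
    k_ctrl: int
    n_ctrl: int
    k_exp: int
    n_exp: int
    score_P: float

    def is_contaminant(self, p_star: float) -> bool:
        return self.score_P < p_star


def presence_counts(table: FeatureTable, metadata: SampleMetadata,
                    detect_min: int = 1) -> pd.DataFrame:
    """Per-feature detection counts in control vs experimental samples.

    A feature is *present* in a sample when its count is >= ``detect_min``.
    Returns a DataFrame indexed by feature_id with columns
    k_ctrl, n_ctrl, k_exp, n_exp (totals constant across features).
    """
    ctrl = [s for s in table.sample_ids
            if metadata.df.loc[s, "role"] == ROLE_CONTROL] if set(
                table.sample_ids) <= set(metadata.sample_ids) else None
    if ctrl is None:
        missing = [s for s in table.sample_ids if s not in metadata.sample_ids]
        raise MetadataError(f"samples without role labels: {missing}")
    exp = [s for s in table.sample_ids if metadata.df.loc[s, "role"] == ROLE_EXPERIMENTAL]
    if not ctrl or not exp:
        raise MetadataError("need at least one control and one experimental sample")
    present = table.df >= detect_min
    out = pd.DataFrame({
        "k_ctrl": present[ctrl].sum(axis=1).astype(int),
        "n_ctrl": len(ctrl),
        "k_exp": present[exp].sum(axis=1).astype(int),
        "n_exp": len(exp),
    })
    return out


def fisher_one_sided(k_ctrl: int, n_ctrl: int, k_exp: int, n_exp: int) -> float:
    """Upper-tail Fisher exact p: P(X >= k_ctrl) with
    X ~ Hypergeometric(n_ctrl + n_exp, k_ctrl + k_exp, n_ctrl)."""
    n_tot = n_ctrl + n_exp
    k_tot = k_ctrl + k_exp
    return float(stats.hypergeom.sf(k_ctrl - 1, n_tot, k_tot, n_ctrl))


def prevalence_score(k_ctrl: int, n_ctrl: int, k_exp: int, n_exp: int) -> float:
    """One-sided score P; small values indicate control-enriched prevalence."""
    if n_ctrl < 1 or n_exp < 1:
        raise ValueError("need n_ctrl >= 1 and n_exp >= 1")
    if not (0 <= k_ctrl <= n_ctrl and 0 <= k_exp <= n_exp):
        raise ValueError("detection counts exceed sample counts")
    n_tot = n_ctrl + n_exp
    k_tot = k_ctrl + k_exp
    if k_tot == 0 or k_tot == n_tot:
        return 1.0  # degenerate margin: presence uninformative

    prev_ctrl = k_ctrl / n_ctrl
    prev_exp = k_exp / n_exp

    # expected cells of the 2x2 table under independence
    expected_min = min(
        n_ctrl * k_tot, n_ctrl * (n_tot - k_tot),
        n_exp * k_tot, n_exp * (n_tot - k_tot),
    ) / n_tot

    if expected_min < 5:
        p = fisher_one_sided(k_ctrl, n_ctrl, k_exp, n_exp)
        if prev_ctrl < prev_exp:
            p = max(p, 0.5)
        return min(p, 1.0)

    table = np.array([[k_ctrl, n_ctrl - k_ctrl], [k_exp, n_exp - k_exp]])
    _, p_two, _, _ = stats.chi2_contingency(table, correction=False)
    half = p_two / 2.0
    if prev_ctrl > prev_exp:
        return float(half)
    if prev_ctrl < prev_exp:
        return float(1.0 - half)
    return 0.5


def prevalence_results(table: FeatureTable, metadata: SampleMetadata,
                       detect_min: int = 1) -> list[PrevalenceResult]:
    counts = presence_counts(table, metadata, detect_min=detect_min)
    return [
        PrevalenceResult(
            feature_id=f,
            k_ctrl=int(r.k_ctrl), n_ctrl=int(r.n_ctrl),
            k_exp=int(r.k_exp), n_exp=int(r.n_exp),
            score_P=prevalence_score(int(r.k_ctrl), int(r.n_ctrl),
                                     int(r.k_exp), int(r.n_exp)),
        )
        for f, r in counts.iterrows()
    ]


def classify_prevalence(results, p_star: float) -> set[str]:
    """Features with score_P strictly below the classification threshold P*."""
    if not (0 < p_star < 1):
        raise ValueError("p_star must lie in (0, 1)")
    return {r.feature_id for r in results if r.score_P < p_star}


def prevalence_table(results, p_stars=(0.1, 0.5)) -> pd.DataFrame:
    """Tabulate results with one contaminant call column per P*."""
    rows = []
    for r in results:
        row = {
            "feature_id": r.feature_id,
            "k_ctrl": r.k_ctrl, "n_ctrl": r.n_ctrl,
            "k_exp": r.k_exp, "n_exp": r.n_exp,
            "score_P": r.score_P,
        }
        for p_star in p_stars:
            row[f"contaminant_p{p_star:g}"] = r.is_contaminant(p_star)
        rows.append(row)
    return pd.DataFrame(rows).set_index("feature_id")
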