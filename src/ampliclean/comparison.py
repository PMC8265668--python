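"""Paired statistical comparison of diversity between removal treatments.

Within a data set, every sample (alpha diversity) or unordered sample pair
(beta diversity) yields one paired observation per treatment. For each pair
of treatments the paired differences are gated through a Shapiro-Wilk
normality test at alpha = 0.05: a paired t test when normality is not
rejected, a Wilcoxon signed-rank test otherwise. Identical vectors give a
degenerate comparison with p = 1. Letter displays summarize the pattern: two
treatments share a letter exactly when they do not differ significantly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError

logger = logging.getLogger(__name__)

DEFAULT_TREATMENT_ORDER = ("none", "full", "t1", "t5", "t10")


@dataclass
class PairedTestResult:
    treatment_a: str
    treatment_b: str
    n_pairs: int
    test_used: str  # paired_t | wilcoxon_signed_rank | degenerate
    p_value: float
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def significance_band(p: float) -> str:
    """Asterisk band: * for p in [0.005, 0.05), ** for [0.0005, 0.005), *** below."""
    if p < 0.0005:
        return "***"
    if p < 0.005:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def _wilcoxon(d: np.ndarray) -> float:
    nz = d[d != 0]  # zero differences dropped (zero_method='wilcox')
    if nz.size == 0:
        return 1.0
    if np.all(nz == nz[0]):
        # constant nonzero differences: zero rank variance; exact sign test
        return min(1.0, 2.0 * 0.5 ** nz.size)
    if nz.size <= 25:
        try:
            return float(stats.wilcoxon(nz, zero_method="wilcox", method="exact").pvalue)
        except (ValueError, stats.FitError):  # ties -> exact unavailable
            pass
    return float(stats.wilcoxon(nz, zero_method="wilcox", method="approx",
                                correction=False).pvalue)


def paired_compare(x, y, alpha: float = 0.05,
                   treatment_a: str = "a", treatment_b: str = "b") -> PairedTestResult:
    """Compare two paired value vectors (missing pairs dropped)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired vectors must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise InsufficientDataError(f"only {x.size} valid pairs; need >= 3")
    d = x - y
    if np.all(d == 0):
        return PairedTestResult(treatment_a, treatment_b, int(d.size),
                                "degenerate", 1.0, alpha)
    if np.all(d == d[0]):
        # constant nonzero shift: no variance for Shapiro or t; exact sign test
        return PairedTestResult(treatment_a, treatment_b, int(d.size),
                                "wilcoxon_signed_rank", _wilcoxon(d), alpha)
    sw_p = float(stats.shapiro(d).pvalue)
    if sw_p >= 0.05:
        p = float(stats.ttest_rel(x, y).pvalue)
        test = "paired_t"
    else:
        p = _wilcoxon(d)
        test = "wilcoxon_signed_rank"
    return PairedTestResult(treatment_a, treatment_b, int(d.size), test, p, alpha)


@dataclass
class LetterGroups:
    """Compact letter display: treatments sharing a letter do not differ
    significantly at ``alpha``."""

    letters: dict[str, str]
    alpha: float = 0.05


def letter_groups(treatments, results, alpha: float = 0.05) -> LetterGroups:
    """Build the letter display from pairwise results.

    Letters are the maximal cliques of the non-significance graph, ordered
    deterministically by treatment rank, so every non-significant pair shares
    at least one letter and no significant pair shares any.
    """
    treatments = list(treatments)
    rank = {t: i for i, t in enumerate(treatments)}
    g = nx.Graph()
    g.add_nodes_from(treatments)
    for r in results:
        if not r.significant:
            g.add_edge(r.treatment_a, r.treatment_b)
    cliques = [sorted(c, key=rank.get) for c in nx.find_cliques(g)]
    cliques.sort(key=lambda c: [rank[t] for t in c])
    letters = {t: "" for t in treatments}
    for i, clique in enumerate(cliques):
        letter = chr(ord("a") + i) if i < 26 else f"a{i}"
        for t in clique:
            letters[t] += letter
    return LetterGroups(letters=letters, alpha=alpha)


def compare_treatments(values: dict[str, pd.Series], alpha: float = 0.05,
                       order=None, holm: bool = False
                       ) -> tuple[list[PairedTestResult], LetterGroups]:
    """All pairwise treatment comparisons plus the letter display.

    ``values`` maps treatment label -> Series of one diversity value per
    pairing key (sample_id for alpha metrics, unordered 'a|b' sample-pair id
    for beta metrics). Only keys present in every treatment are used.
    ``holm`` applies a Holm step-down correction across the pairwise p-values
    (off by default).
    """
    if len(values) < 2:
        raise InsufficientDataError("need at least two treatments to compare")
    labels = [t for t in (order or DEFAULT_TREATMENT_ORDER) if t in values]
    labels += [t for t in values if t not in labels]
    common = None
    for ser in values.values():
        keys = set(ser.index)
        common = keys if common is None else common & keys
    common = sorted(common)
    if len(common) < 3:
        raise InsufficientDataError(f"only {len(common)} shared pairing keys")

    results = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            a, b = labels[i], labels[j]
            res = paired_compare(values[a].reindex(common), values[b].reindex(common),
                                 alpha=alpha, treatment_a=a, treatment_b=b)
            results.append(res)
    if holm:
        from statsmodels.stats.multitest import multipletests
        adj = multipletests([r.p_value for r in results], alpha=alpha, method="holm")[1]
        for r, p in zip(results, adj):
            r.p_value = float(p)
    return results, letter_groups(labels, results, alpha=alpha)


def comparison_table(results, metric: str = "", dataset: str = "") -> pd.DataFrame:
    rows = [{
        "dataset": dataset,
        "metric": metric,
        "treatment_a": r.treatment_a,
        "treatment_b": r.treatment_b,
        "n_pairs": r.n_pairs,
        "test": r.test_used,
        "p_value": r.p_value,
        "band": significance_band(r.p_value),
    } for r in results]
    return pd.DataFrame(rows)
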